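"""Shared fixtures: a small simulated genome plus XX and XY alignment bundles.

Everything is generated at test time from the package's own simulator, so the
suite ships no data files. Session scope keeps the BAM-producing fixtures to
one simulation each.
"""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from chromplex import bammetrics, simdata
from chromplex._util import GenomicInterval, write_bed
from chromplex.refmask import write_fasta

WINDOW = 1_000


def small_spec(seed: int = 0) -> simdata.GenomeSpec:
    """A 60/60/50-kb genome: cheap, still >=50 windows per chromosome at 1 kb."""
    return simdata.GenomeSpec(
        autosome_len=60_000,
        x_len=60_000,
        y_len=50_000,
        par_blocks=[
            (GenomicInterval("chrX", 0, 3_000, "PAR1"),
             GenomicInterval("chrY", 0, 3_000, "PAR1")),
            (GenomicInterval("chrX", 57_000, 60_000, "PAR2"),
             GenomicInterval("chrY", 47_000, 50_000, "PAR2")),
        ],
        xtr_block=(
            GenomicInterval("chrX", 30_000, 36_000, "XTR"),
            GenomicInterval("chrY", 10_000, 16_000, "XTR"),
        ),
        seed=seed,
    )


def make_bam(path: Path, chrom_lengths: dict[str, int], reads: list[dict]) -> Path:
    """Hand-built BAM for exact-value tests.

    Each read dict: chrom, pos, plus optional length (default 100), mapq
    (default 60), qname, flag, seq.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in chrom_lengths.items()],
        "RG": [{"ID": "rg1", "SM": "s"}],
    }
    tid = {n: i for i, n in enumerate(chrom_lengths)}
    segs = []
    for i, r in enumerate(reads):
        length = r.get("length", 100)
        seg = pysam.AlignedSegment()
        seg.query_name = r.get("qname", f"r{i:04d}")
        seg.query_sequence = r.get("seq", "A" * length)
        seg.flag = r.get("flag", 0)
        seg.reference_id = tid[r["chrom"]]
        seg.reference_start = r["pos"]
        seg.mapping_quality = r.get("mapq", 60)
        seg.cigartuples = [(0, length)]
        seg.query_qualities = pysam.qualitystring_to_array("I" * length)
        seg.set_tag("RG", "rg1")
        segs.append(seg)
    segs.sort(key=lambda s: (s.reference_id, s.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for seg in segs:
            bam.write(seg)
    pysam.index(str(path))
    return path


def _bundle(tmpdir: Path, complement: str, seed: int, **sim_kwargs) -> dict:
    spec = small_spec(seed=seed)
    records, features = simdata.simulate_genome(spec)
    fasta = write_fasta(records, tmpdir / "toy.fa")
    write_bed(features, tmpdir / "features.bed")
    write_bed(
        [iv for iv in features if iv.chrom == "chrY" and iv.name.startswith("PAR")],
        tmpdir / "y_pars.bed",
    )
    ploidy_cfg = simdata.PloidyConfig(complement=complement, mean_depth=20, seed=seed + 1)
    variants, vcf = simdata.simulate_variants(
        records, ploidy_cfg, out_vcf=tmpdir / "truth.vcf"
    )
    bam, truth = simdata.simulate_alignments(
        records, spec, ploidy_cfg, tmpdir / f"{complement.lower()}.bam",
        variants=variants, **sim_kwargs,
    )
    windows = {c: bammetrics.traverse(bam, c, WINDOW) for c in ("chrA", "chrX", "chrY")}
    return {
        "spec": spec,
        "records": records,
        "features": features,
        "fasta": fasta,
        "y_par_bed": tmpdir / "y_pars.bed",
        "ploidy": ploidy_cfg,
        "variants": variants,
        "truth_vcf": vcf,
        "bam": bam,
        "truth": truth,
        "windows": windows,
        "dir": tmpdir,
    }


@pytest.fixture(scope="session")
def xy_bundle(tmp_path_factory) -> dict:
    return _bundle(tmp_path_factory.mktemp("xy"), "XY", seed=11)


@pytest.fixture(scope="session")
def xx_bundle(tmp_path_factory) -> dict:
    return _bundle(tmp_path_factory.mktemp("xx"), "XX", seed=23)
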