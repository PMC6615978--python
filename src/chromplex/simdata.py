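"""Synthetic genome, alignment, and variant fixtures with known truth.

The generator emulates, at desk scale, the genomic architecture that drives
sex-chromosome mapping artifacts in real mammalian data:

* a toy genome with one autosome (chrA), an X (chrX) and a Y (chrY);
* two pseudoautosomal blocks (PAR1, PAR2) copied byte-identically between X
  and Y — reads born there map equally well to both chromosomes when both
  are present in the reference, so they receive MAPQ 0 and a coin-flip
  placement;
* an X-transposed-like block (XTR) on Y that is a high-identity (default
  98%) copy of an X block — partial homology that depresses MAPQ without
  zeroing it;
* read depth proportional to copy number, so an XY individual shows
  depth(X)/depth(A) ~ 0.5 and an XX individual ~ 1.0.

All outputs are pure functions of (spec, seed). The "aligner" here is the
simulator itself: placements are written directly into a coordinate-sorted
BAM according to a mapping-quality model that encodes which reference the
reads were notionally mapped against (both sex chromosomes present, Y fully
masked, or Y-PARs masked).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from ._util import ChromplexError, GenomicInterval, write_bed
from .refmask import write_fasta

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: copy number of (autosome, X, Y) per sex-chromosome complement
KARYOTYPES: dict[str, dict[str, int]] = {
    "XX": {"chrA": 2, "chrX": 2, "chrY": 0},
    "XY": {"chrA": 2, "chrX": 1, "chrY": 1},
    "X0": {"chrA": 2, "chrX": 1, "chrY": 0},
    "XXY": {"chrA": 2, "chrX": 2, "chrY": 1},
}

MAPQ_MODELS = ("both_sex_chroms", "y_masked", "y_par_masked")


@dataclass
class GenomeSpec:
    """Layout of the toy genome.

    Default lengths give >=100 windows per chromosome at 1-kb windows while
    keeping simulation cheap. PAR blocks are (X interval, Y interval) pairs
    of equal length copied identically; the XTR block is copied with
    ``xtr_identity`` fraction of matching bases.
    """

    autosome_len: int = 120_000
    x_len: int = 120_000
    y_len: int = 110_000
    par_blocks: list[tuple[GenomicInterval, GenomicInterval]] = field(default=None)  # type: ignore[assignment]
    xtr_block: tuple[GenomicInterval, GenomicInterval] = None  # type: ignore[assignment]
    xtr_identity: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.par_blocks is None:
            self.par_blocks = [
                (GenomicInterval("chrX", 0, 5_000, "PAR1"),
                 GenomicInterval("chrY", 0, 5_000, "PAR1")),
                (GenomicInterval("chrX", self.x_len - 5_000, self.x_len, "PAR2"),
                 GenomicInterval("chrY", self.y_len - 5_000, self.y_len, "PAR2")),
            ]
        if self.xtr_block is None:
            self.xtr_block = (
                GenomicInterval("chrX", 60_000, 70_000, "XTR"),
                GenomicInterval("chrY", 20_000, 30_000, "XTR"),
            )
        if not 0 < self.xtr_identity <= 1:
            raise ChromplexError("xtr_identity must be in (0, 1]")
        lengths = {"chrA": self.autosome_len, "chrX": self.x_len, "chrY": self.y_len}
        for x_iv, y_iv in self.par_blocks:
            if len(x_iv) != len(y_iv):
                raise ChromplexError("PAR block X and Y intervals must be equal length")
        for iv in self.features():
            if iv.end > lengths[iv.chrom]:
                raise ChromplexError(f"feature {iv.name} exceeds {iv.chrom} length")
        # features on the same chromosome must not overlap
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.features():
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda v: v.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ChromplexError(f"overlapping features {a.name} and {b.name}")

    def chrom_lengths(self) -> dict[str, int]:
        return {"chrA": self.autosome_len, "chrX": self.x_len, "chrY": self.y_len}

    def features(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for x_iv, y_iv in self.par_blocks:
            out.extend([x_iv, y_iv])
        out.extend(self.xtr_block)
        return out


@dataclass
class PloidyConfig:
    """Sequencing conditions for one simulated individual.

    ``mean_depth`` is the fold coverage of a diploid chromosome; a haploid
    chromosome receives half of it.
    """

    complement: str = "XY"
    mean_depth: float = 20.0
    read_len: int = 100
    paired: bool = True
    error_rate: float = 0.001
    n_read_groups: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.complement not in KARYOTYPES:
            raise ChromplexError(f"unknown complement {self.complement!r}")
        if self.mean_depth <= 0:
            raise ChromplexError("mean_depth must be > 0")

    def copy_numbers(self) -> dict[str, int]:
        return dict(KARYOTYPES[self.complement])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(spec: GenomeSpec) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Random-but-seeded toy genome honouring the spec's homology structure."""
    rng = np.random.default_rng(spec.seed)
    seqs = {
        name: rng.choice(BASES, size=length)
        for name, length in spec.chrom_lengths().items()
    }
    # copy PARs identically X -> Y
    for x_iv, y_iv in spec.par_blocks:
        seqs["chrY"][y_iv.start : y_iv.end] = seqs["chrX"][x_iv.start : x_iv.end]
    # copy XTR with (1 - identity) substitutions to a different base
    x_iv, y_iv = spec.xtr_block
    block = seqs["chrX"][x_iv.start : x_iv.end].copy()
    if spec.xtr_identity < 1.0:
        sub = rng.random(len(block)) < (1.0 - spec.xtr_identity)
        shifted = (np.searchsorted(BASES, block[sub]) + rng.integers(1, 4, sub.sum())) % 4
        block[sub] = BASES[shifted]
    seqs["chrY"][y_iv.start : y_iv.end] = block
    records = {name: arr.tobytes().decode() for name, arr in seqs.items()}
    return records, spec.features()


def write_genome(
    spec: GenomeSpec, outdir: str | Path, prefix: str = "toy"
) -> tuple[Path, Path]:
    """Write the simulated genome as FASTA (+ .fai) and its feature BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, features = simulate_genome(spec)
    fasta = write_fasta(records, outdir / f"{prefix}.fa")
    bed = outdir / f"{prefix}_features.bed"
    write_bed(features, bed)
    return fasta, bed


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _bam_header(records: Mapping[str, str], rg_ids: Sequence[str], sample: str) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in records.items()],
        "RG": [{"ID": rg, "SM": sample} for rg in rg_ids],
    }


def _fragment_feature(
    chrom: str, start: int, end: int, spec: GenomeSpec
) -> GenomicInterval | None:
    """Feature interval fully containing [start, end) on chrom, if any."""
    for iv in spec.features():
        if iv.chrom == chrom and iv.start <= start and end <= iv.end:
            return iv
    return None


def _homolog_map(spec: GenomeSpec) -> dict[tuple[str, str], GenomicInterval]:
    """(feature name, origin chrom) -> homologous interval on the other chrom."""
    out: dict[tuple[str, str], GenomicInterval] = {}
    for x_iv, y_iv in spec.par_blocks:
        out[(x_iv.name, "chrX")] = y_iv
        out[(y_iv.name, "chrY")] = x_iv
    x_iv, y_iv = spec.xtr_block
    out[("XTR", "chrX")] = y_iv
    out[("XTR", "chrY")] = x_iv
    return out


def simulate_alignments(
    records: Mapping[str, str],
    spec: GenomeSpec,
    ploidy: PloidyConfig,
    out_bam: str | Path,
    mapq_model: str = "both_sex_chroms",
    variants: pd.DataFrame | None = None,
    sample: str = "sample",
) -> tuple[Path, pd.DataFrame]:
    """Write a coordinate-sorted, indexed BAM of simulated reads plus truth.

    ``mapq_model`` encodes the reference the reads were notionally mapped to:

    * ``both_sex_chroms`` — PAR-origin fragments are placed on X or Y with
      equal probability at MAPQ 0 (ambiguous homology); XTR-origin fragments
      stay put with depressed MAPQ (30-54); everything else maps uniquely at
      MAPQ 60.
    * ``y_masked`` — the Y chromosome is all N; valid only for complements
      without a Y. Every read maps uniquely at MAPQ 60.
    * ``y_par_masked`` — the Y copies of the PARs are N: PAR fragments from
      either sex chromosome map uniquely to the X PAR at MAPQ 60; XTR
      homology persists, so XTR fragments keep depressed MAPQ.

    ``variants`` (a truth table from :func:`simulate_variants`) plants
    alternate alleles into read sequences: hom-alt sites on every read,
    het sites on each read with probability 0.5.

    The truth table records the origin and placement of every read.
    """
    if mapq_model not in MAPQ_MODELS:
        raise ChromplexError(f"unknown mapq_model {mapq_model!r}")
    copies = ploidy.copy_numbers()
    if mapq_model == "y_masked" and copies.get("chrY", 0) > 0:
        raise ChromplexError(
            "cannot simulate Y-origin reads against a fully Y-masked reference"
        )
    rng = np.random.default_rng(ploidy.seed)
    homolog = _homolog_map(spec)
    rg_ids = [f"rg{i + 1}" for i in range(max(1, ploidy.n_read_groups))]
    read_len = ploidy.read_len

    # variant lookup: chrom -> (sorted pos0 array, alt byte array, is_het array)
    var_idx: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if variants is not None and len(variants):
        for chrom, grp in variants.groupby("chrom"):
            grp = grp.sort_values("pos")
            var_idx[str(chrom)] = (
                grp["pos"].to_numpy() - 1,
                np.frombuffer("".join(grp["alt"]).encode(), dtype="S1").copy(),
                (grp["genotype"] == "het").to_numpy(),
            )

    chrom_arrays = {
        name: np.frombuffer(seq.encode(), dtype="S1") for name, seq in records.items()
    }
    header = _bam_header(records, rg_ids, sample)
    tid = {name: i for i, name in enumerate(records)}

    out_records: list[tuple[int, int, pysam.AlignedSegment]] = []
    truth_rows: list[tuple] = []
    qual = pysam.qualitystring_to_array("I" * read_len)

    def read_seq(chrom: str, start: int) -> str:
        arr = chrom_arrays[chrom][start : start + read_len].copy()
        pos0, alts, is_het = var_idx.get(chrom, (None, None, None))
        if pos0 is not None:
            lo = np.searchsorted(pos0, start)
            hi = np.searchsorted(pos0, start + read_len)
            for j in range(lo, hi):
                if (not is_het[j]) or rng.random() < 0.5:
                    arr[pos0[j] - start] = alts[j]
        n_err = rng.binomial(read_len, ploidy.error_rate)
        if n_err:
            sites = rng.integers(0, read_len, n_err)
            shift = rng.integers(1, 4, n_err)
            arr[sites] = BASES[(np.searchsorted(BASES, arr[sites]) + shift) % 4]
        return arr.tobytes().decode()

    counter = 0
    for chrom, n_copies in copies.items():
        if n_copies == 0:
            continue
        length = len(records[chrom])
        total_bases = n_copies * (ploidy.mean_depth / 2.0) * length
        if ploidy.paired:
            n_frags = int(round(total_bases / (2 * read_len)))
        else:
            n_frags = int(round(total_bases / read_len))
        if n_frags == 0:
            continue
        if ploidy.paired:
            gaps = np.clip(rng.normal(100, 20, n_frags).round().astype(int), 0, None)
            frag_lens = 2 * read_len + gaps
            frag_lens = np.minimum(frag_lens, length)
            starts = rng.integers(0, length - frag_lens + 1)
        else:
            frag_lens = np.full(n_frags, read_len)
            starts = rng.integers(0, length - read_len + 1, n_frags)
        rgs = rng.integers(0, len(rg_ids), n_frags)
        coin = rng.random(n_frags)

        for i in range(n_frags):
            start = int(starts[i])
            flen = int(frag_lens[i])
            feat = _fragment_feature(chrom, start, start + flen, spec)
            feat_name = feat.name if feat else ""
            placed_chrom, offset, mapq = chrom, 0, 60
            if feat_name in ("PAR1", "PAR2"):
                if mapq_model == "both_sex_chroms":
                    mapq = 0
                    if coin[i] < 0.5:  # flip to the homologous chromosome
                        target = homolog[(feat_name, chrom)]
                        placed_chrom = target.chrom
                        offset = target.start - feat.start
                else:  # masked references resolve PARs uniquely onto the X
                    if chrom == "chrY":
                        target = homolog[(feat_name, chrom)]
                        placed_chrom = target.chrom
                        offset = target.start - feat.start
            elif feat_name == "XTR" and mapq_model in ("both_sex_chroms", "y_par_masked"):
                mapq = int(rng.integers(30, 55))
            qname = f"sim{counter:08d}"
            counter += 1
            rg = rg_ids[rgs[i]]
            if ploidy.paired:
                p1 = start
                p2 = start + flen - read_len
                seqs = (read_seq(chrom, p1), read_seq(chrom, p2))
                placed = (p1 + offset, p2 + offset)
                for mate, (ppos, opos, seq) in enumerate(
                    zip(placed, (p1, p2), seqs), start=1
                ):
                    seg = pysam.AlignedSegment()
                    seg.query_name = qname
                    seg.query_sequence = seq
                    seg.flag = (
                        0x1 | 0x2
                        | (0x40 if mate == 1 else 0x80)
                        | (0x10 if mate == 2 else 0)
                        | (0x20 if mate == 1 else 0)
                    )
                    seg.reference_id = tid[placed_chrom]
                    seg.reference_start = ppos
                    seg.mapping_quality = mapq
                    seg.cigartuples = [(0, read_len)]
                    seg.next_reference_id = tid[placed_chrom]
                    seg.next_reference_start = placed[1] if mate == 1 else placed[0]
                    seg.template_length = flen if mate == 1 else -flen
                    seg.query_qualities = qual
                    seg.set_tag("RG", rg)
                    out_records.append((tid[placed_chrom], ppos, seg))
                    truth_rows.append(
                        (qname, mate, chrom, opos, placed_chrom, ppos, mapq, feat_name, rg)
                    )
            else:
                seq = read_seq(chrom, start)
                seg = pysam.AlignedSegment()
                seg.query_name = qname
                seg.query_sequence = seq
                seg.flag = 0
                seg.reference_id = tid[placed_chrom]
                seg.reference_start = start + offset
                seg.mapping_quality = mapq
                seg.cigartuples = [(0, read_len)]
                seg.query_qualities = qual
                seg.set_tag("RG", rg)
                out_records.append((tid[placed_chrom], start + offset, seg))
                truth_rows.append(
                    (qname, 0, chrom, start, placed_chrom, start + offset, mapq, feat_name, rg)
                )

    out_records.sort(key=lambda t: (t[0], t[1]))
    out_bam = Path(out_bam)
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for _, _, seg in out_records:
            bam.write(seg)
    pysam.index(str(out_bam))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "qname", "mate", "origin_chrom", "origin_pos",
            "placed_chrom", "placed_pos", "mapq", "feature", "read_group",
        ],
    )
    return out_bam, truth


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
]


def write_vcf(
    sites: pd.DataFrame,
    contigs: Mapping[str, int],
    path: str | Path,
    sample: str = "sample",
) -> Path:
    """Write a plain-text VCF from a sites table.

    Expected columns: chrom, pos (1-based), ref, alt, qual, mq, genotype
    ("het"/"hom"), gq, depth, alt_count.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        ordered = sites.sort_values(["chrom", "pos"]) if len(sites) else sites
        for row in ordered.itertuples():
            gt = "0/1" if row.genotype == "het" else "1/1"
            ref_count = int(row.depth) - int(row.alt_count)
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:.1f}\t.\tMQ={row.mq:.1f}\t"
                f"GT:GQ:DP:AD\t{gt}:{int(row.gq)}:{int(row.depth)}:"
                f"{ref_count},{int(row.alt_count)}\n"
            )
    return path


def simulate_variants(
    records: Mapping[str, str],
    ploidy: PloidyConfig,
    het_rate: float = 0.001,
    hom_rate: float = 0.0005,
    mean_depth: float | None = None,
    seed: int | None = None,
    out_vcf: str | Path | None = None,
) -> tuple[pd.DataFrame, Path | None]:
    """Truth variant set with binomially sampled allele counts.

    Diploid chromosomes receive heterozygous sites (alt count ~
    Binomial(depth, 0.5)) and hom-alt sites (~ Binomial(depth, 1 - error));
    haploid chromosomes receive hom-alt sites only — the allele-balance
    structure that separates diploid from haploid chromosomes.
    """
    if not (0 <= het_rate <= 1 and 0 <= hom_rate <= 1):
        raise ChromplexError("variant rates must be in [0, 1]")
    rng = np.random.default_rng(ploidy.seed if seed is None else seed)
    copies = ploidy.copy_numbers()
    depth0 = ploidy.mean_depth if mean_depth is None else mean_depth
    rows: list[tuple] = []
    for chrom, n_copies in copies.items():
        if n_copies == 0 or chrom not in records:
            continue
        length = len(records[chrom])
        seq = records[chrom]
        site_depth = depth0 * n_copies / 2.0
        n_het = rng.binomial(length, het_rate) if n_copies >= 2 else 0
        n_hom = rng.binomial(length, hom_rate)
        pos0 = rng.choice(length, size=n_het + n_hom, replace=False)
        kinds = ["het"] * n_het + ["hom"] * n_hom
        for p, kind in zip(pos0, kinds):
            ref = seq[p]
            if ref == "N":
                continue
            alt = str(
                BASES[(np.searchsorted(BASES, ref.encode()) + rng.integers(1, 4)) % 4],
                "ascii",
            )
            depth = max(1, rng.poisson(site_depth))
            p_alt = 0.5 if kind == "het" else 1.0 - ploidy.error_rate
            alt_count = int(rng.binomial(depth, p_alt))
            rows.append((chrom, int(p) + 1, ref, alt, 100.0, 60.0, kind, 99, depth, alt_count))
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "mq", "genotype", "gq", "depth", "alt_count"],
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    vcf_path = None
    if out_vcf is not None:
        contigs = {name: len(seq) for name, seq in records.items()}
        vcf_path = write_vcf(truth, contigs, out_vcf)
    return truth, vcf_path
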