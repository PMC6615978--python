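"""Strip sex-chromosome reads to FASTQ by read group, remap, and merge.

Correcting gametolog mismapping requires remapping: reads currently aligned
to the sex chromosomes are extracted back to FASTQ (per read group, so
library-level information survives), mapped against the appropriate masked
reference, and the fresh sex-chromosome alignments are merged with the
untouched alignments from the rest of the genome.

A read pair is exported whenever either mate maps to a target chromosome
(pair rescue), which keeps the FASTQs valid for paired remapping. Mates are
restored to their original sequenced orientation (reverse-complemented back)
and emitted in matched order; a mate whose partner record is missing goes to
a singles file.

Remapping runs through user-editable command templates (any aligner/sorter),
or through the built-in deterministic seed-and-verify "toy aligner" so tests
and desk-scale runs need no external binaries. Merging partitions by
chromosome: non-target records come byte-for-byte from the original BAM,
target-chromosome records come only from the remapped BAM and carry a
provenance tag.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from ._util import ChromplexError, logger, revcomp
from .refmask import read_fasta

#: SAM tag marking reads that went through remapping
REMAP_TAG = "XR"

TOY_SEED_LEN = 20
TOY_MAX_MISMATCH_FRAC = 0.1


@dataclass
class ReadGroupBundle:
    """Paired (or single-end) FASTQs for one read group, plus a singles file."""

    read_group_id: str
    fastq_1: Path
    fastq_2: Path | None
    singles: Path | None
    n_pairs: int
    n_singles: int = 0


# ---------------------------------------------------------------------------
# STRIP_READS
# ---------------------------------------------------------------------------

def _fastq_record(read: pysam.AlignedSegment) -> str:
    """FASTQ entry in original sequenced orientation."""
    seq = read.query_sequence or ""
    qual = "".join(chr(q + 33) for q in (read.query_qualities or []))
    if read.is_reverse:
        seq = revcomp(seq)
        qual = qual[::-1]
    return f"@{read.query_name}\n{seq}\n+\n{qual}\n"


def strip_reads(
    bam: str | Path,
    target_chroms: Sequence[str],
    outdir: str | Path,
    paired: bool = True,
) -> list[ReadGroupBundle]:
    """Export reads touching the target chromosomes to per-read-group FASTQs.

    A pair is exported when either mate's primary alignment is on a target
    chromosome; both mates are written exactly once, in matched order across
    fastq_1/fastq_2. Reads without an RG tag fall into a synthetic group
    named "default". Orphaned mates go to a singles FASTQ with a warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with pysam.AlignmentFile(str(bam)) as af:
        missing = [c for c in target_chroms if c not in af.references]
        if missing:
            raise ChromplexError(f"target chromosome(s) not in BAM: {', '.join(missing)}")
        wanted: set[str] = set()
        for chrom in target_chroms:
            for read in af.fetch(chrom):
                if read.is_secondary or read.is_supplementary:
                    continue
                wanted.add(read.query_name)
    # second pass over the whole file (incl. unmapped) collects both mates
    records: dict[str, dict[int, pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(bam)) as af:
        for read in af.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if read.query_name not in wanted:
                continue
            mate = 2 if read.is_read2 else 1
            records.setdefault(read.query_name, {})[mate] = read

    by_rg: dict[str, list[tuple[str, dict[int, pysam.AlignedSegment]]]] = {}
    for qname in sorted(records):
        mates = records[qname]
        any_read = next(iter(mates.values()))
        rg = any_read.get_tag("RG") if any_read.has_tag("RG") else "default"
        by_rg.setdefault(str(rg), []).append((qname, mates))

    bundles: list[ReadGroupBundle] = []
    for rg in sorted(by_rg):
        fq1 = outdir / f"{rg}_1.fastq"
        fq2 = outdir / f"{rg}_2.fastq" if paired else None
        singles = outdir / f"{rg}_singles.fastq"
        n_pairs = n_singles = 0
        h1 = open(fq1, "w")
        h2 = open(fq2, "w") if fq2 else None
        hs = open(singles, "w")
        try:
            for qname, mates in by_rg[rg]:
                if paired and 1 in mates and 2 in mates:
                    h1.write(_fastq_record(mates[1]))
                    h2.write(_fastq_record(mates[2]))
                    n_pairs += 1
                elif not paired:
                    for read in mates.values():
                        h1.write(_fastq_record(read))
                        n_pairs += 1
                else:
                    logger.warning("orphaned mate for %s; writing to singles", qname)
                    for read in mates.values():
                        hs.write(_fastq_record(read))
                        n_singles += 1
        finally:
            h1.close()
            if h2:
                h2.close()
            hs.close()
        bundles.append(
            ReadGroupBundle(
                read_group_id=rg,
                fastq_1=fq1,
                fastq_2=fq2,
                singles=singles if n_singles else None,
                n_pairs=n_pairs,
                n_singles=n_singles,
            )
        )
        if not n_singles:
            singles.unlink(missing_ok=True)
    return bundles


# ---------------------------------------------------------------------------
# Toy aligner: deterministic seed-and-verify exact placement
# ---------------------------------------------------------------------------

def _build_seed_index(records: Mapping[str, str], k: int = TOY_SEED_LEN) -> dict[bytes, list[tuple[int, int]]]:
    """k-mer -> [(tid, pos)] over the reference; k-mers containing N skipped."""
    index: dict[bytes, list[tuple[int, int]]] = {}
    for tid, (name, seq) in enumerate(records.items()):
        raw = seq.encode()
        for pos in range(0, len(raw) - k + 1):
            kmer = raw[pos : pos + k]
            if b"N" in kmer:
                continue
            index.setdefault(kmer, []).append((tid, pos))
    return index


def _read_fastq(path: Path) -> list[tuple[str, str, str]]:
    out = []
    with open(path) as fh:
        while True:
            name = fh.readline().rstrip()
            if not name:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            out.append((name[1:], seq, qual))
    return out


def _toy_align_one(
    seq: str,
    index: dict[bytes, list[tuple[int, int]]],
    chrom_arrays: list[np.ndarray],
    k: int = TOY_SEED_LEN,
) -> tuple[int, int, bool, int] | None:
    """Best placement of seq: (tid, pos, is_reverse, mapq) or None (unmapped).

    Seeds at the read's start, middle, and end are looked up exactly; each
    candidate is verified by full-length Hamming distance. Unique best hit
    gets MAPQ 60; tied best hits get MAPQ 0 at the lowest coordinate.
    """
    read_len = len(seq)
    if read_len < k:
        return None
    max_mm = int(read_len * TOY_MAX_MISMATCH_FRAC)
    best_mm = max_mm + 1
    best_hits: set[tuple[int, int, bool]] = set()
    for strand_seq, is_rev in ((seq, False), (revcomp(seq), True)):
        arr = np.frombuffer(strand_seq.encode(), dtype="S1")
        raw = strand_seq.encode()
        candidates: set[int] = set()
        seen: set[tuple[int, int]] = set()
        for off in (0, read_len // 2 - k // 2, read_len - k):
            for tid, pos in index.get(raw[off : off + k], ()):
                start = pos - off
                if start < 0 or start + read_len > len(chrom_arrays[tid]):
                    continue
                if (tid, start) in seen:
                    continue
                seen.add((tid, start))
                mm = int((chrom_arrays[tid][start : start + read_len] != arr).sum())
                if mm < best_mm:
                    best_mm = mm
                    best_hits = {(tid, start, is_rev)}
                elif mm == best_mm:
                    best_hits.add((tid, start, is_rev))
    if not best_hits or best_mm > max_mm:
        return None
    if len(best_hits) == 1:
        tid, pos, is_rev = next(iter(best_hits))
        return tid, pos, is_rev, 60
    tid, pos, is_rev = min(best_hits)
    return tid, pos, is_rev, 0


def toy_align(
    bundles: Sequence[ReadGroupBundle],
    reference: str | Path,
    out_bam: str | Path,
    sample: str = "sample",
) -> Path:
    """Map bundle FASTQs to the reference with the built-in toy aligner.

    Produces a coordinate-sorted, indexed BAM whose header lists every read
    group. Reads that fail seed lookup or exceed the mismatch budget are
    dropped (the toy aligner emits mapped records only).
    """
    records = read_fasta(reference)
    index = _build_seed_index(records)
    chrom_arrays = [np.frombuffer(seq.encode(), dtype="S1") for seq in records.values()]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in records.items()],
        "RG": [{"ID": b.read_group_id, "SM": sample} for b in bundles],
    }
    out: list[tuple[int, int, pysam.AlignedSegment]] = []

    def emit(name, seq, qual, rg, placement, mate_flag, mate_placement):
        if placement is None:
            return
        tid, pos, is_rev, mapq = placement
        seg = pysam.AlignedSegment()
        seg.query_name = name.split("/")[0].split()[0]
        stored_seq = revcomp(seq) if is_rev else seq
        stored_qual = qual[::-1] if is_rev else qual
        seg.query_sequence = stored_seq
        flag = mate_flag | (0x10 if is_rev else 0)
        if mate_placement is not None:
            mtid, mpos, m_rev, _ = mate_placement
            flag |= 0x1 | (0x20 if m_rev else 0)
            if mtid == tid:
                flag |= 0x2
            seg.next_reference_id = mtid
            seg.next_reference_start = mpos
        elif mate_flag:
            flag |= 0x1 | 0x8
        seg.flag = flag
        seg.reference_id = tid
        seg.reference_start = pos
        seg.mapping_quality = mapq
        seg.cigartuples = [(0, len(seq))]
        seg.query_qualities = pysam.qualitystring_to_array(stored_qual)
        seg.set_tag("RG", rg)
        out.append((tid, pos, seg))

    for bundle in bundles:
        rg = bundle.read_group_id
        if bundle.fastq_2 is not None:
            r1 = _read_fastq(bundle.fastq_1)
            r2 = _read_fastq(bundle.fastq_2)
            for (n1, s1, q1), (n2, s2, q2) in zip(r1, r2):
                p1 = _toy_align_one(s1, index, chrom_arrays)
                p2 = _toy_align_one(s2, index, chrom_arrays)
                emit(n1, s1, q1, rg, p1, 0x40, p2)
                emit(n2, s2, q2, rg, p2, 0x80, p1)
        else:
            for name, seq, qual in _read_fastq(bundle.fastq_1):
                emit(name, seq, qual, rg, _toy_align_one(seq, index, chrom_arrays), 0, None)
        if bundle.singles is not None:
            for name, seq, qual in _read_fastq(bundle.singles):
                emit(name, seq, qual, rg, _toy_align_one(seq, index, chrom_arrays), 0, None)

    out.sort(key=lambda t: (t[0], t[1]))
    out_bam = Path(out_bam)
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for _, _, seg in out:
            bam.write(seg)
    pysam.index(str(out_bam))
    return out_bam


# ---------------------------------------------------------------------------
# REMAPPING
# ---------------------------------------------------------------------------

def remap_external(
    bundles: Sequence[ReadGroupBundle],
    reference: str | Path,
    out_bam: str | Path,
    aligner_cmd_template: str | None = None,
    sort_cmd_template: str | None = None,
    sample: str = "sample",
) -> Path:
    """Map each bundle and merge into one coordinate-sorted BAM.

    With templates, each non-empty bundle runs
    ``aligner_cmd_template.format(ref=..., fq1=..., fq2=..., out=..., rg=...)``
    (the template is responsible for emitting a sorted BAM, or supply
    ``sort_cmd_template`` with {inp} and {out}); per-group BAMs are then
    merged with original read-group headers preserved. Without templates the
    built-in toy aligner handles all bundles in one pass.
    """
    live = [b for b in bundles if b.n_pairs > 0 or b.n_singles > 0]
    for b in bundles:
        if b not in live:
            logger.warning("read group %s has no reads; skipped", b.read_group_id)
    if not live:
        raise ChromplexError("no reads to remap in any bundle")
    if aligner_cmd_template is None:
        return toy_align(live, reference, out_bam, sample=sample)

    for ph in ("{ref}", "{fq1}", "{out}"):
        if ph not in aligner_cmd_template:
            raise ChromplexError(f"aligner template missing placeholder {ph}")
    tmpdir = Path(out_bam).parent
    group_bams: list[Path] = []
    for b in live:
        raw = tmpdir / f"remap_{b.read_group_id}.bam"
        cmd = aligner_cmd_template.format(
            ref=reference, fq1=b.fastq_1, fq2=b.fastq_2 or "", out=raw, rg=b.read_group_id
        )
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise ChromplexError(f"aligner failed (exit {proc.returncode}):\n{proc.stderr}")
        if sort_cmd_template is not None:
            sorted_bam = tmpdir / f"remap_{b.read_group_id}.sorted.bam"
            cmd = sort_cmd_template.format(inp=raw, out=sorted_bam)
            proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
            if proc.returncode != 0:
                raise ChromplexError(f"sort failed (exit {proc.returncode}):\n{proc.stderr}")
            raw = sorted_bam
        group_bams.append(raw)
    if len(group_bams) == 1:
        Path(group_bams[0]).replace(out_bam)
    else:
        pysam.merge("-f", str(out_bam), *[str(p) for p in group_bams])
    pysam.index(str(out_bam))
    return Path(out_bam)


def merge_with_nonsex(
    original_bam: str | Path,
    remapped_bam: str | Path,
    target_chroms: Sequence[str],
    out_bam: str | Path,
) -> Path:
    """Combine untouched non-target alignments with remapped target alignments.

    Non-target chromosome records are copied verbatim from the original BAM;
    target-chromosome records come only from the remapped BAM and are marked
    with the provenance tag. The two inputs must share a sequence dictionary.
    The output is coordinate-sorted and indexed.
    """
    with pysam.AlignmentFile(str(original_bam)) as orig, \
         pysam.AlignmentFile(str(remapped_bam)) as rem:
        dict_o = list(zip(orig.references, orig.lengths))
        dict_r = list(zip(rem.references, rem.lengths))
        if dict_o != dict_r:
            raise ChromplexError(
                "sequence dictionaries differ between original and remapped BAM"
            )
        targets = set(target_chroms)
        header = orig.header.to_dict()
        # carry remapped RG entries not already present
        seen_rgs = {rg["ID"] for rg in header.get("RG", [])}
        for rg in rem.header.to_dict().get("RG", []):
            if rg["ID"] not in seen_rgs:
                header.setdefault("RG", []).append(rg)
        out: list[tuple[int, int, pysam.AlignedSegment]] = []
        for read in orig.fetch(until_eof=True):
            if read.reference_name in targets:
                continue
            out.append((read.reference_id if read.reference_id >= 0 else 1 << 30,
                        read.reference_start if read.reference_start >= 0 else 0, read))
        for read in rem.fetch(until_eof=True):
            if read.reference_name not in targets:
                continue
            read.set_tag(REMAP_TAG, "remapped")
            out.append((read.reference_id, read.reference_start, read))
        out.sort(key=lambda t: (t[0], t[1]))
        out_bam = Path(out_bam)
        with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
            for _, _, read in out:
                bam.write(read)
    pysam.index(str(out_bam))
    return out_bam
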