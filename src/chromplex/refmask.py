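"""Build sex-specific reference genomes by hard-masking.

Homologous (gametologous) sequence shared between the X and Y chromosomes —
most prominently the pseudoautosomal regions (PARs), which are identical —
causes short reads to map ambiguously when both sex chromosomes are present
in the reference. The fix applied here is hard masking: for a homogametic
(e.g., XX) individual the entire Y chromosome is replaced with Ns, and for a
heterogametic (e.g., XY) individual the Y copies of the PARs are replaced
with Ns so PAR reads map uniquely to the X. Masking (rather than dropping
contigs) keeps the two reference versions on the same sequence dictionary,
so BAMs and VCFs produced against either can be processed jointly.

All masking is uppercase 'N', lengths are conserved, and BED coordinates are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pysam

from ._util import ChromplexError, GenomicInterval, logger, merge_intervals, read_bed

FASTA_LINE_WIDTH = 60


@dataclass(frozen=True)
class SequenceDictionary:
    """Ordered (name, length) entries of a FASTA, i.e., its sequence dictionary."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ChromplexError("duplicate chromosome names in sequence dictionary")
        if any(length <= 0 for _, length in self.entries):
            raise ChromplexError("non-positive chromosome length in sequence dictionary")

    @classmethod
    def from_records(cls, records: Mapping[str, str]) -> "SequenceDictionary":
        return cls(tuple((name, len(seq)) for name, seq in records.items()))

    def lengths(self) -> dict[str, int]:
        return dict(self.entries)


@dataclass
class ReferencePair:
    """Paths to the two masked reference versions plus what was masked."""

    homogametic_path: Path
    heterogametic_path: Path
    masked_chroms: list[str] = field(default_factory=list)
    masked_regions: list[GenomicInterval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA I/O (records are plain dicts name -> sequence string)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise ChromplexError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, index: bool = True) -> Path:
    """Write records in input order at fixed 60-column width; emit .fai."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_LINE_WIDTH):
                fh.write(seq[i : i + FASTA_LINE_WIDTH] + "\n")
    if index:
        pysam.faidx(str(path))
    return path


# ---------------------------------------------------------------------------
# Masking operations
# ---------------------------------------------------------------------------

def mask_chromosomes(records: Mapping[str, str], names: Sequence[str]) -> dict[str, str]:
    """Replace every base of each named chromosome with 'N'.

    Record order and lengths are preserved; unnamed records are returned
    unchanged (same string objects).
    """
    missing = [n for n in names if n not in records]
    if missing:
        raise ChromplexError(f"chromosome(s) not in reference: {', '.join(missing)}")
    wanted = set(names)
    return {
        name: ("N" * len(seq) if name in wanted else seq)
        for name, seq in records.items()
    }


def mask_regions(
    records: Mapping[str, str], regions: Sequence[GenomicInterval]
) -> dict[str, str]:
    """Replace bases in the union of the given intervals with 'N'."""
    for iv in regions:
        if iv.chrom not in records:
            raise ChromplexError(f"mask interval on unknown chromosome {iv.chrom!r}")
        if iv.end > len(records[iv.chrom]):
            raise ChromplexError(
                f"mask interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {len(records[iv.chrom])}"
            )
    out = dict(records)
    for iv in merge_intervals(regions):
        seq = out[iv.chrom]
        out[iv.chrom] = seq[: iv.start] + "N" * (iv.end - iv.start) + seq[iv.end :]
    return out


def prepare_reference_pair(
    reference: str | Path,
    heterogametic_only_chroms: Sequence[str],
    shared_region_mask: str | Path | Sequence[GenomicInterval] | None = None,
    extra_masks: Sequence[str | Path] | None = None,
    out_prefix: str | Path = "ref_",
) -> ReferencePair:
    """Produce the homogametic (e.g., XX) and heterogametic (e.g., XY) references.

    Homogametic version: heterogametic-only chromosomes (e.g., chrY) fully
    masked. Heterogametic version: the shared-region mask (e.g., Y copies of
    the PARs) applied. Extra mask BEDs are applied to both. Both outputs are
    written FASTA + .fai and share the input's sequence dictionary.
    """
    records = read_fasta(reference)
    if not heterogametic_only_chroms:
        logger.warning(
            "no heterogametic-only chromosomes given; the two reference "
            "versions will differ only by shared/extra masks"
        )

    shared: list[GenomicInterval] = []
    if shared_region_mask is not None:
        if isinstance(shared_region_mask, (str, Path)):
            shared = read_bed(shared_region_mask)
        else:
            shared = list(shared_region_mask)

    extra: list[GenomicInterval] = []
    for bed in extra_masks or []:
        extra.extend(read_bed(bed))

    homogametic = mask_chromosomes(records, heterogametic_only_chroms)
    if extra:
        homogametic = mask_regions(homogametic, extra)
    heterogametic = mask_regions(records, shared + extra) if (shared or extra) else dict(records)

    out_prefix = str(out_prefix)
    homo_path = write_fasta(homogametic, out_prefix + "homogametic.fa")
    hetero_path = write_fasta(heterogametic, out_prefix + "heterogametic.fa")

    ok, report = verify_dictionaries(homo_path, hetero_path)
    if not ok:  # pragma: no cover - masking conserves lengths by construction
        raise ChromplexError(f"masked references disagree on dictionary:\n{report}")
    return ReferencePair(
        homogametic_path=homo_path,
        heterogametic_path=hetero_path,
        masked_chroms=list(heterogametic_only_chroms),
        masked_regions=shared + extra,
    )


def verify_dictionaries(a: str | Path, b: str | Path) -> tuple[bool, str]:
    """True iff both FASTAs have identical (name, length) entries in order."""
    try:
        dict_a = SequenceDictionary.from_records(read_fasta(a)).entries
        dict_b = SequenceDictionary.from_records(read_fasta(b)).entries
    except OSError as exc:
        raise ChromplexError(f"cannot read FASTA: {exc}") from exc
    if dict_a == dict_b:
        return True, "identical"
    lines = []
    names_a = [n for n, _ in dict_a]
    names_b = [n for n, _ in dict_b]
    for name in dict.fromkeys(names_a + names_b):
        la = dict(dict_a).get(name)
        lb = dict(dict_b).get(name)
        if la != lb:
            lines.append(f"{name}: {la} vs {lb}")
    if names_a != names_b and not lines:
        lines.append(f"record order differs: {names_a} vs {names_b}")
    elif names_a != names_b:
        lines.append(f"record order: {names_a} vs {names_b}")
    return False, "\n".join(lines)
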