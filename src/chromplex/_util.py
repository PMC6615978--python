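"""Shared plumbing: genomic intervals, minimal BED I/O, logging, provenance headers.

BED files handled here are plain 3/4-column text (chrom, start, end[, name]),
0-based half-open. VCF positions elsewhere in the package are 1-based per the
VCF convention; conversion happens at module boundaries, never silently.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"

logger = logging.getLogger("chromplex")


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Configure package logging to stderr and optionally to a file."""
    root = logging.getLogger("chromplex")
    root.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(LOG_FORMAT))
        root.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(str(logfile))
        fh.setFormatter(logging.Formatter(LOG_FORMAT))
        root.addHandler(fh)


class ChromplexError(RuntimeError):
    """Fatal, user-facing error (bad inputs, missing files, broken invariants)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open region on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ChromplexError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED4 file into intervals (extra columns ignored)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ChromplexError(f"{path}:{lineno}: BED line has <3 columns")
            name = fields[3] if len(fields) > 3 else ""
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome, sorted, overlaps coalesced."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def config_hash(obj: object) -> str:
    """Short stable hash of a configuration repr, for provenance headers."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def provenance_header(seed: int | None, cfg_hash: str | None = None) -> str:
    from chromplex import __version__

    parts = [f"# chromplex v{__version__}"]
    if cfg_hash is not None:
        parts.append(f"config_hash={cfg_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "\t".join(parts) + "\n"
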