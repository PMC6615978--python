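"""Windowed depth/MAPQ traversal of BAMs and per-chromosome summaries.

Depth in a window is approximated as the total length of all primary-alignment
reads assigned to the window divided by the window length. A read is assigned
to exactly one window — the one containing its leftmost aligned position — so
reads are conserved across windows (sum of per-window read counts equals the
chromosome's primary read count). The approximation equals exact per-base
depth whenever every read lies entirely within one window, and converges to
it as windows grow.

Window filtering partitions windows into pass/fail BED sets on inclusive
thresholds: mean MAPQ >= min_mapq and depth within [low*mu, high*mu] where mu
is the chromosome's mean window depth. Empty windows always fail.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from ._util import ChromplexError, GenomicInterval, logger, write_bed

#: documented defaults; the strict preset raises min_mapq to 55, which is the
#: threshold needed to eliminate partial-homology (XTR-like) windows
DEFAULT_WINDOW_SIZE = 5_000
DEFAULT_MIN_MAPQ = 30.0
DEFAULT_DEPTH_BOUNDS = (0.25, 4.0)
STRICT_MIN_MAPQ = 55.0

WINDOW_COLUMNS = ["chrom", "start", "end", "approx_depth", "mean_mapq", "n_primary", "empty"]


def _is_primary(read: pysam.AlignedSegment, exclude_duplicates: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if exclude_duplicates and read.is_duplicate:
        return False
    return True


def approx_window_depth(reads: Sequence, window: GenomicInterval, cigar_span: bool = False) -> float:
    """Total read length over window length for the given assigned reads."""
    if len(window) <= 0:  # pragma: no cover - GenomicInterval enforces this
        raise ChromplexError("zero-length window")
    total = 0
    for read in reads:
        if not _is_primary(read, exclude_duplicates=False):
            continue
        total += (read.reference_length if cigar_span else read.query_length) or 0
    return total / len(window)


def window_mean_mapq(reads: Sequence) -> tuple[float, bool]:
    """Arithmetic mean MAPQ over primary reads; (0.0, empty=True) when none."""
    mapqs = [r.mapping_quality for r in reads if _is_primary(r, False)]
    if not mapqs:
        return 0.0, True
    return float(np.mean(mapqs)), False


def traverse(
    bam: str | Path,
    chrom: str,
    window_size: int = DEFAULT_WINDOW_SIZE,
    exclude_duplicates: bool = False,
    cigar_span: bool = False,
) -> pd.DataFrame:
    """Tile a chromosome with consecutive windows and summarise primary reads.

    The final window is truncated at the chromosome end. Each primary read is
    assigned to the single window containing its leftmost aligned position.
    Returns a table with columns chrom, start, end, approx_depth, mean_mapq,
    n_primary, empty.
    """
    if window_size <= 0:
        raise ChromplexError("window_size must be > 0")
    bam = Path(bam)
    if not (Path(str(bam) + ".bai").exists() or Path(str(bam) + ".csi").exists()):
        raise ChromplexError(f"BAM index not found for {bam}")
    with pysam.AlignmentFile(str(bam)) as af:
        if chrom not in af.references:
            raise ChromplexError(f"chromosome {chrom!r} not in BAM header of {bam}")
        chrom_len = af.get_reference_length(chrom)
        n_windows = -(-chrom_len // window_size)
        length_sum = np.zeros(n_windows, dtype=np.int64)
        mapq_sum = np.zeros(n_windows, dtype=np.float64)
        counts = np.zeros(n_windows, dtype=np.int64)
        for read in af.fetch(chrom):
            if not _is_primary(read, exclude_duplicates):
                continue
            w = read.reference_start // window_size
            length_sum[w] += (read.reference_length if cigar_span else read.query_length) or 0
            mapq_sum[w] += read.mapping_quality
            counts[w] += 1

    starts = np.arange(n_windows) * window_size
    ends = np.minimum(starts + window_size, chrom_len)
    window_lens = ends - starts
    with np.errstate(invalid="ignore"):
        depth = length_sum / window_lens
        mean_mapq = np.where(counts > 0, mapq_sum / np.maximum(counts, 1), 0.0)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "approx_depth": depth,
            "mean_mapq": mean_mapq,
            "n_primary": counts,
            "empty": counts == 0,
        }
    )


def filter_windows(
    windows: pd.DataFrame,
    min_mapq: float = DEFAULT_MIN_MAPQ,
    depth_bounds: tuple[float, float] = DEFAULT_DEPTH_BOUNDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition windows into (pass, fail) on MAPQ and relative-depth bounds.

    Depth bounds are multiples of the per-chromosome mean window depth.
    Thresholds are inclusive; empty windows fail unconditionally.
    """
    low, high = depth_bounds
    if low > high:
        raise ChromplexError(f"depth bounds low > high: {depth_bounds}")
    if not len(windows):
        return windows.copy(), windows.copy()
    mu = windows.groupby("chrom")["approx_depth"].transform("mean")
    ok = (
        (windows["mean_mapq"] >= min_mapq)
        & (windows["approx_depth"] >= low * mu)
        & (windows["approx_depth"] <= high * mu)
        & (~windows["empty"])
    )
    return windows[ok].reset_index(drop=True), windows[~ok].reset_index(drop=True)


def windows_to_bed(windows: pd.DataFrame, path: str | Path) -> Path:
    write_bed(
        (GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in windows.itertuples()),
        path,
    )
    return Path(path)


def chrom_stats(
    bams: Sequence[str | Path],
    chroms: Sequence[str],
    exclude_duplicates: bool = False,
) -> pd.DataFrame:
    """One row per (sample, chromosome): primary read count, mean MAPQ, depth.

    The chromosome is treated as a single window for the depth approximation.
    A chromosome missing from a BAM header yields a zero row with a warning,
    so multi-sample tables stay rectangular.
    """
    rows = []
    for bam in bams:
        sample_id = Path(bam).stem
        with pysam.AlignmentFile(str(bam)) as af:
            for chrom in chroms:
                if chrom not in af.references:
                    logger.warning("chromosome %s missing from %s; zero row", chrom, bam)
                    rows.append((sample_id, chrom, 0, 0.0, 0.0))
                    continue
                chrom_len = af.get_reference_length(chrom)
                n = 0
                mapq_sum = 0.0
                length_sum = 0
                for read in af.fetch(chrom):
                    if not _is_primary(read, exclude_duplicates):
                        continue
                    n += 1
                    mapq_sum += read.mapping_quality
                    length_sum += read.query_length or 0
                rows.append(
                    (
                        sample_id,
                        chrom,
                        n,
                        mapq_sum / n if n else 0.0,
                        length_sum / chrom_len,
                    )
                )
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "n_reads", "mean_mapq", "mean_depth"])


def normalize_to_chrom(stats: pd.DataFrame, denominator: str) -> pd.DataFrame:
    """Divide each sample's metrics by its value on the denominator chromosome.

    A zero denominator yields NaN (undefined), never a division error.
    """
    out = stats.copy()
    for col, rel in (
        ("mean_depth", "rel_depth"),
        ("mean_mapq", "rel_mapq"),
        ("n_reads", "rel_reads"),
    ):
        out[rel] = np.nan
    for sample_id, grp in stats.groupby("sample_id"):
        denom_rows = grp[grp["chrom"] == denominator]
        if denom_rows.empty:
            raise ChromplexError(
                f"denominator chromosome {denominator!r} absent for sample {sample_id}"
            )
        denom = denom_rows.iloc[0]
        for col, rel in (
            ("mean_depth", "rel_depth"),
            ("mean_mapq", "rel_mapq"),
            ("n_reads", "rel_reads"),
        ):
            d = denom[col]
            if d == 0:
                logger.warning(
                    "denominator %s is 0 for sample %s (%s); relative values undefined",
                    col, sample_id, denominator,
                )
                continue
            out.loc[grp.index, rel] = grp[col] / d
    return out


def plot_window_metrics(windows: pd.DataFrame, out_png: str | Path, title: str = "") -> Path:
    """Scatter plots of per-window depth and MAPQ along the chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    mid = (windows["start"] + windows["end"]) / 2
    ax1.scatter(mid, windows["approx_depth"], s=4)
    ax1.set_ylabel("approx. depth")
    ax2.scatter(mid, windows["mean_mapq"], s=4, color="darkorange")
    ax2.set_ylabel("mean MAPQ")
    ax2.set_xlabel("position (bp)")
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(out_png, dpi=100)
    plt.close(fig)
    return Path(out_png)
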