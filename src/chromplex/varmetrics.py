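"""Variant filtering, allele read balance, and region-level variant counting.

Read balance at a site is the number of reads supporting the alternate
(non-reference) allele divided by the total reads supporting either allele.
Across a diploid chromosome its distribution peaks near 0.5 (heterozygotes)
and 1.0 (hom-alt); a haploid chromosome shows a single peak near 1.0 because
true heterozygous sites cannot exist. The "heterozygous view" histogram keeps
balances strictly between 0.05 and 1.0 to highlight the heterozygous mass.

Region-unique variant counting compares two call sets (e.g., before vs after
sex-specific masking) by the identity key (chrom, pos, ref, alt) and reports
counts and per-megabase rates for named regions.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from ._util import ChromplexError, GenomicInterval, logger, read_bed

#: documented default thresholds; site QUAL and MQ cutoffs of 30 follow the
#: convention of removing variants with MQ or QUAL < 30
DEFAULT_MIN_SITE_QUAL = 30.0
DEFAULT_MIN_GQ = 30.0
DEFAULT_MIN_DEPTH = 8
DEFAULT_MIN_MQ = 30.0

#: heterozygous-view histogram bounds, strict on both sides
HET_VIEW_LOW = 0.05
HET_VIEW_HIGH = 1.0


@dataclass
class VariantSite:
    """A filtered biallelic site with allele read counts (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    site_qual: float
    mapq_annotation: float | None
    genotype_qual: float | None
    depth: int
    ref_count: int
    alt_count: int

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class RegionVariantReport:
    """Counts of variants unique to each of two call sets within a region."""

    name: str
    length: int
    unique_to_a: int
    unique_to_b: int

    @property
    def rate_a(self) -> float:
        return per_mb_rate(self.unique_to_a, self.length)

    @property
    def rate_b(self) -> float:
        return per_mb_rate(self.unique_to_b, self.length)


# ---------------------------------------------------------------------------
# VCF parsing
# ---------------------------------------------------------------------------

def load_variants(vcf: str | Path, sample: str | int = 0) -> list[VariantSite]:
    """Parse a VCF (plain or bgzipped) into VariantSite records.

    Multi-allelic records are restricted to the alt allele with the highest
    allelic depth; allele counts come from the AD FORMAT field when present.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(vcf)) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            smp = rec.samples[sample] if rec.samples else None
            ad = smp.get("AD") if smp is not None else None
            if ad is not None and len(ad) >= 2 and ad[0] is not None:
                alt_idx = int(np.argmax([a or 0 for a in ad[1:]]))
                ref_count = int(ad[0])
                alt_count = int(ad[alt_idx + 1] or 0)
            else:
                alt_idx, ref_count, alt_count = 0, 0, 0
            dp = smp.get("DP") if smp is not None else None
            gq = smp.get("GQ") if smp is not None else None
            mq = rec.info.get("MQ") if "MQ" in rec.info else None
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[alt_idx],
                    site_qual=float(rec.qual) if rec.qual is not None else 0.0,
                    mapq_annotation=float(mq) if mq is not None else None,
                    genotype_qual=float(gq) if gq is not None else None,
                    depth=int(dp) if dp is not None else ref_count + alt_count,
                    ref_count=ref_count,
                    alt_count=alt_count,
                )
            )
    return sites


def filter_variants(
    sites: Iterable[VariantSite],
    min_site_qual: float = DEFAULT_MIN_SITE_QUAL,
    min_genotype_qual: float = DEFAULT_MIN_GQ,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_mq: float = DEFAULT_MIN_MQ,
) -> list[VariantSite]:
    """Keep sites passing all thresholds (inclusive), preserving order.

    A missing MQ annotation passes the MQ filter with a warning (caller may
    not emit it); a missing GQ fails, conservatively.
    """
    out: list[VariantSite] = []
    warned_mq = False
    for s in sites:
        if s.site_qual < min_site_qual or s.depth < min_depth:
            continue
        if s.genotype_qual is None or s.genotype_qual < min_genotype_qual:
            continue
        if s.mapq_annotation is None:
            if not warned_mq:
                logger.warning("sites without MQ annotation pass the MQ filter")
                warned_mq = True
        elif s.mapq_annotation < min_mq:
            continue
        out.append(s)
    return out


def read_balance(ref_count: int, alt_count: int) -> float:
    """alt / (ref + alt); callers should skip zero-total sites."""
    total = ref_count + alt_count
    if total <= 0:
        raise ChromplexError("read balance undefined when ref_count + alt_count == 0")
    return alt_count / total


def site_balances(sites: Iterable[VariantSite]) -> np.ndarray:
    """Read balances for all sites with at least one allele-supporting read."""
    vals = []
    for s in sites:
        if s.ref_count + s.alt_count == 0:
            logger.warning("skipping %s:%d — no allele-supporting reads", s.chrom, s.pos)
            continue
        vals.append(read_balance(s.ref_count, s.alt_count))
    return np.asarray(vals, dtype=float)


def balance_histogram(
    balances: Sequence[float] | np.ndarray,
    heterozygous_view: bool = False,
    n_bins: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of read balances over [0, 1]; returns (bin_edges, counts).

    The heterozygous view keeps only balances strictly between 0.05 and 1.0,
    hiding the fixed-site mass at the extremes.
    """
    vals = np.asarray(balances, dtype=float)
    if len(vals) and (vals.min() < 0 or vals.max() > 1):
        raise ChromplexError("read balances must lie in [0, 1]")
    if heterozygous_view:
        vals = vals[(vals > HET_VIEW_LOW) & (vals < HET_VIEW_HIGH)]
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return edges, counts


def window_variant_summary(
    sites: Sequence[VariantSite],
    window_size: int,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Per-window variant count and mean read balance for one chromosome.

    Windows tile the chromosome as in BAM traversal; VCF positions are
    1-based, so window index = (pos - 1) // window_size. Empty windows report
    count 0 and NaN balance.
    """
    if window_size <= 0:
        raise ChromplexError("window_size must be > 0")
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise ChromplexError(f"sites span multiple chromosomes: {sorted(chroms)}")
    max_pos = max((s.pos for s in sites), default=0)
    length = chrom_length if chrom_length is not None else max_pos
    n_windows = max(1, -(-length // window_size))
    counts = np.zeros(n_windows, dtype=int)
    bal_sum = np.zeros(n_windows, dtype=float)
    bal_n = np.zeros(n_windows, dtype=int)
    for s in sites:
        w = (s.pos - 1) // window_size
        if w >= n_windows:
            raise ChromplexError(f"site {s.chrom}:{s.pos} beyond chromosome length {length}")
        counts[w] += 1
        if s.ref_count + s.alt_count > 0:
            bal_sum[w] += read_balance(s.ref_count, s.alt_count)
            bal_n[w] += 1
    starts = np.arange(n_windows) * window_size
    ends = np.minimum(starts + window_size, length) if chrom_length else starts + window_size
    with np.errstate(invalid="ignore"):
        mean_balance = np.where(bal_n > 0, bal_sum / np.maximum(bal_n, 1), np.nan)
    chrom = sites[0].chrom if sites else ""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "n_variants": counts,
            "mean_balance": mean_balance,
        }
    )


# ---------------------------------------------------------------------------
# Region-unique variant counting
# ---------------------------------------------------------------------------

@dataclass
class NamedRegion:
    """A named set of intervals (a region may be a union, e.g., a Total row)."""

    name: str
    intervals: list[GenomicInterval]

    @property
    def length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """pos is 1-based (VCF); intervals are 0-based half-open."""
        return any(iv.chrom == chrom and iv.contains(pos - 1) for iv in self.intervals)


def regions_from_bed(path: str | Path) -> list[NamedRegion]:
    """Group BED rows by name column into NamedRegions (order of appearance)."""
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in read_bed(path):
        grouped.setdefault(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}", []).append(iv)
    return [NamedRegion(name, ivs) for name, ivs in grouped.items()]


def per_mb_rate(count: int, length_bp: int) -> float:
    """Variants per megabase: count / (length / 1e6)."""
    if length_bp <= 0:
        raise ChromplexError("region length must be > 0")
    return count / (length_bp / 1e6)


def _variant_keys(vcf: str | Path) -> set[tuple[str, int, str, str]]:
    return {s.key for s in load_variants(vcf)}


def region_unique_variants(
    calls_a: str | Path,
    calls_b: str | Path,
    regions: Sequence[NamedRegion],
) -> list[RegionVariantReport]:
    """Count variants unique to each call set per named region.

    Variant identity is (chrom, pos, ref, alt); both call sets are assumed to
    have been filtered identically beforehand. Per-Mb rates are available on
    the report rows; display rounding is left to the caller.
    """
    keys_a = _variant_keys(calls_a)
    keys_b = _variant_keys(calls_b)
    only_a = keys_a - keys_b
    only_b = keys_b - keys_a
    reports = []
    for region in regions:
        if region.length <= 0:
            raise ChromplexError(f"region {region.name!r} has zero length")
        ua = sum(1 for k in only_a if region.contains(k[0], k[1]))
        ub = sum(1 for k in only_b if region.contains(k[0], k[1]))
        reports.append(RegionVariantReport(region.name, region.length, ua, ub))
    return reports


def region_report_table(reports: Sequence[RegionVariantReport]) -> pd.DataFrame:
    """TSV-ready table; rates >= 10/Mb display to 0 decimals, else 1 decimal."""

    def fmt(rate: float) -> str:
        return f"{rate:.0f}" if rate >= 1000 else f"{rate:.1f}"

    return pd.DataFrame(
        {
            "region": [r.name for r in reports],
            "length_bp": [r.length for r in reports],
            "unique_to_a": [r.unique_to_a for r in reports],
            "rate_a_per_mb": [r.rate_a for r in reports],
            "rate_a_display": [fmt(r.rate_a) for r in reports],
            "unique_to_b": [r.unique_to_b for r in reports],
            "rate_b_per_mb": [r.rate_b for r in reports],
            "rate_b_display": [fmt(r.rate_b) for r in reports],
        }
    )


# ---------------------------------------------------------------------------
# Variant calling (external template or built-in pileup caller)
# ---------------------------------------------------------------------------

#: error probability assumed by the naive caller's binomial model
NAIVE_CALLER_ERROR = 0.01

REQUIRED_CALLER_PLACEHOLDERS = ("{bam}", "{ref}", "{out}")


def naive_call_variants(
    bam: str | Path,
    reference: str | Path,
    out_vcf: str | Path,
    min_alt: int = 1,
    min_mapq_reads: int = 0,
    sample: str = "sample",
) -> Path:
    """Built-in pileup caller for dependency-free tests.

    A site is called wherever >= min_alt reads carry a non-reference base.
    QUAL is the phred-scaled binomial probability of seeing that many alt
    reads from sequencing error alone; the genotype is the maximum-likelihood
    choice among hom-ref, het, and hom-alt binomial models and GQ is the
    phred ratio of the best to second-best likelihood (capped at 99).
    """
    from .refmask import read_fasta

    ref_records = read_fasta(reference)
    rows = []
    with pysam.AlignmentFile(str(bam)) as af:
        for chrom in af.references:
            if chrom not in ref_records:
                raise ChromplexError(f"BAM contig {chrom!r} missing from reference")
            length = af.get_reference_length(chrom)
            cov = np.array(
                af.count_coverage(chrom, 0, length, quality_threshold=0,
                                  read_callback=lambda r: not (r.is_secondary or r.is_supplementary)),
                dtype=np.int64,
            )  # 4 x L in A,C,G,T order
            ref_arr = np.frombuffer(ref_records[chrom].encode(), dtype="S1")
            base_order = np.frombuffer(b"ACGT", dtype="S1")
            ref_idx = np.searchsorted(base_order, ref_arr)
            valid = np.isin(ref_arr, base_order)
            total = cov.sum(axis=0)
            ref_counts = np.where(valid, cov[np.minimum(ref_idx, 3), np.arange(len(ref_arr))], 0)
            alt_counts_all = total - ref_counts
            candidates = np.flatnonzero(valid & (alt_counts_all >= min_alt))
            for p in candidates:
                counts = cov[:, p].copy()
                counts[ref_idx[p]] = -1
                alt_i = int(np.argmax(counts))
                alt_count = int(cov[alt_i, p])
                if alt_count < min_alt:
                    continue
                depth = int(total[p])
                ref_count = int(ref_counts[p])
                qual = float(-10 * np.log10(
                    max(stats.binom.sf(alt_count - 1, depth, NAIVE_CALLER_ERROR), 1e-300)
                ))
                # genotype likelihoods under alt-fraction models
                logl = [
                    stats.binom.logpmf(alt_count, ref_count + alt_count, f)
                    for f in (NAIVE_CALLER_ERROR, 0.5, 1 - NAIVE_CALLER_ERROR)
                ]
                order = np.argsort(logl)[::-1]
                gt = ["hom_ref", "het", "hom"][order[0]]
                gq = min(99, int(round(10 * (logl[order[0]] - logl[order[1]]) / np.log(10))))
                if gt == "hom_ref":
                    continue
                # mean MAPQ of reads overlapping the site
                mqs = [
                    r.mapping_quality
                    for r in af.fetch(chrom, p, p + 1)
                    if not (r.is_unmapped or r.is_secondary or r.is_supplementary)
                ]
                mq = float(np.mean(mqs)) if mqs else 0.0
                rows.append(
                    (chrom, p + 1, str(ref_arr[p], "ascii"),
                     str(base_order[alt_i], "ascii"), min(qual, 3000.0), mq,
                     "het" if gt == "het" else "hom", gq, depth, alt_count)
                )
        contigs = {c: af.get_reference_length(c) for c in af.references}
    sites = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "mq", "genotype", "gq", "depth", "alt_count"],
    )
    from .simdata import write_vcf

    return write_vcf(sites, contigs, out_vcf, sample=sample)


def call_variants_external(
    bam: str | Path,
    reference: str | Path,
    out_vcf: str | Path,
    caller_cmd_template: str | None = None,
    threads: int = 1,
) -> Path:
    """Produce a VCF via a templated external caller, or the built-in one.

    The template must contain {bam}, {ref} and {out} placeholders ({threads}
    is optional). With no template the built-in pileup caller runs instead.
    """
    if caller_cmd_template is None:
        return naive_call_variants(bam, reference, out_vcf)
    missing = [p for p in REQUIRED_CALLER_PLACEHOLDERS if p not in caller_cmd_template]
    if missing:
        raise ChromplexError(
            f"caller template missing placeholder(s): {', '.join(missing)}"
        )
    cmd = caller_cmd_template.format(bam=bam, ref=reference, out=out_vcf, threads=threads)
    proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
    if proc.returncode != 0:
        raise ChromplexError(
            f"variant caller failed (exit {proc.returncode}):\n{proc.stderr}"
        )
    return Path(out_vcf)


def plot_balance_histogram(
    balances: Sequence[float] | np.ndarray,
    out_png: str | Path,
    heterozygous_view: bool = True,
    n_bins: int = 50,
    title: str = "",
) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges, counts = balance_histogram(balances, heterozygous_view, n_bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge")
    ax.set_xlabel("read balance")
    ax.set_ylabel("sites")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_png, dpi=100)
    plt.close(fig)
    return Path(out_png)
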