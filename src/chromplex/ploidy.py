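"""Statistical comparison of windowed depth and the sex-complement call.

Three tests compare mean window depth between a chromosome pair:

1. a percentile bootstrap giving a 95% CI of mean window depth for each
   chromosome, checked for overlap;
2. a label-permutation test of the difference in means, with the +1
   small-sample correction so p is never exactly 0;
3. a two-sample Kolmogorov-Smirnov test on the window-depth distributions
   (D = sup |ECDF_a - ECDF_b|, asymptotic p).

The default complement decision uses only the bootstrap: with
r = mean depth(sex chromosome) / mean depth(autosome) and its bootstrap CI,
a Y chromosome is called absent when the CI upper bound falls below
``t_absent`` (default 0.10) and present when the lower bound exceeds
``t_present`` (default 0.25); between the two the call is indeterminate.
The X is diploid-like when its ratio CI overlaps [0.8, 1.2] and haploid-like
when it lies inside (0.3, 0.7). "XX" = Y absent + diploid-like X;
"XY" = Y present + haploid-like X; anything else is indeterminate. The
thresholds are engineering defaults, exposed in configuration — depth ratios
this clean presume reasonably uniform coverage. The same machinery handles
ZW systems with the roles swapped (W plays Y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import ChromplexError, logger

DEFAULT_N_BOOT = 10_000
DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class DepthComparison:
    """Bootstrap/permutation/KS results for one chromosome pair."""

    chrom_a: str
    chrom_b: str
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    ci_overlap: bool
    perm_p: float
    ks_d: float
    ks_p: float
    n_windows_a: int
    n_windows_b: int
    seed: int | None
    n_boot: int
    n_perm: int
    depths_a: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    depths_b: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class CallThresholds:
    """Decision thresholds on autosome-normalized depth ratios."""

    t_absent: float = 0.10
    t_present: float = 0.25
    diploid_band: tuple[float, float] = (0.8, 1.2)
    haploid_band: tuple[float, float] = (0.3, 0.7)


@dataclass
class SexCall:
    """Inferred sex-chromosome complement with its evidence."""

    sample_id: str
    y_present: str  # present | absent | indeterminate
    x_ploidy_hint: str  # diploid-like | haploid-like | indeterminate
    complement_label: str  # e.g. XX, XY, indeterminate
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Statistical cores
# ---------------------------------------------------------------------------

def bootstrap_mean_ci(
    values: Sequence[float] | np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean: (mean, low, high)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ChromplexError("bootstrap on empty input")
    if n_boot < 1:
        raise ChromplexError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boot_means = vals[idx].mean(axis=1)
    low, high = np.quantile(boot_means, [alpha / 2, 1 - alpha / 2])
    return float(vals.mean()), float(low), float(high)


def bootstrap_ratio_ci(
    numer: Sequence[float] | np.ndarray,
    denom: Sequence[float] | np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of mean(numer)/mean(denom), resampling each
    sample independently: (ratio, low, high)."""
    a = np.asarray(numer, dtype=float)
    b = np.asarray(denom, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ChromplexError("bootstrap on empty input")
    if b.mean() == 0:
        raise ChromplexError("denominator mean depth is 0; ratio undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    boot_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    with np.errstate(divide="ignore"):
        ratios = boot_a / boot_b
    low, high = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    return float(a.mean() / b.mean()), float(low), float(high)


def permutation_depth_test(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
    exact: bool = False,
) -> float:
    """Permutation p-value for |mean(a) - mean(b)|.

    Random mode shuffles labels n_perm times and applies the +1 correction:
    p = (#{perm stat >= observed} + 1) / (n_perm + 1), so p is never 0.
    ``exact=True`` enumerates all label assignments (choose(n, |a|)) and
    returns the exact tail proportion — feasible only for small inputs.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ChromplexError("permutation test on empty input")
    observed = abs(xa.mean() - xb.mean())
    pooled = np.concatenate([xa, xb])
    n, na = pooled.size, xa.size
    if exact:
        if math.comb(n, na) > 2_000_000:
            raise ChromplexError("input too large for exhaustive permutation")
        total = ge = 0
        idx_all = frozenset(range(n))
        for picked in combinations(range(n), na):
            sa = pooled[list(picked)].mean()
            sb = pooled[list(idx_all - set(picked))].mean()
            total += 1
            # tolerance guards float noise so ties count as >= observed
            if abs(sa - sb) >= observed - 1e-12:
                ge += 1
        return ge / total
    if n_perm < 1:
        raise ChromplexError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, 8_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(pooled, (m, 1)), axis=1)
        stat = np.abs(perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1))
        count += int((stat >= observed - 1e-12).sum())
        done += m
    return (count + 1) / (n_perm + 1)


def ks_two_sample(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic p-value."""
    xa = np.sort(np.asarray(a, dtype=float))
    xb = np.sort(np.asarray(b, dtype=float))
    na, nb = xa.size, xb.size
    if na == 0 or nb == 0:
        raise ChromplexError("KS test on empty input")
    grid = np.concatenate([xa, xb])
    cdf_a = np.searchsorted(xa, grid, side="right") / na
    cdf_b = np.searchsorted(xb, grid, side="right") / nb
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    # asymptotic Kolmogorov distribution tail
    en = math.sqrt(na * nb / (na + nb))
    lam = (en + 0.12 + 0.11 / en) * d
    p = 2.0 * sum((-1) ** (k - 1) * math.exp(-2.0 * (lam * k) ** 2) for k in range(1, 101))
    return d, float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Pair comparison and complement inference
# ---------------------------------------------------------------------------

def compare_chrom_pair(
    windows_a: pd.DataFrame | np.ndarray,
    windows_b: pd.DataFrame | np.ndarray,
    chrom_a: str = "a",
    chrom_b: str = "b",
    n_boot: int = DEFAULT_N_BOOT,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
) -> DepthComparison:
    """Run all three depth tests for one chromosome pair.

    Inputs are threshold-passing window tables (or raw depth arrays). All
    randomness flows from a single seeded generator, so identical seeds give
    identical results.
    """

    def depths(x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            return x["approx_depth"].to_numpy(dtype=float)
        return np.asarray(x, dtype=float)

    da, db = depths(windows_a), depths(windows_b)
    if da.size == 0 or db.size == 0:
        raise ChromplexError(f"no windows for pair ({chrom_a}, {chrom_b})")
    rng = np.random.default_rng(seed)
    mean_a, lo_a, hi_a = bootstrap_mean_ci(da, n_boot, alpha, rng)
    mean_b, lo_b, hi_b = bootstrap_mean_ci(db, n_boot, alpha, rng)
    perm_p = permutation_depth_test(da, db, n_perm, rng)
    ks_d, ks_p = ks_two_sample(da, db)
    return DepthComparison(
        chrom_a=chrom_a,
        chrom_b=chrom_b,
        mean_a=mean_a,
        mean_b=mean_b,
        ci_a=(lo_a, hi_a),
        ci_b=(lo_b, hi_b),
        ci_overlap=not (hi_a < lo_b or hi_b < lo_a),
        perm_p=perm_p,
        ks_d=ks_d,
        ks_p=ks_p,
        n_windows_a=int(da.size),
        n_windows_b=int(db.size),
        seed=seed,
        n_boot=n_boot,
        n_perm=n_perm,
        depths_a=da,
        depths_b=db,
    )


def comparison_table(comparisons: Sequence[DepthComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "chrom_a": c.chrom_a, "chrom_b": c.chrom_b,
                "mean_a": c.mean_a, "mean_b": c.mean_b,
                "ci_a_low": c.ci_a[0], "ci_a_high": c.ci_a[1],
                "ci_b_low": c.ci_b[0], "ci_b_high": c.ci_b[1],
                "ci_overlap": c.ci_overlap, "perm_p": c.perm_p,
                "ks_d": c.ks_d, "ks_p": c.ks_p,
                "n_windows_a": c.n_windows_a, "n_windows_b": c.n_windows_b,
                "seed": c.seed, "n_boot": c.n_boot, "n_perm": c.n_perm,
            }
        )
    return pd.DataFrame(rows)


def infer_sex_complement(
    x_comparison: DepthComparison,
    y_comparison: DepthComparison,
    thresholds: CallThresholds | None = None,
    sample_id: str = "sample",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> SexCall:
    """Call the sex-chromosome complement from X-vs-autosome and
    Y-vs-autosome depth comparisons (same autosome in both).

    Only the bootstrap drives the default decision; the permutation and KS
    results travel along as evidence.
    """
    if x_comparison is None or y_comparison is None:
        raise ChromplexError("both X and Y comparisons are required")
    if x_comparison.chrom_b != y_comparison.chrom_b:
        raise ChromplexError(
            "comparisons must share the denominator autosome: "
            f"{x_comparison.chrom_b} vs {y_comparison.chrom_b}"
        )
    th = thresholds or CallThresholds()
    rng = np.random.default_rng(seed)
    r_x, x_lo, x_hi = bootstrap_ratio_ci(
        x_comparison.depths_a, x_comparison.depths_b, n_boot, seed=rng
    )
    r_y, y_lo, y_hi = bootstrap_ratio_ci(
        y_comparison.depths_a, y_comparison.depths_b, n_boot, seed=rng
    )
    if y_hi < th.t_absent:
        y_present = "absent"
    elif y_lo > th.t_present:
        y_present = "present"
    else:
        y_present = "indeterminate"
    dlo, dhi = th.diploid_band
    hlo, hhi = th.haploid_band
    if x_lo <= dhi and x_hi >= dlo:
        x_hint = "diploid-like"
    elif hlo < x_lo and x_hi < hhi:
        x_hint = "haploid-like"
    else:
        x_hint = "indeterminate"
    if y_present == "absent" and x_hint == "diploid-like":
        label = "XX"
    elif y_present == "present" and x_hint == "haploid-like":
        label = "XY"
    else:
        label = "indeterminate"
    return SexCall(
        sample_id=sample_id,
        y_present=y_present,
        x_ploidy_hint=x_hint,
        complement_label=label,
        evidence={
            "r_x": r_x, "r_x_ci": (x_lo, x_hi),
            "r_y": r_y, "r_y_ci": (y_lo, y_hi),
            "x_comparison": x_comparison, "y_comparison": y_comparison,
        },
    )


def classify_samples_quick(
    stats: pd.DataFrame,
    x_chrom: str = "chrX",
    y_chrom: str = "chrY",
    denom_chrom: str = "chrA",
    thresholds: CallThresholds | None = None,
) -> list[SexCall]:
    """Fast multi-sample classification from chromosome-level read counts.

    Each sample's Y read count is normalized by its denominator-autosome
    count. With >= 2 samples the normalized ratios are split into two
    clusters at the largest gap (only if that gap is a clear majority of the
    spread); a single sample is classified against the fixed thresholds.
    All-identical ratios give one cluster and indeterminate calls.
    """
    th = thresholds or CallThresholds()
    ratios: dict[str, float] = {}
    for sample_id, grp in stats.groupby("sample_id"):
        vals = {row["chrom"]: row for _, row in grp.iterrows()}
        if denom_chrom not in vals or vals[denom_chrom]["n_reads"] == 0:
            logger.warning("sample %s lacks reads on %s; skipped", sample_id, denom_chrom)
            continue
        y_reads = vals.get(y_chrom, {"n_reads": 0})["n_reads"]
        ratios[str(sample_id)] = y_reads / vals[denom_chrom]["n_reads"]

    def call_from_ratio(sample_id: str, r: float, y_state: str) -> SexCall:
        label = {"absent": "XX", "present": "XY"}.get(y_state, "indeterminate")
        x_hint = {"absent": "diploid-like", "present": "haploid-like"}.get(
            y_state, "indeterminate"
        )
        return SexCall(sample_id, y_state, x_hint, label, {"y_read_ratio": r})

    items = sorted(ratios.items(), key=lambda kv: kv[1])
    if len(items) == 1:
        sid, r = items[0]
        state = "absent" if r < th.t_absent else "present" if r > th.t_present else "indeterminate"
        return [call_from_ratio(sid, r, state)]

    values = np.array([r for _, r in items])
    gaps = np.diff(values)
    if values.size == 0:
        return []
    if np.allclose(values, values[0]):
        logger.warning("all Y read ratios identical; calls indeterminate")
        return [call_from_ratio(sid, r, "indeterminate") for sid, r in items]
    split = int(np.argmax(gaps)) + 1
    # low cluster = Y absent, high cluster = Y present
    calls = []
    for i, (sid, r) in enumerate(items):
        calls.append(call_from_ratio(sid, r, "absent" if i < split else "present"))
    return sorted(calls, key=lambda c: c.sample_id)
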