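"""Windowed depth/MAPQ traversal, filtering, and chromosome summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from chromplex import bammetrics
from chromplex._util import ChromplexError, GenomicInterval
from conftest import make_bam


# ---------------------------------------------------------------------------
# depth heuristic and window MAPQ on hand-built alignments
# ---------------------------------------------------------------------------

def _reads(bam_path, chrom):
    with pysam.AlignmentFile(str(bam_path)) as af:
        return list(af.fetch(chrom))


def test_approx_window_depth_examples(tmp_path):
    bam = make_bam(
        tmp_path / "a.bam",
        {"c": 1_000},
        [{"chrom": "c", "pos": p} for p in (0, 100, 300, 500, 700)],
    )
    reads = _reads(bam, "c")
    assert bammetrics.approx_window_depth(reads, GenomicInterval("c", 0, 1_000)) == 0.5
    assert bammetrics.approx_window_depth([], GenomicInterval("c", 0, 1_000)) == 0.0

    bam2 = make_bam(
        tmp_path / "b.bam", {"c": 200},
        [{"chrom": "c", "pos": 0}, {"chrom": "c", "pos": 50}],
    )
    assert bammetrics.approx_window_depth(_reads(bam2, "c"), GenomicInterval("c", 0, 100)) == 2.0


def test_window_mean_mapq():
    class R:
        def __init__(self, mapq):
            self.mapping_quality = mapq
            self.is_unmapped = self.is_secondary = self.is_supplementary = False
            self.is_duplicate = False

    assert bammetrics.window_mean_mapq([R(60), R(60), R(0)]) == (40.0, False)
    assert bammetrics.window_mean_mapq([R(37)]) == (37.0, False)
    assert bammetrics.window_mean_mapq([]) == (0.0, True)


@pytest.mark.parametrize(
    "chrom_len,window,expected",
    [
        (10_000, 5_000, [(0, 5_000), (5_000, 10_000)]),
        (12_000, 5_000, [(0, 5_000), (5_000, 10_000), (10_000, 12_000)]),
    ],
)
def test_traverse_window_tiling(tmp_path, chrom_len, window, expected):
    bam = make_bam(tmp_path / "t.bam", {"c": chrom_len}, [{"chrom": "c", "pos": 10}])
    windows = bammetrics.traverse(bam, "c", window)
    assert list(zip(windows["start"], windows["end"])) == expected


def test_traverse_errors(tmp_path):
    bam = make_bam(tmp_path / "e.bam", {"c": 1_000}, [{"chrom": "c", "pos": 0}])
    with pytest.raises(ChromplexError, match="not in BAM header"):
        bammetrics.traverse(bam, "nope", 100)
    import os

    os.remove(str(bam) + ".bai")
    with pytest.raises(ChromplexError, match="index"):
        bammetrics.traverse(bam, "c", 100)


def test_uniform_coverage_windows_hit_target_depth(tmp_path):
    """Simulated uniform 10x fixture: >=95% of 5-kb windows within +/-15%."""
    from chromplex import simdata

    spec = simdata.GenomeSpec(autosome_len=200_000, seed=17)
    records, _ = simdata.simulate_genome(spec)
    cfg = simdata.PloidyConfig(
        complement="XX", mean_depth=10, paired=False, error_rate=0.0, seed=17
    )
    bam, _ = simdata.simulate_alignments(records, spec, cfg, tmp_path / "u.bam")
    w = bammetrics.traverse(bam, "chrA", 5_000)
    frac = ((w["approx_depth"] >= 8.5) & (w["approx_depth"] <= 11.5)).mean()
    assert frac >= 0.95


def test_read_assignment_conserves_reads(xy_bundle):
    with pysam.AlignmentFile(str(xy_bundle["bam"])) as af:
        for chrom in ("chrA", "chrX", "chrY"):
            total = sum(
                1 for r in af.fetch(chrom)
                if not (r.is_unmapped or r.is_secondary or r.is_supplementary)
            )
            assert xy_bundle["windows"][chrom]["n_primary"].sum() == total


def test_approx_depth_equals_exact_depth_for_window_contained_reads(tmp_path):
    rng = np.random.default_rng(0)
    window = 500
    reads = []
    for w in range(10):
        for _ in range(rng.integers(0, 8)):
            pos = int(w * window + rng.integers(0, window - 100 + 1))
            reads.append({"chrom": "c", "pos": pos})
    bam = make_bam(tmp_path / "c.bam", {"c": 5_000}, reads)
    windows = bammetrics.traverse(bam, "c", window)
    with pysam.AlignmentFile(str(bam)) as af:
        cov = np.array(af.count_coverage("c", 0, 5_000)).sum(axis=0)
    for row in windows.itertuples():
        exact = cov[row.start : row.end].mean()
        assert row.approx_depth == pytest.approx(exact, abs=1e-12)


def test_chrom_stats_depth_is_length_weighted_window_mean(xy_bundle):
    stats = bammetrics.chrom_stats([xy_bundle["bam"]], ["chrA", "chrX", "chrY"])
    for chrom in ("chrA", "chrX", "chrY"):
        w = xy_bundle["windows"][chrom]
        lens = (w["end"] - w["start"]).to_numpy()
        expected = float((w["approx_depth"] * lens).sum() / lens.sum())
        got = stats.loc[stats["chrom"] == chrom, "mean_depth"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-9)


def test_chrom_stats_counts_and_missing_chrom(tmp_path):
    reads = [{"chrom": "c", "pos": i % 900} for i in range(500)]
    reads.append({"chrom": "c", "pos": 1, "flag": 0x100})  # secondary, not counted
    bam = make_bam(tmp_path / "n.bam", {"c": 1_000}, reads)
    stats = bammetrics.chrom_stats([bam], ["c", "ghost"])
    assert stats.loc[stats["chrom"] == "c", "n_reads"].iloc[0] == 500
    ghost = stats.loc[stats["chrom"] == "ghost"].iloc[0]
    assert ghost["n_reads"] == 0 and ghost["mean_depth"] == 0.0


# ---------------------------------------------------------------------------
# window filtering
# ---------------------------------------------------------------------------

def _window_df(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "approx_depth", "mean_mapq", "n_primary", "empty"]
    )


def test_filter_windows_partition_and_thresholds():
    # chromosome mean depth is (10+10+10+30+0)/5 = 12; bounds (0.5, 1.5) -> [6, 18]
    df = _window_df(
        [
            ("c", 0, 100, 10.0, 55.0, 5, False),   # clean pass
            ("c", 100, 200, 10.0, 10.0, 5, False),  # MAPQ fail
            ("c", 200, 300, 10.0, 30.0, 5, False),  # MAPQ exactly at threshold: pass
            ("c", 300, 400, 30.0, 60.0, 5, False),  # depth fail (high)
            ("c", 400, 500, 0.0, 0.0, 0, True),     # empty fail
        ]
    )
    passed, failed = bammetrics.filter_windows(df, min_mapq=30.0, depth_bounds=(0.5, 1.5))
    assert len(passed) + len(failed) == len(df)
    assert set(passed["start"]) == {0, 200}
    assert set(failed["start"]) == {100, 300, 400}
    with pytest.raises(ChromplexError, match="low > high"):
        bammetrics.filter_windows(df, depth_bounds=(4.0, 0.25))


def test_filter_windows_depth_bounds_relative_to_chrom_mean():
    df = _window_df(
        [("c", i * 100, (i + 1) * 100, d, 60.0, 5, False) for i, d in enumerate([10, 10, 10, 1])]
    )
    # chromosome mean is 7.75; 1 is above 0.25*mu=1.94? no: 1 < 1.9375 -> fail
    passed, failed = bammetrics.filter_windows(df)
    assert list(failed["approx_depth"]) == [1]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_to_chrom_matches_hand_division():
    rows = []
    rng = np.random.default_rng(7)
    for sample in ("s1", "s2", "s3"):
        for chrom in ("chrX", "chrY", "chr19"):
            rows.append((sample, chrom, int(rng.integers(0, 5_000)),
                         float(rng.uniform(0, 60)), float(rng.uniform(0, 30))))
    stats = pd.DataFrame(rows, columns=["sample_id", "chrom", "n_reads", "mean_mapq", "mean_depth"])
    out = bammetrics.normalize_to_chrom(stats, "chr19")
    for row in out.itertuples():
        denom = stats[(stats["sample_id"] == row.sample_id) & (stats["chrom"] == "chr19")].iloc[0]
        assert row.rel_depth == pytest.approx(row.mean_depth / denom["mean_depth"])
        assert row.rel_reads == pytest.approx(row.n_reads / denom["n_reads"])


def test_normalize_zero_denominator_yields_nan_not_error():
    stats = pd.DataFrame(
        [("s", "chrY", 0, 0.0, 0.0), ("s", "chr19", 100, 60.0, 20.0)],
        columns=["sample_id", "chrom", "n_reads", "mean_mapq", "mean_depth"],
    )
    out = bammetrics.normalize_to_chrom(stats, "chr19")
    assert out.loc[out["chrom"] == "chrY", "rel_depth"].iloc[0] == 0.0
    assert out.loc[out["chrom"] == "chrX"].empty  # sanity

    flipped = bammetrics.normalize_to_chrom(stats, "chrY")  # zero denominator
    assert np.isnan(flipped["rel_depth"]).all()
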