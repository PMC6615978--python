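"""Variant filtering, read balance, histograms, and region-unique counting."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from chromplex import varmetrics
from chromplex._util import ChromplexError, GenomicInterval
from chromplex.simdata import write_vcf
from chromplex.varmetrics import NamedRegion, VariantSite


def _site(**kw) -> VariantSite:
    base = dict(
        chrom="chrX", pos=100, ref="A", alt="T", site_qual=50.0,
        mapq_annotation=60.0, genotype_qual=99.0, depth=30, ref_count=15, alt_count=15,
    )
    base.update(kw)
    return VariantSite(**base)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_variants_boundaries():
    removed = _site(site_qual=29.9)
    kept = _site(site_qual=30.0, mapq_annotation=30.0)
    out = varmetrics.filter_variants([removed, kept], min_site_qual=30, min_mq=30)
    assert out == [kept]


def test_filter_variants_depth_threshold_counts():
    sites = [_site(pos=p, depth=d) for p, d in
             [(1, 30), (2, 5), (3, 12), (4, 7), (5, 9), (6, 40)]]
    out = varmetrics.filter_variants(sites, min_depth=8)
    assert [s.pos for s in out] == [1, 3, 5, 6]


def test_filter_variants_missing_annotations():
    no_mq = _site(mapq_annotation=None)
    no_gq = _site(genotype_qual=None)
    out = varmetrics.filter_variants([no_mq, no_gq])
    assert out == [no_mq]  # missing MQ passes with warning; missing GQ fails


# ---------------------------------------------------------------------------
# read balance and histograms
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ref,alt,expected", [(5, 5, 0.5), (0, 10, 1.0), (7, 3, 0.3)])
def test_read_balance(ref, alt, expected):
    assert varmetrics.read_balance(ref, alt) == expected


def test_read_balance_zero_total_is_error():
    with pytest.raises(ChromplexError):
        varmetrics.read_balance(0, 0)


def test_balance_histogram_heterozygous_view_excludes_extremes():
    edges, counts = varmetrics.balance_histogram([0.02, 0.5, 1.0], heterozygous_view=True, n_bins=10)
    assert counts.sum() == 1
    assert counts[5] == 1  # 0.5 lands in [0.5, 0.6)
    edges, counts = varmetrics.balance_histogram([], heterozygous_view=True, n_bins=10)
    assert counts.sum() == 0


def test_heterozygous_view_is_subset_of_full_view():
    rng = np.random.default_rng(3)
    balances = rng.uniform(0, 1, 500)
    _, full = varmetrics.balance_histogram(balances, heterozygous_view=False, n_bins=20)
    _, het = varmetrics.balance_histogram(balances, heterozygous_view=True, n_bins=20)
    assert (het <= full).all()


def test_simulated_diploid_histogram_modes(xy_bundle):
    """Diploid truth balances peak near 0.5 and (full view) near 1.0."""
    truth = xy_bundle["variants"]
    diploid = truth[truth["chrom"] == "chrA"]
    balances = (diploid["alt_count"] / diploid["depth"]).to_numpy()
    edges, counts = varmetrics.balance_histogram(balances, n_bins=20)
    top_two = np.argsort(counts)[-2:]
    centers = sorted((edges[i] + edges[i + 1]) / 2 for i in top_two)
    assert abs(centers[0] - 0.5) <= 0.1
    assert centers[1] > 0.9


# ---------------------------------------------------------------------------
# windowed variant summaries
# ---------------------------------------------------------------------------

def test_window_variant_summary_examples():
    sites = [_site(pos=p) for p in (100, 4_900, 5_100)]
    out = varmetrics.window_variant_summary(sites, 5_000)
    assert list(out["n_variants"]) == [2, 1]

    sites = [_site(pos=10, ref_count=6, alt_count=4), _site(pos=20, ref_count=4, alt_count=6)]
    out = varmetrics.window_variant_summary(sites, 5_000)
    assert out["mean_balance"].iloc[0] == pytest.approx(0.5)


def test_window_variant_summary_matches_brute_force():
    rng = np.random.default_rng(11)
    window = 700
    sites = [
        _site(pos=int(p), ref_count=int(r), alt_count=int(a))
        for p, r, a in zip(
            rng.integers(1, 20_000, 300), rng.integers(0, 30, 300), rng.integers(1, 30, 300)
        )
    ]
    out = varmetrics.window_variant_summary(sites, window, chrom_length=20_000)
    for w in range(len(out)):
        in_w = [s for s in sites if w * window < s.pos <= (w + 1) * window]
        assert out["n_variants"].iloc[w] == len(in_w)
        if in_w:
            expected = np.mean([s.alt_count / (s.ref_count + s.alt_count) for s in in_w])
            assert out["mean_balance"].iloc[w] == pytest.approx(expected)
        else:
            assert np.isnan(out["mean_balance"].iloc[w])


# ---------------------------------------------------------------------------
# per-Mb rates and region-unique counting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "count,length,expected",
    [(7_563, 2_589_520, 2_920.6), (366, 4_287_237, 85.4), (0, 1_000_000, 0.0)],
)
def test_per_mb_rate(count, length, expected):
    assert round(varmetrics.per_mb_rate(count, length), 1) == expected


def test_per_mb_rate_zero_length_fatal():
    with pytest.raises(ChromplexError):
        varmetrics.per_mb_rate(10, 0)


def _vcf(tmp_path, name, rows, contig_len=100_000):
    import pandas as pd

    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt"]
    ).assign(qual=60.0, mq=60.0, genotype="het", gq=99, depth=30, alt_count=15)
    return write_vcf(df, {"chr1": contig_len}, tmp_path / name)


def test_region_unique_variants_set_difference(tmp_path):
    a = _vcf(tmp_path, "a.vcf", [("chr1", 100, "A", "T"), ("chr1", 200, "G", "C")])
    b = _vcf(tmp_path, "b.vcf", [("chr1", 200, "G", "C"), ("chr1", 300, "C", "G")])
    region = NamedRegion("all", [GenomicInterval("chr1", 0, 100_000)])
    (rep,) = varmetrics.region_unique_variants(a, b, [region])
    assert (rep.unique_to_a, rep.unique_to_b) == (1, 1)

    (swapped,) = varmetrics.region_unique_variants(b, a, [region])
    assert (swapped.unique_to_a, swapped.unique_to_b) == (1, 1)
    # anti-symmetry with distinct counts
    a2 = _vcf(tmp_path, "a2.vcf", [("chr1", 100, "A", "T"), ("chr1", 150, "A", "G"), ("chr1", 200, "G", "C")])
    (r1,) = varmetrics.region_unique_variants(a2, b, [region])
    (r2,) = varmetrics.region_unique_variants(b, a2, [region])
    assert (r1.unique_to_a, r1.unique_to_b) == (r2.unique_to_b, r2.unique_to_a)


def test_identical_vcfs_have_no_unique_variants(tmp_path):
    rows = [("chr1", 100, "A", "T"), ("chr1", 200, "G", "C")]
    a = _vcf(tmp_path, "same_a.vcf", rows)
    b = _vcf(tmp_path, "same_b.vcf", rows)
    (rep,) = varmetrics.region_unique_variants(a, b, [NamedRegion("all", [GenomicInterval("chr1", 0, 100_000)])])
    assert rep.unique_to_a == rep.unique_to_b == 0
    assert rep.rate_a == rep.rate_b == 0.0


def test_disjoint_region_counts_sum_to_union(tmp_path):
    rng = np.random.default_rng(5)
    pos_a = sorted(rng.choice(np.arange(1, 50_000), 80, replace=False))
    pos_b = sorted(rng.choice(np.arange(1, 50_000), 80, replace=False))
    a = _vcf(tmp_path, "ua.vcf", [("chr1", int(p), "A", "T") for p in pos_a])
    b = _vcf(tmp_path, "ub.vcf", [("chr1", int(p), "A", "T") for p in pos_b])
    parts = [
        NamedRegion("r1", [GenomicInterval("chr1", 0, 10_000)]),
        NamedRegion("r2", [GenomicInterval("chr1", 10_000, 30_000)]),
        NamedRegion("r3", [GenomicInterval("chr1", 30_000, 50_000)]),
    ]
    total = NamedRegion("Total", [iv for r in parts for iv in r.intervals])
    reports = varmetrics.region_unique_variants(a, b, parts + [total])
    assert sum(r.unique_to_a for r in reports[:3]) == reports[3].unique_to_a
    assert sum(r.unique_to_b for r in reports[:3]) == reports[3].unique_to_b
    assert sum(r.length for r in reports[:3]) == reports[3].length


def test_region_zero_length_fatal(tmp_path):
    a = _vcf(tmp_path, "za.vcf", [("chr1", 100, "A", "T")])
    region = NamedRegion("empty", [])
    with pytest.raises(ChromplexError):
        varmetrics.region_unique_variants(a, a, [region])


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def test_caller_template_missing_placeholder_is_fatal(tmp_path):
    with pytest.raises(ChromplexError, match="placeholder"):
        varmetrics.call_variants_external(
            "x.bam", "r.fa", tmp_path / "o.vcf", caller_cmd_template="caller {bam} {out}"
        )


def test_naive_caller_recovers_simulated_sites(xy_bundle, tmp_path):
    out = varmetrics.call_variants_external(
        xy_bundle["bam"], xy_bundle["fasta"], tmp_path / "called.vcf"
    )
    called = varmetrics.filter_variants(varmetrics.load_variants(out))
    called_keys = {s.key for s in called}
    truth = xy_bundle["variants"]
    truth_keys = set(zip(truth["chrom"], truth["pos"], truth["ref"], truth["alt"]))
    # no false positives survive filtering
    assert called_keys <= truth_keys
    # high recovery on the well-covered diploid autosome away from chromosome
    # edges (the haploid sex chromosomes sit at half depth, where the GQ and
    # depth filters legitimately drop borderline sites)
    def clean(chrom, pos):
        return chrom == "chrA" and 150 <= pos <= len(xy_bundle["records"][chrom]) - 150

    clean_truth = {k for k in truth_keys if clean(k[0], k[1])}
    assert len(clean_truth) > 50
    assert len(called_keys & clean_truth) / len(clean_truth) >= 0.9


def test_naive_caller_empty_bam_gives_header_only_vcf(tmp_path):
    from conftest import make_bam
    from chromplex.refmask import write_fasta

    bam = make_bam(tmp_path / "empty.bam", {"c": 500}, [])
    ref = write_fasta({"c": "A" * 500}, tmp_path / "ref.fa")
    out = varmetrics.naive_call_variants(bam, ref, tmp_path / "e.vcf")
    assert varmetrics.load_variants(out) == []


def test_vcf_write_load_roundtrip(tmp_path, xy_bundle):
    sites = varmetrics.load_variants(xy_bundle["truth_vcf"])
    truth = xy_bundle["variants"]
    assert len(sites) == len(truth)
    by_key = {s.key: s for s in sites}
    for row in truth.itertuples():
        s = by_key[(row.chrom, row.pos, row.ref, row.alt)]
        assert s.alt_count == row.alt_count
        assert s.depth == row.depth
        assert s.ref_count == row.depth - row.alt_count
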