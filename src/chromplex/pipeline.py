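"""Full pipeline: prepare references, analyze, infer complement, remap, re-analyze.

Per sample: pre-remap window metrics are computed, the sex-chromosome
complement is inferred, reads on the sex chromosomes are stripped and
remapped against the reference version matching the call (the homogametic
version for XX, the heterogametic version for XY), the result is merged with
the untouched non-sex alignments, and metrics are recomputed for a
before/after comparison. Indeterminate samples are reported and never
remapped silently.

Depth deltas in the before/after table are reported as
sign(diff) * log10(|diff|), clamped to 0 when |diff| < 1 (so sub-read-depth
jitter does not register); MAPQ deltas are plain differences.

Every output table carries a provenance header with the package version,
a configuration hash, and the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import ChromplexError, config_hash, logger, provenance_header
from . import bammetrics, ploidy, refmask, striper, varmetrics


@dataclass
class PipelineConfig:
    reference: str
    bams: list[str]
    x_chrom: str = "chrX"
    y_chrom: str = "chrY"
    autosome: str = "chrA"
    y_par_mask_bed: str | None = None
    extra_mask_beds: list[str] = field(default_factory=list)
    window_size: int = bammetrics.DEFAULT_WINDOW_SIZE
    min_mapq: float = bammetrics.DEFAULT_MIN_MAPQ
    depth_bounds: tuple[float, float] = bammetrics.DEFAULT_DEPTH_BOUNDS
    min_site_qual: float = varmetrics.DEFAULT_MIN_SITE_QUAL
    min_genotype_qual: float = varmetrics.DEFAULT_MIN_GQ
    min_variant_depth: int = varmetrics.DEFAULT_MIN_DEPTH
    min_variant_mq: float = varmetrics.DEFAULT_MIN_MQ
    n_boot: int = ploidy.DEFAULT_N_BOOT
    n_perm: int = ploidy.DEFAULT_N_PERM
    seed: int = 0
    aligner_cmd_template: str | None = None
    sort_cmd_template: str | None = None
    caller_cmd_template: str | None = None
    outdir: str = "chromplex_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        if isinstance(cfg.depth_bounds, list):
            cfg.depth_bounds = tuple(cfg.depth_bounds)  # type: ignore[assignment]
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["depth_bounds"] = list(self.depth_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
        return Path(path)

    def validate(self) -> None:
        missing = [p for p in [self.reference, *self.bams] if not Path(p).exists()]
        if self.y_par_mask_bed and not Path(self.y_par_mask_bed).exists():
            missing.append(self.y_par_mask_bed)
        if missing:
            raise ChromplexError(f"missing input file(s): {', '.join(missing)}")


def _write_table(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str) -> Path:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, cfg_hash))
    df.to_csv(path, sep="\t", index=False, mode="a")
    return path


def delta_table(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Before/after per-window comparison on a shared window grid.

    depth_delta = sign(diff) * log10(|diff|), 0 when |diff| < 1;
    mapq_delta = post - pre (plain difference).
    """
    if not (pre["start"].tolist() == post["start"].tolist()
            and pre["chrom"].tolist() == post["chrom"].tolist()):
        raise ChromplexError("pre/post window grids differ; cannot build delta table")
    diff = post["approx_depth"].to_numpy() - pre["approx_depth"].to_numpy()
    depth_delta = np.zeros_like(diff)
    big = np.abs(diff) >= 1.0
    depth_delta[big] = np.sign(diff[big]) * np.log10(np.abs(diff[big]))
    return pd.DataFrame(
        {
            "chrom": pre["chrom"],
            "start": pre["start"],
            "end": pre["end"],
            "depth_before": pre["approx_depth"],
            "depth_after": post["approx_depth"],
            "depth_delta": depth_delta,
            "mapq_before": pre["mean_mapq"],
            "mapq_after": post["mean_mapq"],
            "mapq_delta": post["mean_mapq"].to_numpy() - pre["mean_mapq"].to_numpy(),
        }
    )


def _analyze(bam: str | Path, chroms: Sequence[str], cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    return {c: bammetrics.traverse(bam, c, cfg.window_size) for c in chroms}


def _count_chrom_variants(vcf: Path, chrom: str, cfg: PipelineConfig) -> int:
    sites = varmetrics.filter_variants(
        varmetrics.load_variants(vcf),
        cfg.min_site_qual, cfg.min_genotype_qual, cfg.min_variant_depth, cfg.min_variant_mq,
    )
    return sum(1 for s in sites if s.chrom == chrom)


def run_full(config: PipelineConfig) -> dict:
    """Run the whole pipeline; returns the report bundle (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash covers the analysis parameters, not where the outputs land
    cfg_hash = config_hash({k: v for k, v in asdict(config).items() if k != "outdir"})
    seed = config.seed
    chroms = [config.x_chrom, config.y_chrom, config.autosome]

    pair = refmask.prepare_reference_pair(
        config.reference,
        heterogametic_only_chroms=[config.y_chrom],
        shared_region_mask=config.y_par_mask_bed,
        extra_masks=config.extra_mask_beds or None,
        out_prefix=str(outdir / "ref_"),
    )

    report: dict = {
        "config_hash": cfg_hash,
        "seed": seed,
        "reference_pair": {
            "homogametic": str(pair.homogametic_path),
            "heterogametic": str(pair.heterogametic_path),
        },
        "samples": {},
    }

    for bam in config.bams:
        sample_id = Path(bam).stem
        sdir = outdir / sample_id
        sdir.mkdir(exist_ok=True)
        pre = _analyze(bam, chroms, config)
        for chrom, df in pre.items():
            _write_table(df, sdir / f"pre_{chrom}_windows.tsv", seed, cfg_hash)

        passed = {
            chrom: bammetrics.filter_windows(df, config.min_mapq, config.depth_bounds)[0]
            for chrom, df in pre.items()
        }
        cmp_x = ploidy.compare_chrom_pair(
            passed[config.x_chrom], passed[config.autosome],
            config.x_chrom, config.autosome,
            n_boot=config.n_boot, n_perm=config.n_perm, seed=seed,
        )
        y_windows = passed[config.y_chrom]
        if y_windows.empty:
            # nothing on Y passes (e.g., only MAPQ-0 mismapped homology reads):
            # fall back to unfiltered windows so the depth evidence stays honest
            logger.warning(
                "sample %s: no %s windows pass filters; using unfiltered windows",
                sample_id, config.y_chrom,
            )
            y_windows = pre[config.y_chrom]
        cmp_y = ploidy.compare_chrom_pair(
            y_windows, passed[config.autosome],
            config.y_chrom, config.autosome,
            n_boot=config.n_boot, n_perm=config.n_perm, seed=seed + 1,
        )
        call = ploidy.infer_sex_complement(
            cmp_x, cmp_y, sample_id=sample_id, n_boot=config.n_boot, seed=seed + 2
        )
        _write_table(
            ploidy.comparison_table([cmp_x, cmp_y]),
            sdir / "depth_comparisons.tsv", seed, cfg_hash,
        )
        call_json = {
            "sample_id": call.sample_id,
            "y_present": call.y_present,
            "x_ploidy_hint": call.x_ploidy_hint,
            "complement_label": call.complement_label,
            "r_x": call.evidence["r_x"], "r_x_ci": list(call.evidence["r_x_ci"]),
            "r_y": call.evidence["r_y"], "r_y_ci": list(call.evidence["r_y_ci"]),
            "seed": seed, "config_hash": cfg_hash,
        }
        with open(sdir / "sex_call.json", "w") as fh:
            json.dump(call_json, fh, indent=2)

        sample_report: dict = {"sex_call": call_json, "remapped": False}
        report["samples"][sample_id] = sample_report
        if call.complement_label == "indeterminate":
            logger.warning("sample %s complement indeterminate; remapping skipped", sample_id)
            sample_report["skip_reason"] = "indeterminate sex-chromosome complement"
            continue

        target_ref = (
            pair.homogametic_path if call.complement_label == "XX" else pair.heterogametic_path
        )
        bundles = striper.strip_reads(bam, [config.x_chrom, config.y_chrom], sdir / "fastq")
        remapped = striper.remap_external(
            bundles, target_ref, sdir / "remapped_sexchroms.bam",
            aligner_cmd_template=config.aligner_cmd_template,
            sort_cmd_template=config.sort_cmd_template,
            sample=sample_id,
        )
        final_bam = striper.merge_with_nonsex(
            bam, remapped, [config.x_chrom, config.y_chrom], sdir / "final.bam"
        )
        post = _analyze(final_bam, chroms, config)
        for chrom, df in post.items():
            _write_table(df, sdir / f"post_{chrom}_windows.tsv", seed, cfg_hash)
            _write_table(
                delta_table(pre[chrom], df), sdir / f"delta_{chrom}_windows.tsv",
                seed, cfg_hash,
            )

        vcf_before = varmetrics.call_variants_external(
            bam, config.reference, sdir / "before.vcf", config.caller_cmd_template
        )
        vcf_after = varmetrics.call_variants_external(
            final_bam, target_ref, sdir / "after.vcf", config.caller_cmd_template
        )
        sample_report.update(
            {
                "remapped": True,
                "reference_used": str(target_ref),
                "final_bam": str(final_bam),
                "y_variants_before": _count_chrom_variants(vcf_before, config.y_chrom, config),
                "y_variants_after": _count_chrom_variants(vcf_after, config.y_chrom, config),
                "y_primary_reads_after": int(
                    bammetrics.chrom_stats([final_bam], [config.y_chrom])["n_reads"].iloc[0]
                ),
            }
        )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
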