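"""End-to-end pipeline on a synthetic cohort.

Runs phantom generation -> quality control -> slab extraction at both
depth series -> binarization -> OCTA/OCT comparison -> optimal-depth
selection -> vascular-density measurement -> cohort statistics, and
writes every table plus a run log.  All randomness flows from a single
top-level seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, binarize as _binarize_mod
from .binarize import binarize
from .compare import (
    DisplayCriteria,
    Measurement,
    comparison_map,
    depth_profile,
    evaluate_pair,
    select_optimal_depth,
)
from .io import (
    cvd_results_to_frame,
    profile_to_frame,
    roster_to_csv,
    save_comparison_map,
)
from .phantom import generate_cohort, generate_slab_pair
from .qc import apply_exclusions
from .quantify import DEFAULT_CVD_DEPTH_UM, measure_cvd
from .slabs import (
    ImagePair,
    eligible_at_depth,
    fixed_schedule,
    percentile_depths,
    percentile_schedule,
    quantize_depth,
)
from .stats import compare_groups, fit_cvd_regression, ks_normality, pearson_corr

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    n_healthy: int = 6
    n_csc: int = 0
    effect: float = 8.2
    slope: float = 3.9
    grid: int = 64
    seed: int = 0
    artefact_fraction: float = 0.1
    cvd_depth_nominal_um: float = 100.0
    axial_step: float = 2.6
    write_maps: bool = True

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(data)


@dataclass
class PipelineResult:
    roster: pd.DataFrame
    included_ids: list[str]
    fixed_profile: pd.DataFrame
    percentile_profile: pd.DataFrame
    optimal_fixed_depth: str | None
    optimal_percentile_depth: str | None
    cvd_table: pd.DataFrame
    stats_report: dict[str, Any]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(
        config.n_healthy,
        config.n_csc,
        effect=config.effect,
        slope=config.slope,
        seed=config.seed,
        artefact_fraction=config.artefact_fraction,
        grid=config.grid,
        depth_um=quantize_depth(config.cvd_depth_nominal_um, config.axial_step),
    )
    roster = [rec for rec, _ in cohort]
    cfg_by_id = {rec.eye_id: cfg for rec, cfg in cohort}
    roster_to_csv(roster, out / "roster.csv")

    included, exclusion_log = apply_exclusions(roster)
    pd.DataFrame(
        [{"eye_id": e.eye_id, "reason": e.reason} for e in exclusion_log]
    ).to_csv(out / "exclusions.csv", index=False)

    cvd_depth = quantize_depth(config.cvd_depth_nominal_um, config.axial_step)
    criteria = DisplayCriteria()

    # fixed-depth series
    fixed = fixed_schedule(config.axial_step)
    fixed_measurements: list[Measurement] = []
    for eye in included:
        cfg = cfg_by_id[eye.eye_id]
        for nominal, label in zip(fixed.nominal_values, fixed.labels()):
            depth = quantize_depth(nominal, config.axial_step)
            if not eligible_at_depth(eye, depth):
                continue
            octa, oct_ = generate_slab_pair(cfg, depth)
            pair = ImagePair(octa, oct_, eye.eye_id, nominal, depth)
            fixed_measurements.append(evaluate_pair(pair, label, criteria))
    fixed_rows = depth_profile(fixed_measurements, fixed.labels())
    fixed_profile = profile_to_frame(fixed_rows)
    fixed_profile.to_csv(out / "profile_fixed.csv", index=False)
    optimal_fixed = select_optimal_depth(fixed_rows)

    # percentile series
    pct = percentile_schedule(config.axial_step)
    pct_measurements: list[Measurement] = []
    for eye in included:
        cfg = cfg_by_id[eye.eye_id]
        depths = percentile_depths(eye.sct, config.axial_step)
        for depth, label in zip(depths, pct.labels()):
            octa, oct_ = generate_slab_pair(cfg, depth)
            pair = ImagePair(octa, oct_, eye.eye_id, label, depth)
            pct_measurements.append(evaluate_pair(pair, label, criteria))
    pct_rows = depth_profile(pct_measurements, pct.labels())
    pct_profile = profile_to_frame(pct_rows)
    pct_profile.to_csv(out / "profile_percentile.csv", index=False)
    optimal_pct = select_optimal_depth(pct_rows)

    # CVD at the measurement depth + comparison maps
    results = []
    for eye in included:
        cfg = cfg_by_id[eye.eye_id]
        octa, oct_ = generate_slab_pair(cfg, cvd_depth)
        results.append(measure_cvd(octa, depth=cvd_depth, eye_id=eye.eye_id))
        if config.write_maps:
            cmap = comparison_map(binarize(octa), binarize(oct_))
            maps_dir = out / "maps"
            maps_dir.mkdir(exist_ok=True)
            save_comparison_map(
                maps_dir / f"{eye.eye_id}_{cvd_depth:05.1f}um_map.png", cmap
            )
    cvd_table = cvd_results_to_frame(results)
    meta = pd.DataFrame(
        [
            {
                "eye_id": e.eye_id,
                "age": e.age,
                "sex": e.sex,
                "axial_length": e.axial_length,
                "sct": e.sct,
                "group": e.group,
            }
            for e in included
        ]
    )
    cvd_table = cvd_table.merge(meta, on="eye_id")
    cvd_table.to_csv(out / "cvd.csv", index=False)

    # statistics
    report: dict[str, Any] = {
        "n_included": len(included),
        "n_excluded": len(exclusion_log),
        "optimal_fixed_depth": optimal_fixed,
        "optimal_percentile_depth": optimal_pct,
        "cvd_depth_um": cvd_depth,
    }
    healthy = cvd_table[cvd_table["group"] == "healthy"]
    if len(healthy) >= 10:
        ks_stat, ks_p = ks_normality(healthy["cvd"])
        report["healthy_cvd_mean"] = float(healthy["cvd"].mean())
        report["healthy_cvd_sd"] = float(healthy["cvd"].std(ddof=1))
        report["healthy_cvd_normality_p"] = ks_p
        r, p = pearson_corr(healthy["sct"], healthy["cvd"])
        report["pearson_sct_r"] = r
        report["pearson_sct_p"] = p
        reg = fit_cvd_regression(healthy)
        sct = reg.coefficients["sct"]
        report["sct_slope_per_100um"] = sct.estimate
        report["sct_slope_ci"] = [sct.ci_low, sct.ci_high]
        report["sct_slope_p"] = sct.p
    if config.n_csc > 0 and (cvd_table["group"] != "healthy").any():
        two = cvd_table.assign(
            group=np.where(cvd_table["group"] == "healthy", "healthy", "csc")
        )
        if (two["group"] == "csc").sum() >= 3 and (two["group"] == "healthy").sum() >= 3:
            gc = compare_groups(two)
            report["group_means"] = gc.group_means
            report["group_sds"] = gc.group_sds
            report["anova_p"] = gc.anova_p
            report["ancova_p"] = gc.ancova_p
            report["adjusted_means"] = gc.adjusted_means
    else:
        report["group_comparison"] = "skipped: no CSC eyes in cohort"

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log = {
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))

    return PipelineResult(
        roster=pd.read_csv(out / "roster.csv"),
        included_ids=[e.eye_id for e in included],
        fixed_profile=fixed_profile,
        percentile_profile=pct_profile,
        optimal_fixed_depth=optimal_fixed,
        optimal_percentile_depth=optimal_pct,
        cvd_table=cvd_table,
        stats_report=report,
    )
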