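"""End-to-end study orchestration at desk scale.

phantom cohort (or user rasters) -> binarization & coverage -> local
thickness -> speed decoding -> Poiseuille flow -> AVR -> NVC metrics ->
two-group statistics -> CSV report bundle.

Every run is fully determined by its config and seed; a manifest records
both so any output can be regenerated byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .avr import classify_direction, compute_avr
from .density import binarize, coverage_table
from .flow import FlowModelParams, decode_speed, flow_rate_map, regional_cbf
from .maps import RegionSet
from .nvc import StimSchedule, aggregate_responses, analyze_trace
from .phantom import AnimalPhantom, Cohort, CohortParams, simulate_cohort
from .stats import compare_groups, method_for_metric, summary_row
from .thickness import (
    apply_reliability_floor,
    local_thickness,
    regional_thickness_summary,
)

log = logging.getLogger("vasculomap")

ANALYSIS_REGIONS = ("whole_brain", "cortex", "hippocampus", "white_matter")


@dataclass
class PipelineConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    flow: FlowModelParams = field(default_factory=FlowModelParams)
    seed: int = 0
    out_dir: str | Path | None = None
    cbf_domain: str = "vessel"
    stats_policy: dict[str, str] | None = None


@dataclass
class AnimalResult:
    animal_id: str
    group: str
    coverage_pct: dict[str, float]
    thickness_summary: dict[str, dict]
    thickness_pixels: dict[str, np.ndarray]
    speed_pixels: dict[str, np.ndarray]
    mean_speed: dict[str, float]
    cbf: dict[str, float]
    avr: float
    nvc_table: pd.DataFrame
    nvc_curves: np.ndarray


def analyze_animal(
    animal: AnimalPhantom,
    flow_params: FlowModelParams = FlowModelParams(),
    cbf_domain: str = "vessel",
) -> AnimalResult:
    """Run every quantification stage on one animal's exports."""
    regions = animal.regions
    mask = binarize(animal.density)
    cov = coverage_table(mask, regions)

    tmap = apply_reliability_floor(
        local_thickness(mask), floor_radius_um=flow_params.floor_radius_um
    )
    speed = decode_speed(animal.speed, flow_params)
    fmap = flow_rate_map(speed, tmap, flow_params)
    dmap = classify_direction(animal.directional)

    thick_sum: dict[str, dict] = {}
    thick_px: dict[str, np.ndarray] = {}
    speed_px: dict[str, np.ndarray] = {}
    mean_speed: dict[str, float] = {}
    cbf: dict[str, float] = {}
    for name in ANALYSIS_REGIONS:
        sel = regions.mask(name)
        eligible = tmap.reliable_foreground() & sel
        thick_sum[name] = regional_thickness_summary(tmap, regions, name)
        thick_px[name] = tmap.values[eligible]
        vessel = mask.values & sel
        speed_px[name] = speed.values[vessel]
        mean_speed[name] = float(speed.values[vessel].mean())
        cbf[name] = regional_cbf(fmap, mask, regions, name, domain=cbf_domain)

    avr_res = compute_avr(dmap, regions, "cortex")
    nvc_table, nvc_curves = analyze_trace(animal.trace)
    return AnimalResult(
        animal_id=animal.animal_id,
        group=animal.group,
        coverage_pct=cov,
        thickness_summary=thick_sum,
        thickness_pixels=thick_px,
        speed_pixels=speed_px,
        mean_speed=mean_speed,
        cbf=cbf,
        avr=avr_res.avr,
        nvc_table=nvc_table,
        nvc_curves=nvc_curves,
    )


def _group_values(
    results: list[AnimalResult], getter, group: str
) -> list[float]:
    return [getter(r) for r in results if r.group == group]


def compare_cohort(
    results: list[AnimalResult],
    schedule: StimSchedule,
    policy: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Young-vs-aged comparison table over every pipeline metric.

    Animal-level metrics (coverage, regional CBF, mean speed, AVR) and
    per-response NVC metrics use the Student test; pixel-level thickness
    and speed distributions use Welch, per the default policy.
    """
    groups = ("young", "aged")
    rows: list[dict] = []

    def add(metric: str, young_vals, aged_vals) -> None:
        method = method_for_metric(metric, policy)
        res = compare_groups(young_vals, aged_vals, method)
        rows.append(summary_row(metric, groups, res))

    for name in ANALYSIS_REGIONS:
        add(
            f"coverage_{name}",
            _group_values(results, lambda r: r.coverage_pct[name], "young"),
            _group_values(results, lambda r: r.coverage_pct[name], "aged"),
        )
        add(
            f"cbf_{name}",
            _group_values(results, lambda r: r.cbf[name], "young"),
            _group_values(results, lambda r: r.cbf[name], "aged"),
        )
        # pixel-level distributions, pooled within group
        for metric, attr in (("thickness", "thickness_pixels"), ("speed", "speed_pixels")):
            young_px = np.concatenate(
                [getattr(r, attr)[name] for r in results if r.group == "young"]
            )
            aged_px = np.concatenate(
                [getattr(r, attr)[name] for r in results if r.group == "aged"]
            )
            add(f"{metric}_{name}", young_px, aged_px)

    add(
        "avr_cortex",
        _group_values(results, lambda r: r.avr, "young"),
        _group_values(results, lambda r: r.avr, "aged"),
    )

    nvc_all = pd.concat([r.nvc_table for r in results], ignore_index=True)
    for metric in ("average_response_pct", "peak_pct", "time_to_peak_s"):
        vals = nvc_all.dropna(subset=[metric])
        add(
            f"nvc_{metric}",
            vals.loc[vals["group"] == "young", metric],
            vals.loc[vals["group"] == "aged", metric],
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineReport:
    config: PipelineConfig
    results: list[AnimalResult]
    per_animal: pd.DataFrame
    comparisons: pd.DataFrame
    nvc_responses: pd.DataFrame
    nvc_curves: dict[str, pd.DataFrame]


def _per_animal_table(results: list[AnimalResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for name in ANALYSIS_REGIONS:
            rows.append(
                {
                    "animal_id": r.animal_id,
                    "group": r.group,
                    "region": name,
                    "coverage_pct": r.coverage_pct[name],
                    "mean_diameter_um": r.thickness_summary[name]["mean_diameter_um"],
                    "median_diameter_um": r.thickness_summary[name][
                        "median_diameter_um"
                    ],
                    "mean_speed_mm_s": r.mean_speed[name],
                    "cbf_ml_min": r.cbf[name],
                    "avr_cortex": r.avr if name == "cortex" else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Simulate (or load), quantify, and compare a full cohort.

    When ``config.out_dir`` is set, writes per_animal_metrics.csv,
    group_comparisons.csv, nvc_responses.csv, nvc_mean_curve_<group>.csv
    and manifest.json into it.
    """
    t0 = time.time()
    log.info("stage phantom: generating cohort (seed=%d)", config.seed)
    cohort: Cohort = simulate_cohort(config.cohort, seed=config.seed)

    results: list[AnimalResult] = []
    for animal in cohort.animals:
        t1 = time.time()
        results.append(analyze_animal(animal, config.flow, config.cbf_domain))
        log.info("stage quantify: %s done in %.1fs", animal.animal_id, time.time() - t1)

    per_animal = _per_animal_table(results)
    comparisons = compare_cohort(results, config.cohort.schedule, config.stats_policy)
    nvc_responses, nvc_curves = aggregate_responses(
        [r.nvc_table for r in results],
        [r.nvc_curves for r in results],
        config.cohort.schedule,
    )
    log.info("pipeline finished in %.1fs", time.time() - t0)

    report = PipelineReport(
        config=config,
        results=results,
        per_animal=per_animal,
        comparisons=comparisons,
        nvc_responses=nvc_responses,
        nvc_curves=nvc_curves,
    )
    if config.out_dir is not None:
        write_report(report, Path(config.out_dir))
    return report


def write_report(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.per_animal.to_csv(out_dir / "per_animal_metrics.csv", index=False)
    report.comparisons.to_csv(out_dir / "group_comparisons.csv", index=False)
    report.nvc_responses.to_csv(out_dir / "nvc_responses.csv", index=False)
    for group, curve in report.nvc_curves.items():
        curve.to_csv(out_dir / f"nvc_mean_curve_{group}.csv", index=False)
    manifest = {
        "package": "vasculomap",
        "version": __version__,
        "seed": report.config.seed,
        "n_young": report.config.cohort.n_young,
        "n_aged": report.config.cohort.n_aged,
        "grid_shape": list(report.config.cohort.grid_shape),
        "pixel_size_um": report.config.cohort.pixel_size_um,
        "cbf_domain": report.config.cbf_domain,
        "flow": asdict(report.config.flow),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
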