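"""Per-tumor hybrid-therapy analysis and cohort assembly.

For each tumor case the pipeline computes the ⁹⁰Y dose map once (local
deposition method), simulates every planned RF ablation, rebins the Ω ≥ 6.9
kill masks onto the dose grid, subtracts their union from the tumor mask
("unablated tumor"), and recomputes the dose metrics on the *same* dose map.
Cohort tables mirror the per-tumor layout: ablation-site counts, durations,
pre/post volumes, percent volume change, and pre/post metric summaries.

Percent volume change uses the post-ablation denominator,
100·(pre − post)/post, the convention under which the bundled reference
cohort's printed values reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import bioheat, dosimetry
from .bioheat import ElectrodeSpec, SimulationConfig
from .dosimetry import DoseMetrics, LdmConstants
from .grids import LabelMask, ScalarMap
from .planning import AblationPlan

__all__ = [
    "TumorCase",
    "CaseResult",
    "PipelineConfig",
    "apply_ablation",
    "run_case",
    "pct_volume_change",
    "cohort_table",
    "CohortTable",
    "make_zone_simulator",
]

METRIC_NAMES = ("d_avg", "d_max", "d50", "d70", "d90", "v100")


@dataclass
class TumorCase:
    """One tumor with its activity map, masks, plan, and tissue assignment."""

    case_id: str
    device: str  # 'resin' | 'glass'
    activity: ScalarMap  # Bq per voxel
    tumor: LabelMask
    organ_masks: dict[str, LabelMask] = field(default_factory=dict)
    plan: AblationPlan | None = None
    tissue: str = "hcc"  # preset name; normal_liver for non-HCC disease

    def __post_init__(self) -> None:
        if not self.tumor.grid.approx_equal(self.activity.grid):
            raise ValueError("tumor mask and activity map must share one grid")
        for name, m in self.organ_masks.items():
            if not m.grid.approx_equal(self.activity.grid):
                raise ValueError(f"organ mask {name!r} is not on the case grid")


@dataclass
class CaseResult:
    case_id: str
    n_sites: int
    durations_s: list[float]
    pre_metrics: DoseMetrics
    post_metrics: DoseMetrics
    pre_volume_cm3: float
    post_volume_cm3: float
    ablated_in_tumor_cm3: float
    pct_volume_change: float
    deltas: dict[str, float]
    pct_changes: dict[str, float]
    dose: ScalarMap | None = None
    zones: list[LabelMask] | None = None
    post_mask: LabelMask | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings: LDM constants plus the fidelity of the per-site
    thermal simulations (domain, spacing, time step)."""

    ldm: LdmConstants = LdmConstants()
    sim_spacing_mm: float = 2.0
    sim_domain_mm: tuple[float, float, float] = (80.0, 80.0, 120.0)
    sim_time_step_s: float = 2.0
    kill_occupancy: float = 0.5
    restrict_ablation_below_gy: float | None = None  # clip zones to sub-level tumor


def apply_ablation(
    tumor: LabelMask, zones: Sequence[LabelMask]
) -> tuple[LabelMask, float]:
    """Subtract the union of ablation zones from the tumor mask.

    Returns the unablated tumor mask and the ablated-in-tumor volume in cm³;
    overlapping zones are counted once.
    """
    union = np.zeros(tumor.values.shape, dtype=bool)
    for z in zones:
        if not z.grid.approx_equal(tumor.grid):
            raise ValueError("ablation zone is not on the tumor grid")
        union |= z.values
    post = LabelMask(tumor.grid, tumor.values & ~union)
    ablated_cm3 = (tumor.n_true - post.n_true) * tumor.grid.voxel_volume_mm3 / 1000.0
    return post, ablated_cm3


def pct_volume_change(pre_cm3: float, post_cm3: float) -> float:
    """Percent tumor-volume change, post-ablation denominator:
    100·(pre − post)/post."""
    if post_cm3 <= 0:
        raise ValueError("post-ablation volume must be > 0")
    return 100.0 * (pre_cm3 - post_cm3) / post_cm3


def make_zone_simulator(case: TumorCase, config: PipelineConfig):
    """Zone simulator handle for planning/pipeline use.

    Runs the full-duration thermal simulation once per electrode pose and
    serves shorter durations from the stored Ω snapshots (Ω only grows, so a
    snapshot at t is exactly the kill mask of a t-second run).
    """
    cache: dict[tuple, bioheat.AblationResult] = {}

    def simulate(electrode: ElectrodeSpec, duration_s: float) -> LabelMask:
        key = (electrode.tip_position, electrode.direction)
        if key not in cache:
            sim_cfg = SimulationConfig(
                domain_size=config.sim_domain_mm,
                grid_spacing=config.sim_spacing_mm,
                time_step=config.sim_time_step_s,
                duration=bioheat.SimulationConfig().max_duration,
            )
            cache[key] = bioheat.simulate_ablation(electrode, case.tissue, sim_cfg)
        return bioheat.ablation_zone_on_grid(
            cache[key], case.tumor.grid,
            occupancy=config.kill_occupancy, duration_s=duration_s)

    return simulate


def run_case(case: TumorCase, config: PipelineConfig = PipelineConfig(),
             zone_simulator=None) -> CaseResult:
    """Run the full analysis for one tumor.

    The dose map is computed once; pre- and post-ablation metrics come from
    the same map, the latter on tumor-minus-ablation only.  An empty plan
    leaves the post metrics identical to the pre metrics.
    """
    dose = dosimetry.ldm_dose(case.activity, config.ldm)
    pre_metrics = dosimetry.dose_metrics(dose, case.tumor)
    pre_volume = case.tumor.volume_cm3

    zones: list[LabelMask] = []
    durations: list[float] = []
    if case.plan is not None:
        simulate = zone_simulator or make_zone_simulator(case, config)
        for placement in case.plan.placements:
            zone = simulate(placement.electrode, placement.duration)
            if config.restrict_ablation_below_gy is not None:
                zone = LabelMask(
                    zone.grid,
                    zone.values & (dose.values < config.restrict_ablation_below_gy))
            zones.append(zone)
            durations.append(placement.duration)

    post_mask, ablated_cm3 = apply_ablation(case.tumor, zones)
    post_metrics = dosimetry.dose_metrics(dose, post_mask) if post_mask.n_true \
        else pre_metrics
    post_volume = post_mask.volume_cm3

    deltas = {
        m: getattr(post_metrics, m) - getattr(pre_metrics, m) for m in METRIC_NAMES
    }
    pct = {
        m: (100.0 * deltas[m] / getattr(pre_metrics, m)
            if getattr(pre_metrics, m) != 0 else float("nan"))
        for m in METRIC_NAMES
    }
    return CaseResult(
        case_id=case.case_id,
        n_sites=len(zones),
        durations_s=durations,
        pre_metrics=pre_metrics,
        post_metrics=post_metrics,
        pre_volume_cm3=pre_volume,
        post_volume_cm3=post_volume,
        ablated_in_tumor_cm3=ablated_cm3,
        pct_volume_change=pct_volume_change(pre_volume, post_volume)
        if post_volume > 0 else float("nan"),
        deltas=deltas,
        pct_changes=pct,
        dose=dose,
        zones=zones,
        post_mask=post_mask,
    )


@dataclass
class CohortTable:
    """Per-tumor rows plus the cohort summary."""

    rows: pd.DataFrame
    summary: dict[str, float]


def cohort_table(results: Sequence[CaseResult]) -> CohortTable:
    """Assemble per-tumor rows and cohort summary statistics.

    Summary entries: total ablation simulations (sum of site counts), mean
    pre−post volume difference, and mean/SD of every metric, its delta, and
    its percent change.
    """
    if not results:
        raise ValueError("at least one case result is required")
    rows = []
    for r in results:
        row = {
            "case_id": r.case_id,
            "n_sites": r.n_sites,
            "durations_s": "/".join(f"{d:.0f}" for d in r.durations_s),
            "pre_volume_cm3": r.pre_volume_cm3,
            "post_volume_cm3": r.post_volume_cm3,
            "ablated_in_tumor_cm3": r.ablated_in_tumor_cm3,
            "pct_volume_change": r.pct_volume_change,
        }
        for m in METRIC_NAMES:
            row[f"pre_{m}"] = getattr(r.pre_metrics, m)
            row[f"post_{m}"] = getattr(r.post_metrics, m)
            row[f"delta_{m}"] = r.deltas[m]
            row[f"pct_change_{m}"] = r.pct_changes[m]
        rows.append(row)
    df = pd.DataFrame(rows)

    summary: dict[str, float] = {
        "n_tumors": float(len(df)),
        "total_simulations": float(df["n_sites"].sum()),
        "mean_volume_difference_cm3": float(
            (df["pre_volume_cm3"] - df["post_volume_cm3"]).mean()),
        "mean_pct_volume_change": float(df["pct_volume_change"].mean()),
        "sd_pct_volume_change": float(df["pct_volume_change"].std(ddof=1))
        if len(df) > 1 else 0.0,
    }
    for col in [c for c in df.columns if c.startswith(("pre_", "post_", "delta_", "pct_change_"))
                and df[c].dtype != object]:
        summary[f"mean_{col}"] = float(df[col].mean())
        summary[f"sd_{col}"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
    return CohortTable(rows=df, summary=summary)
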