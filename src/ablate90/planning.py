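"""Electrode plans targeting under-dosed tumor under safety constraints.

A plan is up to four electrode placements of at most 600 s each.  Plans are
validated against the planning rules used for dose-guided ablation: keep the
predicted kill zone inside tumor that received less than the target isodose
where possible (soft), stay clear of spare organs such as the liver capsule
and gallbladder (hard on overlap), and keep the zone boundary at least 10 mm
from gastrointestinal tissue (hard).

``auto_plan`` is a deterministic convenience heuristic — clinical plans are
placed manually, and plans can always be supplied as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .bioheat import ElectrodeSpec
from .grids import LabelMask, ScalarMap

__all__ = [
    "ElectrodePlacement",
    "AblationPlan",
    "PlanConstraints",
    "PlacementReport",
    "ValidationReport",
    "cold_regions",
    "validate_plan",
    "auto_plan",
    "plan_to_json",
    "plan_from_json",
]

MAX_PLACEMENTS = 4
MAX_DURATION_S = 600.0


@dataclass(frozen=True)
class ElectrodePlacement:
    electrode: ElectrodeSpec
    duration: float  # s

    def __post_init__(self) -> None:
        if not 0 < self.duration <= MAX_DURATION_S:
            raise ValueError(f"duration must be in (0, {MAX_DURATION_S}] s")


@dataclass
class AblationPlan:
    placements: list[ElectrodePlacement]
    patient_id: str = ""
    tumor_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.placements) <= MAX_PLACEMENTS:
            raise ValueError(f"a plan holds 1–{MAX_PLACEMENTS} placements")


@dataclass(frozen=True)
class PlanConstraints:
    target_isodose: float = 100.0  # Gy; zones should sit below this (soft)
    gi_margin: float = 10.0  # mm, hard minimum distance to GI tissue
    gi_mask_name: str = "gi"

    def __post_init__(self) -> None:
        if self.gi_margin < 0:
            raise ValueError("margins must be >= 0")


@dataclass
class PlacementReport:
    index: int
    zone_volume_cm3: float
    fraction_outside_tumor: float
    fraction_over_isodose: float  # soft warning when > 0
    organ_distances_mm: dict[str, float]
    organ_overlap_cm3: dict[str, float]
    hard_violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    placements: list[PlacementReport]

    @property
    def ok(self) -> bool:
        return all(not p.hard_violations for p in self.placements)

    def as_dict(self) -> dict:
        return {
            "ok": self.ok,
            "placements": [
                {
                    "index": p.index,
                    "zone_volume_cm3": p.zone_volume_cm3,
                    "fraction_outside_tumor": p.fraction_outside_tumor,
                    "fraction_over_isodose": p.fraction_over_isodose,
                    "organ_distances_mm": p.organ_distances_mm,
                    "organ_overlap_cm3": p.organ_overlap_cm3,
                    "hard_violations": p.hard_violations,
                    "warnings": p.warnings,
                }
                for p in self.placements
            ],
        }


# ---------------------------------------------------------------------------


def cold_regions(
    dose: ScalarMap,
    tumor: LabelMask,
    level: float = 100.0,
    min_diameter: float = 20.0,
) -> list[LabelMask]:
    """Connected under-dosed tumor sub-volumes, largest first.

    A region qualifies when its minimum bounding-box edge is at least
    ``min_diameter`` mm (operationalizing "cold areas > 2 cm in size").
    """
    if tumor.n_true == 0:
        raise ValueError("tumor mask is empty")
    cold = tumor.values & (dose.values < level)
    labels, n = ndimage.label(cold)
    spacing = np.asarray(dose.grid.spacing)
    out: list[LabelMask] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        idx = np.nonzero(comp)
        extent = np.array([(idx[a].max() - idx[a].min() + 1) * spacing[a] for a in range(3)])
        if extent.min() >= min_diameter:
            out.append(LabelMask(dose.grid, comp))
    out.sort(key=lambda m: m.n_true, reverse=True)
    return out


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def min_surface_distance_mm(a: LabelMask, b: LabelMask) -> float:
    """Minimum Euclidean surface-to-surface distance between two masks (mm).

    Overlapping or touching masks give 0.
    """
    if a.n_true == 0 or b.n_true == 0:
        return float("inf")
    if (a.values & b.values).any():
        return 0.0
    dist_to_b = ndimage.distance_transform_edt(~b.values, sampling=a.grid.spacing)
    return float(dist_to_b[_surface(a.values)].min())


def validate_plan(
    plan: AblationPlan,
    predicted_zones: Sequence[LabelMask],
    dose: ScalarMap,
    tumor: LabelMask,
    organ_masks: dict[str, LabelMask] | None = None,
    constraints: PlanConstraints = PlanConstraints(),
) -> ValidationReport:
    """Check every placement's predicted kill zone against the plan rules."""
    if len(predicted_zones) != len(plan.placements):
        raise ValueError("one predicted zone per placement is required")
    organ_masks = organ_masks or {}
    hot = dose.values >= constraints.target_isodose
    reports = []
    for i, zone in enumerate(predicted_zones):
        if not zone.grid.approx_equal(dose.grid):
            raise ValueError(f"zone {i} is not on the dose grid")
        nz = zone.n_true
        outside = float((zone.values & ~tumor.values).sum() / nz) if nz else 0.0
        over = float((zone.values & hot).sum() / nz) if nz else 0.0
        dists: dict[str, float] = {}
        overlaps: dict[str, float] = {}
        hard: list[str] = []
        warn: list[str] = []
        for name, organ in organ_masks.items():
            d = min_surface_distance_mm(zone, organ)
            dists[name] = d
            ov = (zone & organ).volume_cm3
            overlaps[name] = ov
            if name == constraints.gi_mask_name:
                if d < constraints.gi_margin:
                    hard.append(
                        f"zone boundary {d:.1f} mm from '{name}' tissue "
                        f"(< {constraints.gi_margin:.0f} mm margin)")
            elif ov > 0:
                hard.append(f"zone overlaps spare tissue '{name}' by {ov:.2f} cm³")
        if over > 0:
            warn.append(
                f"{100 * over:.1f}% of zone lies over ≥{constraints.target_isodose:.0f} Gy tissue")
        if outside > 0:
            warn.append(f"{100 * outside:.1f}% of zone lies outside the tumor")
        reports.append(PlacementReport(
            index=i, zone_volume_cm3=zone.volume_cm3,
            fraction_outside_tumor=outside, fraction_over_isodose=over,
            organ_distances_mm=dists, organ_overlap_cm3=overlaps,
            hard_violations=hard, warnings=warn))
    return ValidationReport(reports)


# ---------------------------------------------------------------------------
# Automatic planning (heuristic)

_CANDIDATE_DIRECTIONS = (
    (0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 0.0, 0.0),
    (0.0, 0.0, -1.0), (0.0, -1.0, 0.0), (-1.0, 0.0, 0.0),
)
_CANDIDATE_DURATIONS = (600.0, 480.0, 360.0, 240.0, 120.0)

ZoneSimulator = Callable[[ElectrodeSpec, float], LabelMask]


def auto_plan(
    dose: ScalarMap,
    tumor: LabelMask,
    simulator: ZoneSimulator,
    organ_masks: dict[str, LabelMask] | None = None,
    constraints: PlanConstraints = PlanConstraints(),
    max_placements: int = MAX_PLACEMENTS,
    min_cold_diameter: float = 20.0,
    patient_id: str = "",
    tumor_id: str = "",
) -> tuple[AblationPlan | None, list[str]]:
    """Greedy electrode placement over cold regions.

    Each iteration targets the largest still-unserved cold region, placing
    the electrode through its centroid.  Candidate approach directions are
    the six axis directions (a stand-in for percutaneous access paths); the
    first direction and the longest duration whose predicted zone passes the
    hard constraints are kept.  Deterministic given its inputs.

    Returns ``(plan, reasons)``; ``plan`` is None with explanatory reasons
    when nothing feasible was found.
    """
    organ_masks = organ_masks or {}
    served = np.zeros(tumor.values.shape, dtype=bool)
    placements: list[ElectrodePlacement] = []
    zones: list[LabelMask] = []
    reasons: list[str] = []

    for it in range(max_placements):
        remaining = LabelMask(tumor.grid, tumor.values & ~served)
        if remaining.n_true == 0:
            break
        regions = cold_regions(dose, remaining, level=constraints.target_isodose,
                               min_diameter=min_cold_diameter)
        if not regions:
            if it == 0:
                reasons.append("no cold regions of the required size")
            break
        target = regions[0]
        idx = np.nonzero(target.values)
        spacing = np.asarray(tumor.grid.spacing)
        origin = np.asarray(tumor.grid.origin)
        centroid = origin + spacing * np.array([idx[a].mean() for a in range(3)])

        placed = False
        for direction in _CANDIDATE_DIRECTIONS:
            electrode = ElectrodeSpec(tip_position=tuple(centroid + 15.0 * np.asarray(direction)),
                                      direction=direction)
            try:
                full_zone = simulator(electrode, _CANDIDATE_DURATIONS[0])
            except ValueError as exc:  # e.g. tip outside the dose volume
                reasons.append(f"direction {direction}: {exc}")
                continue
            for duration in _CANDIDATE_DURATIONS:
                zone = full_zone if duration == _CANDIDATE_DURATIONS[0] \
                    else simulator(electrode, duration)
                trial = AblationPlan(placements=[ElectrodePlacement(electrode, duration)])
                report = validate_plan(trial, [zone], dose, tumor, organ_masks, constraints)
                if report.ok:
                    placements.append(ElectrodePlacement(electrode, duration))
                    zones.append(zone)
                    served |= zone.values | target.values
                    placed = True
                    break
            if placed:
                break
        if not placed:
            reasons.append(
                f"no feasible placement for cold region of {target.volume_cm3:.1f} cm³")
            served |= target.values  # do not retry the same region
    if not placements:
        return None, reasons or ["no feasible placement"]
    return AblationPlan(placements=placements, patient_id=patient_id, tumor_id=tumor_id), reasons


# ---------------------------------------------------------------------------
# JSON round trip


def plan_to_json(plan: AblationPlan, path: str | Path | None = None) -> str:
    payload = {
        "patient_id": plan.patient_id,
        "tumor_id": plan.tumor_id,
        "placements": [
            {
                "tip_mm": list(p.electrode.tip_position),
                "direction": list(p.electrode.direction),
                "duration_s": p.duration,
                "coolant_temp_c": p.electrode.coolant_temp,
            }
            for p in plan.placements
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def plan_from_json(source: str | Path) -> AblationPlan:
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        text = Path(source).read_text()
    else:
        text = str(source)
    payload = json.loads(text)
    placements = [
        ElectrodePlacement(
            electrode=ElectrodeSpec(
                tip_position=tuple(p["tip_mm"]),
                direction=tuple(p["direction"]),
                coolant_temp=p.get("coolant_temp_c", 25.0),
            ),
            duration=float(p["duration_s"]),
        )
        for p in payload["placements"]
    ]
    return AblationPlan(placements=placements,
                        patient_id=payload.get("patient_id", ""),
                        tumor_id=payload.get("tumor_id", ""))
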