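"""Cold-region extraction, plan validation, and greedy auto-planning."""

import numpy as np
import pytest

from ablate90.bioheat import ElectrodeSpec
from ablate90.grids import LabelMask, ScalarMap, VoxelGrid
from ablate90.planning import (
    AblationPlan,
    ElectrodePlacement,
    PlanConstraints,
    auto_plan,
    cold_regions,
    min_surface_distance_mm,
    plan_from_json,
    plan_to_json,
    validate_plan,
)


def case_grid(n=40, h=2.0):
    half = (n - 1) / 2 * h
    return VoxelGrid((n, n, n), (h, h, h), (-half, -half, -half))


def sphere(grid, center, radius):
    X, Y, Z = grid.center_coords()
    d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    return d2 <= radius**2


class TestColdRegions:
    def test_uniformly_hot_tumor_has_none(self):
        grid = case_grid()
        tumor = LabelMask(grid, sphere(grid, (0, 0, 0), 25.0))
        dose = ScalarMap(grid, np.full(grid.shape, 150.0))
        assert cold_regions(dose, tumor, level=100.0) == []

    def test_embedded_cold_sphere_recovered(self):
        grid = case_grid()
        tumor = LabelMask(grid, sphere(grid, (0, 0, 0), 30.0))
        dose = np.full(grid.shape, 150.0)
        cold = sphere(grid, (5.0, 0.0, 0.0), 12.5)  # 25 mm diameter
        dose[cold] = 40.0
        regions = cold_regions(ScalarMap(grid, dose), tumor, level=100.0)
        assert len(regions) == 1
        expected = 4 / 3 * np.pi * 12.5**3 / 1000.0
        assert regions[0].volume_cm3 == pytest.approx(expected, rel=0.1)

    def test_regions_sorted_largest_first(self):
        grid = case_grid()
        tumor = LabelMask(grid, sphere(grid, (0, 0, 0), 35.0))
        dose = np.full(grid.shape, 150.0)
        dose[sphere(grid, (-15.0, 0, 0), 11.0)] = 10.0
        dose[sphere(grid, (16.0, 0, 0), 14.0)] = 10.0
        regions = cold_regions(ScalarMap(grid, dose), tumor, level=100.0)
        assert len(regions) == 2
        assert regions[0].n_true > regions[1].n_true

    def test_small_regions_filtered_by_bounding_box(self):
        grid = case_grid()
        tumor = LabelMask(grid, sphere(grid, (0, 0, 0), 30.0))
        dose = np.full(grid.shape, 150.0)
        dose[sphere(grid, (0, 0, 0), 7.0)] = 10.0  # 14 mm < 20 mm criterion
        assert cold_regions(ScalarMap(grid, dose), tumor, min_diameter=20.0) == []


class TestDistances:
    def test_matches_brute_force_all_pairs(self, rng):
        grid = VoxelGrid((16, 16, 16), (2.0, 2.0, 2.0))
        a = np.zeros(grid.shape, bool)
        b = np.zeros(grid.shape, bool)
        a[2:5, 2:5, 2:5] = True
        b[rng.integers(8, 14), rng.integers(8, 14), rng.integers(8, 14)] = True
        ma, mb = LabelMask(grid, a), LabelMask(grid, b)
        pa = np.argwhere(a) * 2.0
        pb = np.argwhere(b) * 2.0
        brute = min(np.linalg.norm(x - y) for x in pa for y in pb)
        assert min_surface_distance_mm(ma, mb) == pytest.approx(brute)

    def test_overlap_gives_zero(self):
        grid = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0))
        m = LabelMask(grid, np.ones(grid.shape, bool))
        assert min_surface_distance_mm(m, m) == 0.0


class TestValidatePlan:
    def setup_case(self):
        grid = case_grid()
        tumor = LabelMask(grid, sphere(grid, (0, 0, 0), 30.0))
        dose = np.full(grid.shape, 50.0)  # everything under-dosed
        gi = LabelMask(grid, sphere(grid, (-36.0, 0, 0), 4.0))
        gb = LabelMask(grid, sphere(grid, (36.0, 0, 0), 4.0))
        plan = AblationPlan([ElectrodePlacement(
            ElectrodeSpec(tip_position=(0.0, 0.0, 15.0)), 600.0)])
        return grid, tumor, ScalarMap(grid, dose), gi, gb, plan

    def test_compliant_zone_has_no_violations(self):
        grid, tumor, dose, gi, gb, plan = self.setup_case()
        zone = LabelMask(grid, sphere(grid, (0, 0, 0), 10.0))
        rep = validate_plan(plan, [zone], dose, tumor, {"gi": gi, "gallbladder": gb})
        assert rep.ok
        assert rep.placements[0].fraction_outside_tumor == 0.0

    def test_gi_margin_violation_is_hard(self):
        grid, tumor, dose, gi, gb, plan = self.setup_case()
        zone = LabelMask(grid, sphere(grid, (-28.0, 0, 0), 4.0))  # ~4 mm from GI
        rep = validate_plan(plan, [zone], dose, tumor, {"gi": gi})
        assert not rep.ok
        assert "margin" in rep.placements[0].hard_violations[0]

    def test_spare_tissue_overlap_is_hard(self):
        grid, tumor, dose, gi, gb, plan = self.setup_case()
        zone = LabelMask(grid, sphere(grid, (33.0, 0, 0), 6.0))
        rep = validate_plan(plan, [zone], dose, tumor, {"gallbladder": gb})
        assert not rep.ok
        assert "gallbladder" in rep.placements[0].hard_violations[0]

    def test_over_isodose_is_soft_warning(self):
        grid, tumor, dose, gi, gb, plan = self.setup_case()
        hot = dose.values.copy()
        hot[sphere(grid, (0, 0, 0), 6.0)] = 150.0
        zone = LabelMask(grid, sphere(grid, (0, 0, 0), 10.0))
        rep = validate_plan(plan, [zone], ScalarMap(grid, hot), tumor)
        assert rep.ok
        assert rep.placements[0].fraction_over_isodose > 0
        assert rep.placements[0].warnings


def stub_simulator(grid):
    """Deterministic ellipsoid ablation zone around the electrode tip."""

    def simulate(electrode: ElectrodeSpec, duration_s: float) -> LabelMask:
        mid = np.asarray(electrode.tip_position) - \
            0.5 * electrode.active_length * np.asarray(electrode.direction)
        radius = 8.0 + 8.0 * duration_s / 600.0
        return LabelMask(grid, sphere(grid, mid, radius))

    return simulate


class TestAutoPlan:
    def make_inputs(self):
        grid = case_grid()
        tumor = LabelMask(grid, sphere(grid, (0, 0, 0), 32.0))
        dose = np.full(grid.shape, 150.0)
        dose[sphere(grid, (0.0, 0.0, 0.0), 13.0)] = 20.0
        return grid, tumor, ScalarMap(grid, dose)

    def test_tip_near_cold_centroid(self):
        grid, tumor, dose = self.make_inputs()
        plan, reasons = auto_plan(dose, tumor, stub_simulator(grid))
        assert plan is not None and len(plan.placements) >= 1
        tip = np.asarray(plan.placements[0].electrode.tip_position)
        direction = np.asarray(plan.placements[0].electrode.direction)
        mid = tip - 15.0 * direction
        assert np.linalg.norm(mid) <= 5.0  # cold region centered at origin

    def test_no_cold_regions_gives_empty_plan(self):
        grid, tumor, _ = self.make_inputs()
        hot = ScalarMap(grid, np.full(grid.shape, 150.0))
        plan, reasons = auto_plan(hot, tumor, stub_simulator(grid))
        assert plan is None
        assert reasons

    def test_deterministic(self):
        grid, tumor, dose = self.make_inputs()
        p1, _ = auto_plan(dose, tumor, stub_simulator(grid))
        p2, _ = auto_plan(dose, tumor, stub_simulator(grid))
        assert plan_to_json(p1) == plan_to_json(p2)

    def test_limits_respected(self):
        grid = case_grid()
        tumor = LabelMask(grid, sphere(grid, (0, 0, 0), 36.0))
        dose = ScalarMap(grid, np.full(grid.shape, 20.0))  # everything cold
        plan, _ = auto_plan(dose, tumor, stub_simulator(grid))
        assert plan is not None
        assert len(plan.placements) <= 4
        assert all(p.duration <= 600.0 for p in plan.placements)


class TestPlanJson:
    def test_round_trip(self, tmp_path):
        plan = AblationPlan(
            [ElectrodePlacement(ElectrodeSpec((1.0, 2.0, 3.0), (0.0, 1.0, 0.0)), 420.0)],
            patient_id="p1", tumor_id="t1")
        path = tmp_path / "plan.json"
        plan_to_json(plan, path)
        back = plan_from_json(path)
        assert back.patient_id == "p1"
        assert back.placements[0].duration == 420.0
        assert np.allclose(back.placements[0].electrode.tip_position, (1, 2, 3))

    def test_duration_bounds_enforced(self):
        with pytest.raises(ValueError):
            ElectrodePlacement(ElectrodeSpec((0, 0, 0)), 601.0)
        with pytest.raises(ValueError):
            AblationPlan([])
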