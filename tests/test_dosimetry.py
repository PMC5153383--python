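"""Local-deposition dosimetry, DVHs, dose metrics, and decay timing."""

import math

import numpy as np
import pytest

from ablate90.dosimetry import (
    DoseMetrics,
    LdmConstants,
    dose_fraction_delivered,
    dose_metrics,
    dvh,
    eligibility,
    isodose_mask,
    ldm_dose,
)
from ablate90.grids import LabelMask, ScalarMap, VoxelGrid
from conftest import small_grid


def oracle_metrics(doses: np.ndarray) -> DoseMetrics:
    """Independent sort-and-index implementation of the rank definition."""
    vals = np.array(sorted(doses, reverse=True))
    n = len(vals)

    def dxx(p):
        return vals[math.ceil(p / 100 * n) - 1]

    return DoseMetrics(
        d_avg=vals.mean(), d_max=vals[0], d50=dxx(50), d70=dxx(70), d90=dxx(90),
        v100=100.0 * np.sum(vals > 100.0) / n)


class TestLdmDose:
    def test_one_gbq_in_one_kg_gives_the_ldm_constant(self):
        # 1000 voxels of 1 cm3 at 1000 kg/m3 => exactly 1 kg of tissue
        grid = VoxelGrid((10, 10, 10), (10.0, 10.0, 10.0))
        constants = LdmConstants(tissue_density=1000.0)
        act = ScalarMap(grid, np.full(grid.shape, 1e9 / 1000.0), units="Bq")
        dose = ldm_dose(act, constants)
        assert np.allclose(dose.values, constants.gy_per_gbq_per_kg)

    def test_zero_activity_zero_dose(self):
        grid = small_grid((4, 4, 4))
        dose = ldm_dose(ScalarMap(grid, np.zeros(grid.shape)))
        assert not dose.values.any()

    def test_linearity(self, rng):
        grid = small_grid((5, 5, 5))
        a = rng.random(grid.shape) * 1e6
        d1 = ldm_dose(ScalarMap(grid, a))
        d2 = ldm_dose(ScalarMap(grid, 2 * a))
        assert np.allclose(d2.values, 2 * d1.values)

    def test_negative_activity_rejected(self):
        grid = small_grid((2, 2, 2))
        with pytest.raises(ValueError):
            ldm_dose(ScalarMap(grid, np.full(grid.shape, -1.0)))

    def test_energy_bookkeeping(self, rng):
        # sum(dose * voxel mass) == C * total activity in GBq
        grid = small_grid((8, 8, 8))
        constants = LdmConstants()
        act = ScalarMap(grid, rng.random(grid.shape) * 1e7)
        dose = ldm_dose(act, constants)
        voxel_mass = constants.tissue_density * grid.voxel_volume_mm3 * 1e-9
        total_energy = float(np.sum(dose.values * voxel_mass))
        expected = constants.gy_per_gbq_per_kg * float(act.values.sum()) * 1e-9
        assert total_energy == pytest.approx(expected, rel=1e-9)


class TestDoseMetrics:
    def test_uniform_tumor(self):
        grid = small_grid((4, 4, 4))
        dose = ScalarMap(grid, np.full(grid.shape, 120.0))
        m = dose_metrics(dose, LabelMask(grid, np.ones(grid.shape, bool)))
        assert (m.d50, m.d70, m.d90, m.d_avg, m.d_max) == (120,) * 5
        assert m.v100 == 100.0

    def test_two_voxel_tumor_rank_definition(self):
        grid = VoxelGrid((2, 1, 1), (2.0, 2.0, 2.0))
        dose = ScalarMap(grid, np.array([50.0, 150.0]).reshape(2, 1, 1))
        m = dose_metrics(dose, LabelMask(grid, np.ones((2, 1, 1), bool)))
        assert m.d_avg == 100.0
        assert m.d50 == 150.0
        assert m.d70 == 50.0
        assert m.d90 == 50.0
        assert m.v100 == 50.0

    def test_matches_independent_oracle(self, random_dose, full_mask):
        m = dose_metrics(random_dose, full_mask)
        o = oracle_metrics(random_dose.values.ravel())
        for f in ("d_avg", "d_max", "d50", "d70", "d90", "v100"):
            assert getattr(m, f) == pytest.approx(getattr(o, f))

    def test_metric_ordering_invariants(self, random_dose, full_mask):
        m = dose_metrics(random_dose, full_mask)
        assert m.d90 <= m.d70 <= m.d50 <= m.d_max
        assert m.d_avg <= m.d_max
        assert 0 <= m.v100 <= 100

    def test_empty_mask_rejected(self, random_dose):
        empty = LabelMask(random_dose.grid, np.zeros(random_dose.grid.shape, bool))
        with pytest.raises(ValueError, match="no voxels"):
            dose_metrics(random_dose, empty)

    def test_lower_set_removal_improves_all_metrics(self, rng):
        # removing the coldest voxels can only raise every summary metric
        grid = small_grid((10, 10, 10))
        dose = ScalarMap(grid, rng.gamma(2.0, 60.0, grid.shape))
        full = LabelMask(grid, np.ones(grid.shape, bool))
        before = dose_metrics(dose, full)
        cut = np.quantile(dose.values, 0.2)
        reduced = LabelMask(grid, dose.values > cut)
        after = dose_metrics(dose, reduced)
        for f in ("d_avg", "d50", "d70", "d90", "v100"):
            assert getattr(after, f) >= getattr(before, f) - 1e-12
        assert after.d_max == before.d_max


class TestDvh:
    def test_uniform_field_is_step_function(self):
        grid = small_grid((4, 4, 4))
        dose = ScalarMap(grid, np.full(grid.shape, 42.0))
        h = dvh(dose, LabelMask(grid, np.ones(grid.shape, bool)), bin_width=1.0)
        assert h.cumulative_fraction[0] == 100.0
        assert h.volume_fraction_at(42.0) == 100.0
        assert h.volume_fraction_at(43.0) == 0.0

    def test_matches_direct_voxel_counting(self, random_dose, full_mask):
        h = dvh(random_dose, full_mask, bin_width=1.0)
        vals = random_dose.values.ravel()
        for edge, frac in zip(h.dose_edges[1:], h.cumulative_fraction[1:]):
            expected = 100.0 * np.sum(vals >= edge) / vals.size
            assert frac == pytest.approx(expected)

    def test_disjoint_masks_mix_by_volume(self, rng):
        grid = small_grid((8, 8, 8))
        dose = ScalarMap(grid, rng.random(grid.shape) * 200.0)
        a = np.zeros(grid.shape, bool)
        b = np.zeros(grid.shape, bool)
        a[:4], b[4:] = True, True
        ha = dvh(dose, LabelMask(grid, a), 5.0)
        hb = dvh(dose, LabelMask(grid, b), 5.0)
        hab = dvh(dose, LabelMask(grid, a | b), 5.0)
        for edge in np.arange(0.0, 200.0, 5.0):
            mix = 0.5 * ha.volume_fraction_at(edge) + 0.5 * hb.volume_fraction_at(edge)
            assert hab.volume_fraction_at(edge) == pytest.approx(mix)

    def test_dvh_v100_consistent_with_metrics(self, random_dose, full_mask):
        m = dose_metrics(random_dose, full_mask)
        h = dvh(random_dose, full_mask, bin_width=1.0)
        assert abs(h.volume_fraction_at(100.0 + 1.0) - m.v100) <= \
            100.0 / full_mask.n_true * (np.sum(
                (random_dose.values > 100) & (random_dose.values < 101)) + 1)


class TestEligibility:
    @pytest.mark.parametrize("device,d70,expected", [
        ("resin", 99.9, True),
        ("resin", 100.0, False),   # strict inequality at the limit
        ("glass", 120.0, True),
        ("glass", 150.0, False),
    ])
    def test_inclusion_rule(self, device, d70, expected):
        m = DoseMetrics(d_avg=d70, d_max=d70, d50=d70, d70=d70, d90=d70, v100=0.0)
        assert eligibility(m, device) is expected

    def test_unknown_device_rejected(self):
        m = DoseMetrics(1, 1, 1, 1, 1, 0)
        with pytest.raises(ValueError, match="device"):
            eligibility(m, "steel")


class TestIsodose:
    def test_level_zero_is_whole_grid(self, random_dose):
        assert isodose_mask(random_dose, 0.0).values.all()

    def test_levels_nest(self, random_dose):
        m100 = isodose_mask(random_dose, 100.0)
        m120 = isodose_mask(random_dose, 120.0)
        m150 = isodose_mask(random_dose, 150.0)
        assert not (m120.values & ~m100.values).any()
        assert not (m150.values & ~m120.values).any()

    def test_count_matches_brute_force(self, random_dose):
        level = 80.0
        assert isodose_mask(random_dose, level).n_true == int(
            np.sum(random_dose.values >= level))


class TestDecayTiming:
    def test_boundary_values(self):
        assert dose_fraction_delivered(0.0) == 0.0
        assert dose_fraction_delivered(64.05) == pytest.approx(0.5)

    def test_two_weeks_delivers_about_97_5_percent(self):
        frac = dose_fraction_delivered(336.0)
        assert abs(frac - 0.975) < 0.002  # closed form gives ~97.4%

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dose_fraction_delivered(-1.0)
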