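"""Cumulative DVH and functional dose-volume vector extraction."""

import numpy as np
import pytest

from ventidose.dvh import (
    FV_DOSE_LEVELS,
    FvVector,
    cumulative_dvh,
    extract_fv_vector,
    volume_at_dose,
)
from ventidose.grids import DoseGrid, StructureMask
from ventidose.phantom import PhantomSpec, generate_dose_grid


def _mask(shape, spacing=(2, 2, 2), full=True):
    inside = np.ones(shape, bool) if full else np.zeros(shape, bool)
    return StructureMask(inside=inside, spacing=spacing, name="fLung")


def _dose(values, spacing=(2, 2, 2)):
    return DoseGrid(dose=np.asarray(values, float), spacing=spacing)


class TestCumulativeDvh:
    def test_uniform_dose_is_step_function(self):
        dose = _dose(np.full((6, 6, 6), 30.0))
        curve = cumulative_dvh(dose, _mask((6, 6, 6)))
        below = curve.bin_edges <= 30.0
        assert np.all(curve.cumulative_percent[below] == 100.0)
        assert np.all(curve.cumulative_percent[~below] == 0.0)

    def test_two_level_dose_half_volume_at_midpoint(self):
        vals = np.full((6, 6, 6), 10.0)
        vals[:3] = 40.0
        curve = cumulative_dvh(_dose(vals), _mask((6, 6, 6)))
        assert curve.at(20.0) == pytest.approx(50.0)

    def test_linear_ramp_matches_analytic_line(self):
        n = 120
        ramp = np.linspace(0.0, 60.0, n).reshape(n, 1, 1) * np.ones((1, 4, 4))
        curve = cumulative_dvh(_dose(ramp), _mask((n, 4, 4)), bin_width=0.1)
        sel = curve.bin_edges <= 60.0
        analytic = 100.0 * (1.0 - curve.bin_edges[sel] / 60.0)
        # within one bin width of the analytic line (ramp quantization)
        assert np.max(np.abs(curve.cumulative_percent[sel] - analytic)) <= 100.0 / n + 0.1 * 100.0 / 60.0

    def test_curve_starts_at_100_and_ends_at_zero(self):
        rng = np.random.default_rng(0)
        dose = _dose(rng.uniform(0, 55, (8, 8, 8)))
        curve = cumulative_dvh(dose, _mask((8, 8, 8)))
        assert curve.cumulative_percent[0] == 100.0
        assert curve.cumulative_percent[-1] == 0.0
        assert np.all(np.diff(curve.cumulative_percent) <= 0)

    def test_mean_dose_identity_within_one_bin(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 60, (10, 10, 10))
        mask = _mask((10, 10, 10))
        bw = 0.1
        curve = cumulative_dvh(_dose(vals), mask, bin_width=bw)
        integral = bw * np.sum(curve.cumulative_percent / 100.0)
        assert abs(integral - vals.mean()) <= bw

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cumulative_dvh(_dose(np.zeros((4, 4, 4))), _mask((4, 4, 4), full=False))


class TestVolumeAtDose:
    def test_v0_is_always_100(self):
        rng = np.random.default_rng(2)
        dose = _dose(rng.uniform(0, 60, (6, 6, 6)))
        assert volume_at_dose(dose, _mask((6, 6, 6)), 0.0) == 100.0

    def test_uniform_22gy_thresholds(self):
        dose = _dose(np.full((6, 6, 6), 22.0))
        mask = _mask((6, 6, 6))
        assert volume_at_dose(dose, mask, 20.0) == 100.0
        assert volume_at_dose(dose, mask, 22.0) == 100.0  # inclusive ">="
        assert volume_at_dose(dose, mask, 25.0) == 0.0

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_equals_brute_force_count(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 65, (7, 6, 5))
        inside = rng.random((7, 6, 5)) < 0.5
        inside[0, 0, 0] = True
        mask = StructureMask(inside=inside, spacing=(2, 2, 2))
        for level in (5.0, 17.3, 40.0):
            count = sum(
                1
                for i in range(7)
                for j in range(6)
                for k in range(5)
                if inside[i, j, k] and vals[i, j, k] >= level
            )
            expected = 100.0 * count / inside.sum()
            assert volume_at_dose(_dose(vals), mask, level) == expected

    def test_absolute_cc_output(self):
        vals = np.full((10, 10, 10), 22.0)
        mask = _mask((10, 10, 10), spacing=(10, 10, 10))  # 1 cc voxels
        assert volume_at_dose(_dose(vals, (10, 10, 10)), mask, 20.0, absolute_cc=True) == pytest.approx(1000.0)


class TestFvVector:
    def test_uniform_22gy_pattern(self):
        fv = extract_fv_vector(_dose(np.full((6, 6, 6), 22.0)), _mask((6, 6, 6)))
        for level in (5, 10, 15, 20):
            assert fv[level] == 100.0
        for level in (25, 30, 35, 40, 45, 50, 55, 60):
            assert fv[level] == 0.0

    def test_zero_dose_gives_zero_vector(self):
        fv = extract_fv_vector(_dose(np.zeros((6, 6, 6))), _mask((6, 6, 6)))
        assert all(fv[x] == 0.0 for x in FV_DOSE_LEVELS)

    def test_phantom_dose_equals_brute_force_counts(self):
        spec = PhantomSpec()
        dose = generate_dose_grid(spec, spec.lung_geometry[0].center, 60.0, 40.0)
        rng = np.random.default_rng(6)
        inside = rng.random(spec.grid_shape) < 0.3
        inside[10, 10, 10] = True
        mask = StructureMask(inside=inside, spacing=spec.spacing)
        fv = extract_fv_vector(dose, mask)
        d = dose.dose[inside]
        for level in FV_DOSE_LEVELS:
            assert fv[level] == 100.0 * np.sum(d >= level) / d.size

    def test_vector_is_monotone_for_any_dose(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            dose = _dose(rng.uniform(0, 70, (6, 6, 6)))
            fv = extract_fv_vector(dose, _mask((6, 6, 6)))
            vals = [fv[x] for x in FV_DOSE_LEVELS]
            assert vals == sorted(vals, reverse=True)

    def test_resolution_doubling_changes_vx_below_one_percent(self):
        coarse_spec = PhantomSpec(grid_shape=(40, 40, 40), spacing=(4.0, 4.0, 4.0))
        # same physical extent sampled twice as finely
        fine_spec = PhantomSpec(
            grid_shape=(79, 79, 79),
            spacing=(2.0, 2.0, 2.0),
            lung_geometry=coarse_spec.lung_geometry,
        )
        target = coarse_spec.lung_geometry[0].center
        left = coarse_spec.lung_geometry[0]
        for spec in (coarse_spec, fine_spec):
            dose = generate_dose_grid(spec, target, 60.0, 40.0)
            pts = dose.world_grid()
            inside = left.radius(pts) <= 1.0
            mask = StructureMask(inside=inside, spacing=spec.spacing)
            fv = extract_fv_vector(dose, mask)
            if spec is coarse_spec:
                coarse = fv
            else:
                fine = fv
        for level in FV_DOSE_LEVELS:
            assert abs(coarse[level] - fine[level]) < 1.0

    def test_invalid_vector_rejected(self):
        increasing = {x: float(x) for x in FV_DOSE_LEVELS}
        with pytest.raises(ValueError, match="non-increasing"):
            FvVector(v=increasing)
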