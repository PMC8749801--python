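"""Metric definitions on hand-built inputs with known answers."""

import numpy as np
import pytest

from pmbat import (
    DepthCurve,
    VoxelGrid,
    dose_reduction,
    dvh,
    dvh_spread,
    global_uncertainty,
    integral_dose,
    lateral_profile,
    mean_letd,
    pvdr,
)
from pmbat.metrics import LateralProfile


class _StubSampler:
    """Duck-typed sampler with an analytic dose field (for profile tests)."""

    def __init__(self, fn, radius=80.0, slits=(-4.0, 0.0, 4.0)):
        self._fn = fn

        class _Ph:
            pass

        class _Coll:
            ctc = 4.0

        class _Field:
            collimated = True
            collimator = _Coll()

        class _Plan:
            pass

        self.phantom = _Ph()
        self.phantom.radius = radius
        f = _Field()
        f.slits = tuple(slits)
        self.plan = _Plan()
        self.plan.fields = (f,)

    def dose_at(self, pts):
        pts = np.atleast_2d(pts)
        return self._fn(pts[:, 0])


class TestLateralProfileAndPVDR:
    def test_flat_profile_has_pvdr_one(self):
        s = _StubSampler(lambda x: np.full_like(x, 3.0))
        prof = lateral_profile(s, 10.0)
        assert prof.is_flat
        assert pvdr(prof) == 1.0

    def test_synthetic_comb_recovers_positions_and_ratio(self):
        # cosine comb with period 4: peaks 10 at slit centers, valleys 2
        s = _StubSampler(lambda x: 6.0 + 4.0 * np.cos(2 * np.pi * x / 4.0))
        prof = lateral_profile(s, 10.0)
        np.testing.assert_allclose(sorted(prof.peak_positions), [-4.0, 0.0, 4.0],
                                   atol=0.02)
        np.testing.assert_allclose(sorted(prof.valley_positions), [-2.0, 2.0],
                                   atol=0.02)
        assert pvdr(prof) == pytest.approx(5.0, rel=1e-3)

    def test_peaks_and_valleys_alternate(self, case1_samplers):
        prof = lateral_profile(case1_samplers["pmbrt"], 20.0)
        merged = np.sort(np.concatenate([prof.peak_positions,
                                         prof.valley_positions]))
        kinds = [
            "p" if p in prof.peak_positions else "v" for p in merged
        ]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_zero_valley_is_an_error(self):
        prof = LateralProfile(
            positions=np.linspace(-4, 4, 9),
            dose=np.array([0, 1, 0, 1, 2.0, 1, 0, 1, 0]),
            depth=5.0,
            peak_positions=np.array([0.0]),
            peak_doses=np.array([2.0]),
            valley_positions=np.array([-2.0, 2.0]),
            valley_doses=np.array([0.0, 0.0]),
        )
        with pytest.raises(ValueError, match="valley"):
            pvdr(prof)


class TestDoseReduction:
    def test_identical_curves_give_zero(self):
        a = DepthCurve(np.arange(0, 10.0), np.full(10, 2.0))
        red = dose_reduction(a, a)
        np.testing.assert_allclose(red.values, 0.0)

    def test_zero_comparison_gives_100(self):
        a = DepthCurve(np.arange(0, 10.0), np.full(10, 2.0))
        b = DepthCurve(np.arange(0, 10.0), np.zeros(10))
        np.testing.assert_allclose(dose_reduction(a, b).values, 100.0)

    def test_zero_reference_masked(self):
        a = DepthCurve(np.arange(0, 4.0), np.array([1.0, 0.0, 2.0, 4.0]))
        b = DepthCurve(np.arange(0, 4.0), np.array([0.5, 1.0, 1.0, 1.0]))
        red = dose_reduction(a, b)
        assert np.isnan(red.values[1])
        np.testing.assert_allclose(red.values[[0, 2, 3]], [50.0, 50.0, 75.0])

    def test_comparison_resampled_onto_reference(self):
        a = DepthCurve(np.arange(0, 10.0), np.full(10, 4.0))
        b = DepthCurve(np.arange(0, 19.0) / 2.0, np.full(19, 1.0))
        np.testing.assert_allclose(dose_reduction(a, b).values, 75.0)

    def test_depths_must_increase(self):
        with pytest.raises(ValueError):
            DepthCurve(np.array([0.0, 2.0, 1.0]), np.zeros(3))


def _uniform_grid(value, dims=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(origin=np.zeros(3), spacing=spacing,
                     values=np.full(dims, float(value)))


class TestDVH:
    def test_uniform_dose_is_a_rectangle(self):
        g = _uniform_grid(1.0)
        mask = np.ones(g.dims, bool)
        curve = dvh(g, mask)
        assert curve.volume_fraction[0] == 1.0
        np.testing.assert_allclose(curve.volume_fraction[:-1], 1.0)
        assert curve.d_at_volume(0.5) == pytest.approx(1.0, abs=0.01)

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(5)
        g = VoxelGrid(np.zeros(3), np.ones(3), rng.random((6, 6, 6)))
        curve = dvh(g, np.ones(g.dims, bool))
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
        assert len(curve.thresholds) >= 256

    def test_empty_mask_rejected(self):
        g = _uniform_grid(1.0)
        with pytest.raises(ValueError, match="empty"):
            dvh(g, np.zeros(g.dims, bool))

    def test_spread_measures_steepness(self):
        flat = dvh(_uniform_grid(1.0), np.ones((4, 4, 4), bool))
        rng = np.random.default_rng(6)
        wide = dvh(
            VoxelGrid(np.zeros(3), np.ones(3), 1 + 0.5 * rng.standard_normal((6, 6, 6))),
            np.ones((6, 6, 6), bool),
        )
        assert dvh_spread(wide) > dvh_spread(flat)


class TestIntegralDose:
    def test_uniform_dose_gives_volume(self):
        g = _uniform_grid(1.0, spacing=(0.5, 1.0, 2.0))
        mask = np.ones(g.dims, bool)
        assert integral_dose(g, mask) == pytest.approx(64 * 1.0)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(7)
        g = VoxelGrid(np.zeros(3), np.ones(3), rng.random((5, 5, 5)))
        m1 = np.zeros(g.dims, bool)
        m1[:2] = True
        m2 = ~m1
        assert integral_dose(g, m1) + integral_dose(g, m2) == pytest.approx(
            integral_dose(g, np.ones(g.dims, bool))
        )


class TestMeanLET:
    def test_uniform_let_returned_exactly(self):
        d = np.array([0.5, 1.0, 2.0])
        assert mean_letd(d, np.full(3, 7.0)) == pytest.approx(7.0)

    def test_dose_weighted_examples(self):
        assert mean_letd(np.array([1.0, 3.0]), np.array([4.0, 2.0])) == 2.5
        assert mean_letd(np.array([3.0, 1.0]), np.array([2.0, 6.0])) == 3.0

    def test_arithmetic_alternative(self):
        assert mean_letd(np.array([1.0, 3.0]), np.array([4.0, 2.0]),
                         weighting="arithmetic") == 3.0

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError, match="zero total dose"):
            mean_letd(np.zeros(3), np.ones(3))


class TestGlobalUncertainty:
    def test_needs_two_realizations(self):
        with pytest.raises(ValueError):
            global_uncertainty([np.ones((2, 2, 2))])

    def test_known_ensemble_value(self):
        a = np.full((2, 2, 2), 1.1)
        b = np.full((2, 2, 2), 0.9)
        # per-voxel std(ddof=1) of {1.1, 0.9} is 0.1414, mean 1.0
        assert global_uncertainty([a, b]) == pytest.approx(np.sqrt(0.02), rel=1e-6)
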