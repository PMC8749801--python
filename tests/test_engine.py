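"""Dose engine: superposition, geometry invariances, scoring, noise."""

import numpy as np
import pytest

from pmbat import (
    DoseSampler,
    GridSpec,
    MinibeamCollimator,
    add_stochastic_noise,
    build_sobp,
    global_uncertainty,
    make_arc_plan,
    normalize_to_ptv_mean,
    ptv_sample_points,
)
from pmbat.geometry import FieldFrame
from pmbat.metrics import lateral_profile, pvdr

SLITS7 = tuple(4.0 * (np.arange(7) - 3.0))


def _layers():
    return build_sobp(104.8, 124.8)


def _single_array_plan(angle=0.0, weight_scale=1.0, n_fields=1, sep=0.0):
    plan = make_arc_plan(
        n_fields,
        sep,
        collimator=MinibeamCollimator(),
        arc_center_angle=angle,
        scan_extent_y=24.0,
        slits=SLITS7,
        layers=_layers(),
    )
    return plan if weight_scale == 1.0 else plan.scaled(weight_scale)


def test_zero_outside_body_and_upstream(phantom):
    s = DoseSampler(_single_array_plan(), phantom)
    pts = np.array([[0.0, 0.0, 85.0], [0.0, 0.0, -90.0], [0.0, 70.0, 50.0]])
    np.testing.assert_array_equal(s.dose_at(pts), 0.0)


def test_two_half_weight_fields_equal_one(phantom):
    full = DoseSampler(_single_array_plan(), phantom)
    half = _single_array_plan(weight_scale=0.5)
    doubled = make_arc_plan(
        1, 0.0, collimator=MinibeamCollimator(), scan_extent_y=24.0,
        slits=SLITS7, layers=_layers(),
    )
    from pmbat.geometry import ArcPlan
    two = ArcPlan(fields=half.fields + half.fields, angular_separation=0.0)
    s2 = DoseSampler(two, phantom)
    pts = np.array([[0.0, 0.0, 70.0], [2.0, 3.0, 40.0], [-4.0, -5.0, 10.0]])
    np.testing.assert_allclose(s2.dose_at(pts), full.dose_at(pts), rtol=1e-12)


def test_plan_dose_is_sum_of_field_doses(phantom, case1):
    _, _, plans = case1
    s = DoseSampler(plans["pmbat"], phantom)
    rng = np.random.default_rng(1)
    pts = rng.uniform(-40, 40, size=(50, 3))
    total = s.dose_at(pts)
    by_field = sum(s.field_dose(f, pts) for f in plans["pmbat"].fields)
    np.testing.assert_allclose(by_field, total, rtol=1e-12, atol=1e-300)


def test_mirror_symmetry_of_symmetric_arc(phantom, case1):
    _, _, plans = case1
    s = DoseSampler(plans["pmbat"], phantom)
    y = np.linspace(-30, 30, 21)
    pts_plus = np.column_stack([np.zeros_like(y), y, np.full_like(y, 40.0)])
    pts_minus = pts_plus.copy()
    pts_minus[:, 1] *= -1
    a, b = s.dose_at(pts_plus), s.dose_at(pts_minus)
    np.testing.assert_allclose(a, b, rtol=1e-3)


def test_rotation_equivariance(phantom):
    base = DoseSampler(_single_array_plan(angle=0.0, n_fields=3, sep=15.0), phantom)
    rot = DoseSampler(_single_array_plan(angle=40.0, n_fields=3, sep=15.0), phantom)
    rng = np.random.default_rng(2)
    pts = rng.uniform(-35, 35, size=(40, 3))
    rotated_pts = FieldFrame(40.0).field_to_world(pts)
    np.testing.assert_allclose(
        rot.dose_at(rotated_pts), base.dose_at(pts), rtol=1e-3, atol=1e-12
    )


def test_peak_to_valley_ratio_shallow(phantom):
    s = DoseSampler(_single_array_plan(), phantom)
    peak = s.dose_at([[0.0, 0.0, 70.0]])[0]      # slit center, 10 mm deep
    valley = s.dose_at([[2.0, 0.0, 70.0]])[0]    # mid-valley
    assert peak / valley > 2.0


def test_peak_positions_track_slit_centers_at_any_gantry_angle(phantom):
    # fractionation preservation: profile maxima stay on slit centers
    for angle in (0.0, 37.0, 90.0):
        plan = _single_array_plan(angle=angle)
        s = DoseSampler(plan, phantom)
        fr = FieldFrame(angle)
        x = np.arange(-14.0, 14.0, 0.01)
        depth = 20.0
        pts_field = np.column_stack(
            [x, np.zeros_like(x), np.full_like(x, phantom.radius - depth)]
        )
        dose = s.dose_at(fr.field_to_world(pts_field))
        for c in SLITS7:
            sel = np.abs(x - c) <= 1.0
            xpk = x[sel][np.argmax(dose[sel])]
            assert abs(xpk - c) <= 0.05


class TestLET:
    def test_single_layer_matches_depth_table(self, phantom):
        from pmbat.beam import EnergyLayer, letd_vs_depth, DEFAULT_PARAMS

        layer = EnergyLayer(energy=130.0, weight=1.0)
        plan = make_arc_plan(
            1, 0.0, collimator=MinibeamCollimator(), scan_extent_y=24.0,
            slits=SLITS7, layers=(layer,),
        )
        s = DoseSampler(plan, phantom)
        depth = 30.0
        _, letd = s.letd_at([[0.0, 0.0, phantom.radius - depth]])
        expected = letd_vs_depth(130.0).letd_at(
            depth + DEFAULT_PARAMS.shifter_wet_mm
        )
        assert letd[0] == pytest.approx(float(expected), rel=1e-3)

    def test_zero_dose_gives_zero_letd(self, phantom):
        s = DoseSampler(_single_array_plan(), phantom)
        dose, letd = s.letd_at([[0.0, 0.0, 200.0]])
        assert dose[0] == 0.0 and letd[0] == 0.0

    def test_letd_positive_where_dose_positive(self, phantom, case1):
        _, _, plans = case1
        s = DoseSampler(plans["pmbat"], phantom)
        rng = np.random.default_rng(3)
        pts = rng.uniform(-60, 60, size=(200, 3))
        dose, letd = s.letd_at(pts)
        assert np.all(letd[dose > 0] > 0)
        assert np.all(letd[dose == 0] == 0)


class TestScoring:
    def test_grid_values_equal_point_evaluation(self, phantom):
        s = DoseSampler(_single_array_plan(), phantom)
        spec = GridSpec(origin=(-2.0, -2.0, 30.0), spacing=(0.5, 2.0, 2.0),
                        dims=(9, 3, 10))
        grid = s.score_grid(spec)
        np.testing.assert_array_equal(
            grid.values.ravel(), s.dose_at(spec.voxel_centers())
        )

    def test_total_dose_linear_in_plan_weight(self, phantom):
        plan = _single_array_plan()
        spec = GridSpec(origin=(-6.0, -6.0, 20.0), spacing=(0.5, 3.0, 3.0),
                        dims=(25, 5, 15))
        g1 = DoseSampler(plan, phantom).score_grid(spec)
        g3 = DoseSampler(plan.scaled(3.0), phantom).score_grid(spec)
        np.testing.assert_allclose(g3.values, 3.0 * g1.values, rtol=1e-12)

    def test_integral_converges_under_refinement(self, phantom):
        # halving the y,z spacing changes the scored integral by < 1%
        s = DoseSampler(_single_array_plan(), phantom)
        totals = {}
        for h in (4.0, 2.0):
            spec = GridSpec.centered_cube(40.0, (0.5, h, h))
            g = s.score_grid(spec)
            totals[h] = g.values.sum() * g.voxel_volume
        assert totals[2.0] == pytest.approx(totals[4.0], rel=0.01)


class TestNormalization:
    def test_mean_ptv_dose_exactly_one(self, case1_samplers, ptv20):
        pts = ptv_sample_points(ptv20)
        for s in case1_samplers.values():
            assert np.mean(s.dose_at(pts)) == pytest.approx(1.0, rel=1e-12)

    def test_pure_scaling_leaves_pvdr_unchanged(self, phantom, ptv20):
        s = DoseSampler(_single_array_plan(), phantom)
        s2 = normalize_to_ptv_mean(s, ptv_sample_points(ptv20))
        p1 = pvdr(lateral_profile(s, 10.0))
        p2 = pvdr(lateral_profile(s2, 10.0))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_ptv_dose_rejected(self, phantom):
        s = DoseSampler(_single_array_plan(), phantom)
        far = np.array([[0.0, 0.0, 180.0]])
        with pytest.raises(ValueError, match="no dose"):
            normalize_to_ptv_mean(s, far)


def test_degenerate_arc_equals_single_array(phantom):
    arc1 = make_arc_plan(
        1, 0.0, collimator=MinibeamCollimator(), scan_extent_y=24.0,
        slits=SLITS7, layers=_layers(),
    )
    s_arc = DoseSampler(arc1, phantom)
    s_single = DoseSampler(_single_array_plan(), phantom)
    pts = np.array([[0.0, 0.0, 60.0], [1.0, 2.0, 10.0], [-2.0, -8.0, -5.0]])
    np.testing.assert_allclose(s_arc.dose_at(pts), s_single.dose_at(pts))


class TestStochasticMode:
    def _grid(self, phantom):
        s = DoseSampler(_single_array_plan(), phantom)
        spec = GridSpec(origin=(-2.0, -2.0, -12.0), spacing=(0.5, 2.0, 2.0),
                        dims=(9, 3, 12))
        return s.score_grid(spec)

    def test_identical_realizations_have_zero_uncertainty(self, phantom):
        g = self._grid(phantom)
        assert global_uncertainty([g, g, g]) == 0.0

    def test_uncertainty_scales_with_noise_amplitude(self, phantom):
        g = self._grid(phantom)
        stats = {}
        for level in (0.02, 0.04):
            rng = np.random.default_rng(42)
            stats[level] = global_uncertainty(
                [add_stochastic_noise(g, rng, level) for _ in range(8)]
            )
        assert stats[0.04] == pytest.approx(2.0 * stats[0.02], rel=0.15)

    def test_seeded_noise_is_reproducible(self, phantom):
        g = self._grid(phantom)
        a = add_stochastic_noise(g, np.random.default_rng(7), 0.02)
        b = add_stochastic_noise(g, np.random.default_rng(7), 0.02)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, g.values)
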