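import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitpolar as gp
from gaitpolar.gaitogram import CrossingPoint
from gaitpolar.oscillator import TWO_PI


def ideal_series(n_cycles=4, samples_per_cycle=500, shape=np.sin):
    """Perfect phase ramp with COPx = shape(phase)."""
    n = n_cycles * samples_per_cycle
    t = np.arange(n) / 100.0
    phase = np.mod(np.linspace(0, n_cycles * TWO_PI, n, endpoint=False), TWO_PI)
    copx = shape(phase)
    series = gp.GaitPhaseSeries(t=t, phase=phase, omega_series=np.full(n, TWO_PI),
                                uhat=copx.copy(), error=np.zeros(n))
    cop = gp.COPxSeries(t=t, copx=copx, valid_mask=np.ones(n, bool))
    return series, cop


class TestClosedArea:
    def test_constant_radius_half_circle(self):
        theta = np.linspace(0, np.pi, 2000)
        c = 3.0
        area = gp.closed_area(theta, np.full_like(theta, c))
        assert area == pytest.approx(0.5 * c * c * np.pi, rel=1e-3)

    def test_sine_lobe_quarter_pi(self):
        theta = np.linspace(0, np.pi, 5000)
        area = gp.closed_area(theta, np.sin(theta))
        assert area == pytest.approx(np.pi / 4, rel=1e-3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_shoelace_oracle_on_star_curves(self, seed):
        # random star-shaped lobes r(theta) > 0: polar area must agree with
        # the Cartesian shoelace area of the polygon closed through the origin
        rng = np.random.default_rng(seed)
        span = rng.uniform(0.5 * np.pi, 1.5 * np.pi)
        theta = np.linspace(0.0, span, 150)
        r = 1.0 + 0.8 * np.abs(np.sin(rng.integers(1, 4) * theta + rng.uniform(0, 7))) \
            + rng.uniform(0.0, 0.5)
        polar = gp.closed_area(theta, r)
        x = np.concatenate([[0.0], r * np.cos(theta)])
        y = np.concatenate([[0.0], r * np.sin(theta)])
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1)))
        assert polar == pytest.approx(shoelace, rel=0.01)

    def test_non_monotone_theta_raises(self):
        with pytest.raises(gp.GeometryError):
            gp.closed_area(np.array([0.0, 0.5, 0.4, 1.0]), np.ones(4))

    def test_too_few_samples_raises(self):
        with pytest.raises(gp.GeometryError):
            gp.closed_area(np.array([0.0, 1.0]), np.ones(2))

    def test_literal_mode_weights_by_theta(self):
        theta = np.linspace(0, np.pi, 4000)
        r = np.ones_like(theta)
        literal = gp.closed_area(theta, r, literal=True)
        assert literal == pytest.approx(0.5 * np.pi**2 / 2, rel=1e-3)


class TestAreaRatioIndex:
    def test_equal_areas_zero_ari(self):
        rR, rL, ari = gp.area_ratio_index(2.0, 2.0)
        assert (rR, rL, ari) == (50.0, 50.0, 0.0)

    def test_patient_row_arithmetic(self):
        # 60.9 / 39.1 percentage split implies ARI 21.8
        rR, rL, ari = gp.area_ratio_index(60.9, 39.1)
        assert gp.round_half_away(rR, 1) == 60.9
        assert gp.round_half_away(rL, 1) == 39.1
        assert gp.round_half_away(ari, 1) == 21.8

    def test_three_to_one_split(self):
        rR, rL, ari = gp.area_ratio_index(3.0, 1.0)
        assert (rR, rL, ari) == (75.0, 25.0, 50.0)

    def test_zero_total_area_raises(self):
        with pytest.raises(gp.UndefinedIndexError):
            gp.area_ratio_index(0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    def test_ratios_sum_to_100_exactly(self, a, b):
        rR, rL, ari = gp.area_ratio_index(a, b)
        assert rR + rL == pytest.approx(100.0, abs=1e-9)
        assert ari >= 0


class TestClassification:
    def test_default_cutoffs_are_45_55(self):
        assert gp.disorder_cutoffs(10.0) == (45.0, 55.0)

    def test_low_left_share_is_left_hemiplegic(self):
        c = gp.classify_disorder(60.9, 39.1)
        assert (c.verdict, c.affected, c.unaffected) == ("disorder", "left", "right")

    def test_low_right_share_is_right_hemiplegic(self):
        c = gp.classify_disorder(36.0, 64.0)
        assert (c.verdict, c.affected, c.unaffected) == ("disorder", "right", "left")

    def test_symmetric_is_normal(self):
        c = gp.classify_disorder(50.0, 50.0)
        assert (c.verdict, c.affected) == ("normal", "none")

    def test_threshold_is_strict(self):
        assert gp.classify_disorder(55.0, 45.0).verdict == "normal"
        assert gp.classify_disorder(55.1, 44.9).verdict == "disorder"


class TestTangentAngle:
    def test_zero_numerator_as_printed(self):
        a = gp.tangent_angle(CrossingPoint(2.0, 1.5), CrossingPoint(1.0, 1.5))
        assert a == 0.0

    def test_hand_evaluated_polar_form(self):
        a = gp.tangent_angle(CrossingPoint(2.0, 1.0), CrossingPoint(1.0, 4.0))
        assert a == pytest.approx(abs(math.atan2(-3.0, 1.0)), abs=1e-12)
        assert a == pytest.approx(1.249, abs=5e-4)

    def test_cartesian_mode_symmetric_gait_is_horizontal(self):
        # transfer points on opposite sides at equal radii -> tangent is the
        # horizontal diameter, deviation 0
        a = gp.tangent_angle(CrossingPoint(5.0, math.pi), CrossingPoint(5.0, 0.0),
                             mode="cartesian")
        assert a == pytest.approx(0.0, abs=1e-12)

    def test_cartesian_mode_detects_tilt(self):
        a = gp.tangent_angle(CrossingPoint(5.0, math.pi - 0.3), CrossingPoint(5.0, 0.0),
                             mode="cartesian")
        assert 0.05 < a < math.pi / 2

    def test_coincident_points_raise(self):
        with pytest.raises(gp.UndefinedSlopeError):
            gp.tangent_angle(CrossingPoint(1.0, 2.0), CrossingPoint(1.0, 2.0))

    def test_unknown_mode_rejected(self):
        with pytest.raises(gp.ValidationError):
            gp.tangent_angle(CrossingPoint(1.0, 0.0), CrossingPoint(2.0, 1.0), mode="bogus")


class TestBuildGaitogram:
    def test_sine_idealization_splits_into_half_lobes(self):
        series, cop = ideal_series()
        gg = gp.build_gaitogram(series, cop)
        # 4 nominal cycles give 3 wraps; the boundary segments are dropped
        assert gg.n_cycles == 2
        for cyc in gg.cycles:
            upper = cyc.side > 0
            assert np.all(cyc.theta[upper] <= np.pi + 1e-6)
            np.testing.assert_allclose(cyc.r[upper], np.sin(cyc.theta[upper]), atol=1e-9)
        aR, aL = gp.cycle_side_areas(gg.cycles[0])
        assert aR == pytest.approx(np.pi / 4, rel=2e-3)
        assert aL == pytest.approx(np.pi / 4, rel=2e-3)

    def test_degenerate_zero_copx(self):
        series, cop = ideal_series(shape=lambda th: np.zeros_like(th))
        gg = gp.build_gaitogram(series, cop)
        for cyc in gg.cycles:
            np.testing.assert_array_equal(cyc.r, 0.0)
        with pytest.raises(gp.UndefinedIndexError):
            gp.area_ratio_index(*gp.cycle_side_areas(gg.cycles[0]))

    def test_mismatched_grids_rejected(self):
        series, cop = ideal_series()
        other = gp.COPxSeries(t=cop.t + 0.5, copx=cop.copx, valid_mask=cop.valid_mask)
        with pytest.raises(gp.ValidationError):
            gp.build_gaitogram(series, other)

    def test_single_cycle_insufficient(self):
        series, cop = ideal_series(n_cycles=2)  # only one wrap
        with pytest.raises(gp.InsufficientCyclesError):
            gp.build_gaitogram(series, cop)

    def test_synthetic_trial_cycle_count_and_alternation(self, layout):
        trial, _ = gp.generate_trial(gp.GaitTemplate(n_strides=10, noise_sd=0.0))
        cop = gp.compute_copx(trial, layout)
        phase = gp.estimate_phase(cop, gp.ao_profile("healthy"))
        gg = gp.build_gaitogram(phase, cop)
        assert 8 <= gg.n_cycles <= 10


class TestSubjectIndices:
    def test_foot_swap_swaps_areas_and_preserves_ari(self, clean_pipeline):
        # anchor disabled: mirroring flips which transfer defines theta = 0,
        # so only the unanchored gaitogram swaps exactly
        _, _, cop, phase = clean_pipeline
        gi = gp.gaitogram_indices(phase, cop, anchor=False)
        mirrored = gp.COPxSeries(t=cop.t, copx=-cop.copx, valid_mask=cop.valid_mask)
        gm = gp.gaitogram_indices(phase, mirrored, anchor=False)
        assert gm.area_R == pytest.approx(gi.area_L, rel=1e-6)
        assert gm.area_L == pytest.approx(gi.area_R, rel=1e-6)
        assert gm.ari == pytest.approx(gi.ari, abs=1e-6)

    def test_plot_gaitogram_writes_file(self, clean_pipeline, tmp_path):
        _, _, cop, phase = clean_pipeline
        from gaitpolar.gaitogram import anchor_phase_to_transfer, build_gaitogram
        anchored = anchor_phase_to_transfer(phase, cop)
        gg = build_gaitogram(anchored, cop)
        gi = gp.gaitogram_indices(phase, cop)
        out = gp.plot_gaitogram(gg, tmp_path / "gaitogram.png", gi)
        assert (tmp_path / "gaitogram.png").stat().st_size > 0
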