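"""Tests of detection, trajectory statistics and summary measures."""

import numpy as np
import pytest

from conftest import ensemble_from_positions
from saccnoise.stats import (
    TrajectoryStatistics,
    amplitude_duration_stats,
    bin_by_motor_error,
    correlation_trajectory,
    detect_saccade,
    main_sequence_at_fixed_amplitude,
    normalize_and_resample,
    proportionality_index,
)
from saccnoise.synth import ConditionConfig, NoiseCoefficients, generate_ensemble, generate_session


def triangular_saccade(rate=1000.0, peak=400.0, t_peak=0.020, t_end=0.040, total=0.080):
    """Position trace whose velocity is a symmetric triangle."""
    t = np.arange(0, total, 1.0 / rate)
    v = np.where(t <= t_peak, peak * t / t_peak,
                 np.where(t <= t_end, peak * (t_end - t) / (t_end - t_peak), 0.0))
    return t, np.concatenate(([0.0], np.cumsum((v[1:] + v[:-1]) / 2) / rate))


class TestDetection:
    def test_triangular_velocity_ten_percent_crossings(self):
        """Linear velocity ramp: 10% of a 400 deg/s peak is crossed at 2 ms
        and 38 ms (filter disabled to keep the ramp exact)."""
        t, y = triangular_saccade()
        det = detect_saccade(y, rate=1000.0, filter_hz=None)
        assert det.found
        assert t[det.onset] == pytest.approx(0.002, abs=1.5e-3)
        assert t[det.offset] == pytest.approx(0.038, abs=1.5e-3)

    def test_flat_trace_reports_no_saccade(self):
        det = detect_saccade(np.zeros(100), rate=1000.0)
        assert not det.found

    def test_duration_matches_profile_crossing_span(self, ms):
        """Noise-free synthetic saccade: detected duration equals the
        profile's own 10%-threshold crossing span within one sample."""
        from saccnoise.dynamics import TimeGrid
        from saccnoise.synth import mean_trajectory

        rate = 1000.0
        grid = TimeGrid.for_duration(float(ms.duration(10.0)) + 0.04, 1.0 / rate)
        y = mean_trajectory(10.0, ms, grid)
        det = detect_saccade(y, rate)
        # oracle: crossing span of the exact (unfiltered) velocity profile
        tq = np.arange(0.0, float(ms.duration(10.0)), 1e-5)
        v = ms.velocity(tq, 10.0)
        above = v >= 0.1 * v.max()
        span = tq[np.flatnonzero(above)[-1]] - tq[np.flatnonzero(above)[0]]
        assert det.duration == pytest.approx(span, abs=1.5 / rate)


class TestBinning:
    def test_half_open_interval_convention(self):
        Y = np.tile(triangular_saccade()[1], (3, 1))
        ens = ensemble_from_positions(Y, motor_errors=np.array([9.0, 12.4, 12.6]))
        bins = bin_by_motor_error(ens)
        assert bins[10.0].n_trials == 2
        assert bins[15.0].n_trials == 1

    def test_uniform_errors_fill_bins_proportionally(self):
        rng = np.random.default_rng(0)
        me = rng.uniform(0.0, 22.5, size=4000)
        Y = np.tile(triangular_saccade()[1], (4000, 1))
        bins = bin_by_motor_error(ensemble_from_positions(Y, motor_errors=me))
        for c in (5.0, 10.0, 15.0):
            assert bins[c].n_trials / 4000 == pytest.approx(5.0 / 22.5, rel=0.1)

    def test_statistics_refuse_single_trial_class(self):
        Y = np.tile(triangular_saccade()[1], (2, 1))
        ens = ensemble_from_positions(Y, motor_errors=np.array([10.0, 20.0]))
        with pytest.raises(ValueError, match="2 trials"):
            normalize_and_resample(bin_by_motor_error(ens)[20.0])


class TestTrajectoryStatistics:
    def test_identical_traces_have_zero_variance(self):
        Y = np.tile(triangular_saccade()[1], (2, 1))
        st = normalize_and_resample(ensemble_from_positions(Y))
        np.testing.assert_allclose(st.var_y, 0.0, atol=1e-20)
        np.testing.assert_allclose(st.cov_ye, 0.0, atol=1e-20)

    def test_correlation_is_exactly_one_at_last_sample(self):
        ens = generate_ensemble(50, "control", seed=1)
        st = normalize_and_resample(ens)
        assert st.rho_ye[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.nanmax(np.abs(st.rho_ye)) <= 1.0 + 1e-9

    def test_order_and_mirror_invariance(self):
        ens = generate_ensemble(60, "control", seed=2)
        st = normalize_and_resample(ens)
        perm = np.random.default_rng(0).permutation(ens.n_trials)
        st_perm = normalize_and_resample(ens.subset(perm))
        np.testing.assert_allclose(st_perm.var_y, st.var_y, rtol=1e-12)
        flipped = ensemble_from_positions(-ens.positions, motor_errors=ens.motor_errors)
        st_flip = normalize_and_resample(flipped)
        np.testing.assert_allclose(st_flip.var_y, st.var_y, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(st_flip.y_bar, -st.y_bar, rtol=1e-9, atol=1e-9)


class TestCorrelationTrajectory:
    def test_interpolated_threshold_crossing(self):
        """ρ = [0.5, 0.95, 1.0] on three samples: the 0.9 crossing is
        interpolated between the first two."""
        var = np.ones(3)
        st = TrajectoryStatistics(
            t_norm=np.linspace(0, 1, 3), y_bar=np.zeros(3), var_y=var,
            cov_ye=np.array([0.5, 0.95, 1.0]), A_bar=10.0, D_bar=0.04, n_trials=100,
        )
        rho, p09 = correlation_trajectory(st)
        expected = 100 * 0.5 * (0.9 - 0.5) / (0.95 - 0.5)
        assert p09 == pytest.approx(expected, abs=1e-9)

    def test_planning_only_crossing_at_onset(self, ms):
        cfg = ConditionConfig(A_bar=10.0, noise=NoiseCoefficients(k_A=0.1), main_sequence=ms)
        ens = generate_ensemble(400, cfg, seed=3)
        D_i = np.asarray(ms.duration(ens.planned_amplitudes))
        st = normalize_and_resample(ens, mode="per_trial",
                                    windows=(np.zeros(len(D_i)), D_i), interp="cubic")
        _, p09 = correlation_trajectory(st)
        assert p09 < 5.0

    def test_control_preset_crossing_is_interior(self):
        ens = generate_ensemble(2000, "control", seed=4)
        st = normalize_and_resample(ens)
        _, p09 = correlation_trajectory(st)
        assert 0.0 < p09 < 100.0


class TestAmplitudeDurationStats:
    def test_exact_main_sequence_case(self):
        """Amplitudes perfectly proportional to durations: unit correlation
        and var_Amp = α²·var_TDur."""
        rng = np.random.default_rng(1)
        alpha0 = 0.66
        dur_ms = rng.uniform(35, 45, 200)
        amps = alpha0 * dur_ms
        t, base = triangular_saccade()
        Y = np.outer(amps / base[-1], base)
        ens = ensemble_from_positions(Y)
        # all traces share the triangular time course, so detected durations
        # are equal; inject the known pairs directly
        ens.durations[:] = dur_ms * 1e-3
        ens.amplitudes[:] = amps
        st = amplitude_duration_stats(ens)
        assert st.cc_tdur_amp == pytest.approx(1.0, abs=1e-9)
        assert st.alpha == pytest.approx(alpha0, rel=1e-9)
        assert st.var_amp == pytest.approx(st.alpha2_var_tdur, rel=1e-9)

    def test_independent_amplitude_and_duration_decorrelate(self):
        rng = np.random.default_rng(2)
        t, base = triangular_saccade()
        Y = np.tile(base, (3000, 1))
        ens = ensemble_from_positions(Y)
        ens.durations[:] = rng.normal(0.040, 0.005, 3000)
        ens.amplitudes[:] = rng.normal(10.0, 1.0, 3000)
        st = amplitude_duration_stats(ens)
        assert abs(st.cc_tdur_amp) < 0.06

    def test_control_preset_amplitude_stabilized(self):
        """Feedback stabilizes amplitude: within the 10-deg class,
        var_Amp < α²·var_TDur with α taken from the session-wide main
        sequence."""
        ses = generate_session(400, "control", seed=5)
        alpha = float(np.polyfit(ses.durations * 1e3, ses.amplitudes, 1)[0])
        sub = bin_by_motor_error(ses)[10.0]
        st = amplitude_duration_stats(sub, alpha=alpha)
        assert st.var_amp < st.alpha2_var_tdur


class TestMainSequenceInterpolation:
    def test_interpolated_values_match_reference_member(self, ms):
        """Noise-free family sampled at several amplitudes: values at
        A0 = 10 equal the 10-deg member's own detected parameters, and the
        deceleration fraction is the configured 55%."""
        cfg = ConditionConfig(A_bar=10.0, noise=NoiseCoefficients(), main_sequence=ms,
                              motor_error_sd=0.0)
        ses = generate_session(3, cfg, targets=(5.0, 7.5, 10.0, 12.5, 15.0, 20.0), seed=0)
        out = main_sequence_at_fixed_amplitude(ses, A0=10.0)
        ref = generate_ensemble(2, cfg, seed=0)
        assert out["total_duration_ms"] == pytest.approx(
            float(np.mean(ref.durations)) * 1e3, rel=0.03)
        assert out["decel_duration_ms"] / out["total_duration_ms"] == pytest.approx(0.55, abs=0.02)
        out2 = main_sequence_at_fixed_amplitude(ses, A0=10.0)
        assert out == out2  # determinism

    def test_extrapolation_refused(self, ms):
        ses = generate_session(3, ConditionConfig(main_sequence=ms), targets=(5.0, 10.0), seed=0)
        with pytest.raises(ValueError, match="range"):
            main_sequence_at_fixed_amplitude(ses, A0=24.0)


class TestProportionalityIndex:
    def test_collinear_vectors_score_one(self):
        v = np.array([1.0, 2.0, 3.0])
        X = np.outer([1.0, 2.5, 0.5, 1.5, 3.0], v)
        assert proportionality_index(X) == pytest.approx(1.0, abs=1e-9)

    def test_spherical_cloud_scores_near_zero(self):
        """Isotropic 3-D Gaussians at the origin: the index averages ≈ 0
        over replicates (the projected fraction equals 1/n)."""
        rng = np.random.default_rng(3)
        vals = [proportionality_index(rng.standard_normal((5, 3)), standardize=False)
                for _ in range(3000)]
        assert np.mean(vals) == pytest.approx(0.0, abs=0.05)

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            assert proportionality_index(rng.standard_normal((6, 4))) <= 1.0 + 1e-12
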