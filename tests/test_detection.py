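"""Onset detection, velocity estimators, pause flagging, event qualification."""

import numpy as np
import pytest

from smtpm.processing import BMSeries, bm_series, correct_drift
from smtpm.simulate import SimulationConfig, simulate_bead_trajectory
from smtpm.detection import (
    DerivativeBand,
    UnwindingDetector,
    analyze_trajectory,
    detect_unwind_start,
    fit_velocity_slope,
    flag_pause,
    velocity_dwell,
)


def synthetic_series(bm_values, dt=2.0 / 3.0, window_frames=20, frame_rate=30.0):
    """BM series built directly from values on a non-overlapping window grid."""
    bm_values = np.asarray(bm_values, dtype=float)
    return BMSeries(
        bead_id="synth",
        times=20.0 + np.arange(len(bm_values)) * dt,
        bm=bm_values,
        window_frames=window_frames,
        frame_rate=frame_rate,
        stride=window_frames,  # already decimated
    )


def ramp_series(t0=270.0, v=3.58, c=0.0718, sigma0=9.9, t_end=400.0, noise=0.0, seed=0):
    dt = 2.0 / 3.0
    t = 20.0 + np.arange(int((t_end - 20.0) / dt)) * dt
    u = np.clip((t - t0) * v, 0.0, 90.0)
    bm = sigma0 + c * u
    if noise:
        bm = bm + np.random.default_rng(seed).normal(0.0, noise, len(bm))
    # truncate at release
    keep = u < 90.0
    s = synthetic_series(bm[keep])
    s.times = t[keep]
    return s


class TestOnsetDetection:
    def test_noiseless_step_located_at_step(self):
        bm = np.full(600, 9.9)
        bm[450:] = 16.4
        s = synthetic_series(bm)
        t0 = detect_unwind_start(s)
        assert t0 == pytest.approx(s.times[450], abs=2.0 / 3.0)

    def test_noiseless_ramp_onset_exact(self):
        s = ramp_series(noise=0.0)
        t0 = detect_unwind_start(s, disappeared=True)
        assert t0 == pytest.approx(270.0, abs=2.0 / 3.0)

    def test_simulated_trace_onset_within_5s(self):
        """Full pipeline on a simulated unwinding trace with onset at 270 s."""
        cfg = SimulationConfig(duration=600.0, tau=0.01, v_true=3.58, sigma0_sd=0.0)
        tr = simulate_bead_trajectory(cfg, rng=np.random.default_rng(42), t_start=270.0)
        s = bm_series(correct_drift(tr))
        t0 = detect_unwind_start(s, disappeared=tr.disappeared)
        assert t0 is not None
        assert abs(t0 - 270.0) <= 5.0

    def test_flat_noisy_series_not_detected(self):
        """Stationary traces: no onset called (false-positive control)."""
        hits = 0
        for seed in range(30):
            cfg = SimulationConfig(duration=520.0, tau=0.01, sigma0_sd=0.0)
            tr = simulate_bead_trajectory(cfg, rng=np.random.default_rng(900 + seed),
                                          unwinds=False)
            s = bm_series(correct_drift(tr))
            hits += detect_unwind_start(s) is not None
        assert hits <= 1

    def test_short_series_error(self):
        s = synthetic_series(np.full(20, 9.9))
        with pytest.raises(ValueError, match="min_windows"):
            detect_unwind_start(s)

    def test_band_ordering_enforced(self):
        with pytest.raises(ValueError):
            DerivativeBand(mean=0.0, lower=0.1, upper=0.2, persistence=10)


class TestVelocityEstimators:
    def test_slope_to_velocity_conversion(self):
        t = np.linspace(100.0, 150.0, 80)
        s = BMSeries("b", t, 9.9 + 0.257 * (t - 100.0), 20, 30.0)
        slope, v = fit_velocity_slope(s, 100.0, 150.0, c=0.0718)
        assert slope == pytest.approx(0.257, rel=1e-9)
        assert v == pytest.approx(3.58, abs=0.01)

    def test_zero_slope(self):
        t = np.linspace(0.0, 50.0, 80)
        s = BMSeries("b", t, np.full(80, 9.9), 20, 30.0)
        _, v = fit_velocity_slope(s, 0.0, 50.0, c=0.0718)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_ramp_round_trip(self):
        """Simulator truth at v = 7.44 recovered through the full estimator."""
        s = ramp_series(v=7.44)
        det = UnwindingDetector().fit(s, disappeared=True)
        assert det.v_slope_ == pytest.approx(7.44, abs=0.02)

    def test_slope_equals_dwell_on_noiseless_ramp(self):
        """The two velocity estimators coincide on clean ramps (up to the
        half-window discretization of t_max)."""
        s = ramp_series(v=3.58)
        det = UnwindingDetector().fit(s, disappeared=True)
        assert det.v_slope_ == pytest.approx(det.v_dwell_, rel=0.02)

    @pytest.mark.parametrize("dwell,expected", [(25.0, 3.6), (12.1, 7.438)])
    def test_dwell_quotient(self, dwell, expected):
        assert velocity_dwell(90, 100.0, 100.0 + dwell) == pytest.approx(expected, abs=5e-3)

    def test_dwell_degenerate_error(self):
        with pytest.raises(ValueError):
            velocity_dwell(90, 100.0, 100.0)

    def test_invalid_conversion_factor(self):
        s = ramp_series()
        with pytest.raises(ValueError, match="c must be > 0"):
            fit_velocity_slope(s, 270.0, 290.0, c=0.0)

    def test_too_few_points_error(self):
        t = np.linspace(0, 50, 80)
        s = BMSeries("b", t, np.full(80, 9.9), 20, 30.0)
        with pytest.raises(ValueError, match="fewer than 5"):
            fit_velocity_slope(s, 49.0, 50.0, c=0.0718)


class TestConsistency:
    """Cohort-level estimator properties on simulated molecules."""

    @pytest.mark.parametrize("v_true", [3.58, 7.44, 7.50, 10.52])
    def test_mean_velocity_within_10pct(self, v_true):
        cfg = SimulationConfig(duration=600.0, tau=0.01, v_true=v_true,
                               sigma0_sd=0.0, p_pause=0.0)
        vs = []
        for seed in range(50):
            tr = simulate_bead_trajectory(
                cfg, rng=np.random.default_rng(3000 + seed), t_start=270.0
            )
            s = bm_series(correct_drift(tr))
            det = UnwindingDetector().fit(s, disappeared=tr.disappeared)
            if det.qualifies_ and not det.paused_:
                vs.append(det.v_slope_)
        assert len(vs) >= 40
        assert np.mean(vs) == pytest.approx(v_true, rel=0.10)

    def test_onset_error_below_10_windows(self):
        """Onset localization at default noise stays below 10 analysis
        windows (6.7 s)."""
        cfg = SimulationConfig(duration=600.0, tau=0.01, v_true=3.58, sigma0_sd=0.0)
        errs = []
        for seed in range(25):
            tr = simulate_bead_trajectory(
                cfg, rng=np.random.default_rng(4000 + seed), t_start=270.0
            )
            s = bm_series(correct_drift(tr))
            det = UnwindingDetector().fit(s, disappeared=tr.disappeared)
            if det.detected_:
                errs.append(abs(det.t_start_ - 270.0))
        assert len(errs) >= 20
        assert np.mean(errs) < 10 * 20 / 30.0


class TestPauseFlag:
    def test_inserted_pause_flagged(self):
        cfg = SimulationConfig(duration=600.0, tau=0.01, v_true=3.58,
                               sigma0_sd=0.0, pause_dur=30.0)
        tr = simulate_bead_trajectory(cfg, rng=np.random.default_rng(7),
                                      t_start=150.0, paused=True)
        s = bm_series(correct_drift(tr))
        det = UnwindingDetector().fit(s, disappeared=tr.disappeared)
        assert det.paused_

    def test_monotone_ramp_not_flagged(self):
        s = ramp_series(v=3.58)
        assert not flag_pause(s, 270.0, s.times[-1])

    def test_pause_fraction_consistent_with_rate(self):
        """Cohort flagged fraction tracks the simulated pause probability
        (<10% of molecules, a small minority)."""
        cfg = SimulationConfig(duration=600.0, tau=0.01, v_true=3.58, seed=21,
                               p_pause=0.08)
        from smtpm.simulate import simulate_cohort
        trajs = simulate_cohort(cfg, 60, all_unwind=True)
        flagged = 0
        detected = 0
        for tr in trajs:
            s = bm_series(correct_drift(tr))
            ev = analyze_trajectory(tr, s)
            if ev.detected:
                detected += 1
                flagged += ev.paused
        assert detected >= 55
        assert flagged / detected < 0.20
        assert flagged >= 1


class TestQualification:
    def test_simulated_unwinding_qualifies(self):
        cfg = SimulationConfig(duration=600.0, tau=0.01, v_true=3.58, sigma0_sd=0.0)
        tr = simulate_bead_trajectory(cfg, rng=np.random.default_rng(13), t_start=270.0)
        s = bm_series(correct_drift(tr))
        ev = analyze_trajectory(tr, s)
        assert ev.qualifies

    def test_persisting_bead_does_not_qualify(self):
        cfg = SimulationConfig(duration=520.0, tau=0.01, sigma0_sd=0.0)
        tr = simulate_bead_trajectory(cfg, rng=np.random.default_rng(14), unwinds=False)
        s = bm_series(correct_drift(tr))
        ev = analyze_trajectory(tr, s)
        assert not ev.qualifies

    def test_flat_disappearance_does_not_qualify(self):
        """Nonspecific detachment: trace ends but BM never rose."""
        cfg = SimulationConfig(duration=520.0, tau=0.01, sigma0_sd=0.0)
        tr = simulate_bead_trajectory(cfg, rng=np.random.default_rng(15), unwinds=False)
        s = bm_series(correct_drift(tr))
        det = UnwindingDetector().fit(s, disappeared=True)
        assert not det.qualifies_
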