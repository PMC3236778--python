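"""BM computation, drift correction, QC, populations, calibration, tracking."""

import warnings

import numpy as np
import pytest

from conftest import make_trajectory
from smtpm.simulate import (
    Optics,
    SimulationConfig,
    render_frames,
    simulate_bead_trajectory,
    simulate_population,
)
from smtpm.processing import (
    BMAnalyzer,
    DriftCorrector,
    SymmetryFilter,
    bm_series,
    calibrate,
    correct_drift,
    localize_centroids,
    population_bm,
    qc_symmetry,
)


class TestBMSeries:
    def test_constant_positions_zero_bm(self):
        tr = make_trajectory(np.full(100, 3.0), np.full(100, -2.0))
        s = bm_series(tr)
        assert np.allclose(s.bm, 0.0)

    def test_alternating_hand_computed(self):
        """x alternating 0,1 nm -> MSD_x = 0.25 nm^2, BM = 0.3536 nm."""
        x = np.tile([0.0, 1.0], 50)
        tr = make_trajectory(x, np.zeros(100))
        s = bm_series(tr, window_frames=20)
        assert np.allclose(s.bm, np.sqrt(0.25 / 2.0), atol=1e-12)
        assert s.bm[0] == pytest.approx(0.3536, abs=1e-4)

    def test_stationary_recovers_sigma(self, stationary_config):
        tr = simulate_bead_trajectory(
            stationary_config, rng=np.random.default_rng(4), unwinds=False, sigma0=7.0
        )
        s = bm_series(tr)
        assert np.mean(s.bm) == pytest.approx(7.0, rel=0.05)

    def test_window_duration(self):
        tr = make_trajectory(np.zeros(50), np.zeros(50))
        s = bm_series(tr, window_frames=20)
        assert int(s.window_s * 100) / 100 == 0.66

    def test_windows_skip_unrecorded(self):
        rec = np.ones(100, dtype=bool)
        rec[40:45] = False
        x = np.where(rec, 1.0, np.nan)
        tr = make_trajectory(x, x.copy(), recorded=rec)
        s = bm_series(tr, window_frames=20)
        # no window may straddle the gap
        assert len(s) == 100 - 19 - (5 + 19)

    def test_rigid_motion_invariance(self, stationary_config):
        """BM is unchanged by translation and by swapping the axes."""
        tr = simulate_bead_trajectory(
            stationary_config, rng=np.random.default_rng(8), unwinds=False, sigma0=5.0
        )
        s0 = bm_series(tr)
        shifted = make_trajectory(tr.x + 123.4, tr.y - 55.5, frame_rate=tr.frame_rate)
        swapped = make_trajectory(tr.y, tr.x, frame_rate=tr.frame_rate)
        assert np.allclose(s0.bm, bm_series(shifted).bm)
        assert np.allclose(s0.bm, bm_series(swapped).bm)

    def test_too_small_window_error(self):
        tr = make_trajectory(np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError):
            bm_series(tr, window_frames=1)


class TestDriftCorrection:
    def test_linear_drift_removed(self):
        cfg_d = SimulationConfig(duration=120.0, tau=0.01, drift=0.5, sigma0_sd=0.0, dead_time=0.0)
        cfg_0 = SimulationConfig(duration=120.0, tau=0.01, drift=0.0, sigma0_sd=0.0, dead_time=0.0)
        td = simulate_bead_trajectory(cfg_d, rng=np.random.default_rng(6), unwinds=False, sigma0=9.9)
        t0 = simulate_bead_trajectory(cfg_0, rng=np.random.default_rng(6), unwinds=False, sigma0=9.9)
        bm_d = bm_series(correct_drift(td)).bm.mean()
        bm_0 = bm_series(correct_drift(t0)).bm.mean()
        assert abs(bm_d - bm_0) / bm_0 < 0.03

    def test_zero_drift_near_identity(self, stationary_config):
        tr = simulate_bead_trajectory(
            stationary_config, rng=np.random.default_rng(7), unwinds=False, sigma0=9.9
        )
        raw = bm_series(tr).bm.mean()
        corrected = bm_series(correct_drift(tr)).bm.mean()
        assert abs(corrected - raw) / raw < 0.01

    def test_pure_drift_gives_zero_bm(self):
        t = np.arange(3000) / 30.0
        tr = make_trajectory(0.5 * t, -0.3 * t)
        s = bm_series(correct_drift(tr))
        assert np.nanmax(s.bm) < 0.05

    def test_short_trajectory_error(self):
        tr = make_trajectory(np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError, match="drift window"):
            correct_drift(tr, drift_window_s=10.0)


class TestSymmetryQC:
    def test_isotropic_passes(self, stationary_config):
        tr = simulate_bead_trajectory(
            stationary_config, rng=np.random.default_rng(5), unwinds=False, sigma0=9.9
        )
        assert qc_symmetry(tr).symmetric

    def test_injected_ratio_fails(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1200) * np.sqrt(1.15)
        y = rng.standard_normal(1200)
        # force the empirical variance ratio to exactly 1.15
        x *= np.sqrt(1.15 / np.var(x[:1000]) * np.var(y[:1000]))
        tr = make_trajectory(x, y)
        qc = qc_symmetry(tr)
        assert qc.ratio == pytest.approx(1.15, abs=1e-9)
        assert not qc.symmetric

    def test_boundary_ratio_inclusive(self):
        x = np.tile([-1.0, 1.0], 600) * np.sqrt(1.1)
        y = np.tile([-1.0, 1.0], 600)
        qc = qc_symmetry(make_trajectory(x, y))
        assert qc.ratio == pytest.approx(1.1, abs=1e-12)
        assert qc.symmetric

    def test_pass_rate_isotropic_and_anisotropic(self):
        """Sampling noise of a 1000-frame variance ratio gives ~6% spread, so
        most but not all isotropic beads fall inside [0.9, 1.1]; 2:1
        anisotropic beads essentially always fall outside."""
        cfg = SimulationConfig(duration=40.0, dead_time=0.0, tau=0.01, drift=0.0, sigma0_sd=0.0)
        rng = np.random.default_rng(11)
        iso = [
            qc_symmetry(simulate_bead_trajectory(cfg, rng=rng, unwinds=False)).symmetric
            for _ in range(200)
        ]
        assert np.mean(iso) >= 0.85
        aniso = [
            qc_symmetry(
                simulate_bead_trajectory(cfg, rng=rng, unwinds=False, asymmetric=True)
            ).symmetric
            for _ in range(100)
        ]
        assert sum(aniso) == 0

    def test_too_few_frames_error(self):
        tr = make_trajectory(np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError):
            qc_symmetry(tr, n_frames=1000)


class TestPopulation:
    @pytest.mark.parametrize("mean,sd,n", [(9.90, 2.18, 66), (15.00, 4.23, 57)])
    def test_population_recovery(self, mean, sd, n):
        cfg = SimulationConfig(duration=40.0, dead_time=0.0, tau=0.01, drift=0.0)
        trajs = simulate_population(cfg, n, mean, sd, rng=np.random.default_rng(12))
        pop = population_bm(trajs)
        assert abs(pop.mean - mean) < 2.0 * sd / np.sqrt(n)

    def test_degenerate_population_flagged(self):
        x = np.tile([0.0, 1.0], 600)
        trajs = [make_trajectory(x, x, bead_id=f"b{i}") for i in range(3)]
        pop = population_bm(trajs, qc=False)
        assert pop.sd == 0.0
        assert pop.degenerate

    def test_fewer_than_two_beads_error(self):
        x = np.tile([0.0, 1.0], 600)
        with pytest.raises(ValueError):
            population_bm([make_trajectory(x, x)], qc=False)


class TestCalibration:
    def test_printed_population_means(self):
        cal = calibrate(9.90, 15.00, 71)
        assert cal.c == pytest.approx(0.0718, abs=5e-5)

    def test_equal_means_zero(self):
        assert calibrate(10.0, 10.0, 71).c == 0.0

    def test_direct_quotient(self):
        assert calibrate(10.0, 17.1, 71).c == pytest.approx(0.1, abs=1e-12)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            calibrate(9.9, 15.0, 0)

    def test_negative_factor_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            calibrate(15.0, 9.9, 71)

    def test_round_trip_from_simulated_cohorts(self):
        """Simulate fork and mimicked-unwound populations consistent with
        c_true, measure, calibrate: c within 10% of c_true (n = 60 each)."""
        c_true = 0.0718
        cfg = SimulationConfig(duration=40.0, dead_time=0.0, tau=0.01)
        rng = np.random.default_rng(1)
        fork = simulate_population(cfg, 60, 9.90, 2.18, rng=rng)
        mimic = simulate_population(cfg, 60, 9.90 + c_true * 71, 4.23, rng=rng)
        cal = calibrate(population_bm(fork), population_bm(mimic), 71)
        assert abs(cal.c - c_true) / c_true < 0.10


class TestLocalization:
    def _static_traj(self, x_nm=0.0, y_nm=0.0, n=20):
        cfg = SimulationConfig(duration=n / 30.0, dead_time=0.0, drift=0.0)
        tr = simulate_bead_trajectory(cfg, rng=np.random.default_rng(0), unwinds=False, sigma0=1e-9)
        tr.x[:] = x_nm
        tr.y[:] = y_nm
        return tr

    def test_subpixel_recovery(self):
        optics = Optics(photons=2e5, background=5.0)
        tr = self._static_traj(x_nm=0.3 * optics.pixel_nm)
        frames = render_frames(tr, optics, rng=np.random.default_rng(3))
        out = localize_centroids(frames, optics)
        err_px = np.abs(out.x - tr.x).max() / optics.pixel_nm
        assert err_px <= 0.05

    def test_tracked_path_recovered(self):
        optics = Optics(photons=2e5, background=5.0)
        cfg = SimulationConfig(duration=2.0, dead_time=0.0, drift=0.0, tau=0.05)
        tr = simulate_bead_trajectory(cfg, rng=np.random.default_rng(9), unwinds=False, sigma0=50.0)
        frames = render_frames(tr, optics, rng=np.random.default_rng(4))
        out = localize_centroids(frames, optics)
        assert np.abs(out.x - tr.x).max() / optics.pixel_nm <= 0.05
        assert np.abs(out.y - tr.y).max() / optics.pixel_nm <= 0.05

    def test_empty_frames_unrecorded(self):
        optics = Optics(photons=2e5, background=5.0)
        tr = self._static_traj()
        frames = render_frames(tr, optics, rng=np.random.default_rng(5))
        frames[10:] = 5.0  # bead gone: background only
        out = localize_centroids(frames, optics)
        assert out.recorded[:10].all()
        assert not out.recorded[10:].any()

    def test_two_spots_tracks_nearest(self):
        optics = Optics(photons=2e5, background=5.0, image_size=(48, 48))
        tr = self._static_traj(n=10)
        frames = render_frames(tr, optics, rng=np.random.default_rng(6))
        # add a second, farther spot from frame 1 on
        yy, xx = np.mgrid[0:48, 0:48].astype(float)
        decoy = 2e5 / (2 * np.pi * 1.2**2) * np.exp(
            -((xx - 40.0) ** 2 + (yy - 40.0) ** 2) / (2 * 1.2**2)
        )
        frames[1:] += decoy
        out = localize_centroids(frames, optics)
        assert np.abs(out.x).max() / optics.pixel_nm < 0.2

    def test_ambiguous_first_frame_error(self):
        optics = Optics(photons=2e5, background=5.0, image_size=(48, 48))
        tr = self._static_traj(n=3)
        frames = render_frames(tr, optics, rng=np.random.default_rng(7))
        yy, xx = np.mgrid[0:48, 0:48].astype(float)
        frames += 2e5 / (2 * np.pi * 1.2**2) * np.exp(
            -((xx - 40.0) ** 2 + (yy - 40.0) ** 2) / (2 * 1.2**2)
        )
        with pytest.raises(ValueError, match="multiple candidate spots"):
            localize_centroids(frames, optics)

    def test_all_empty_error(self):
        with pytest.raises(ValueError, match="no spot"):
            localize_centroids(np.full((5, 16, 16), 3.0), Optics(), threshold=50.0)
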