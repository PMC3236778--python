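"""Synthetic bead-trajectory generator for TPM unwinding experiments.

The observable in a TPM unwinding experiment is the restricted Brownian
motion of a surface-tethered bead recorded at a fixed frame rate.  The
generator models the bead centroid on each axis as a stationary
mean-reverting (Ornstein-Uhlenbeck) process whose instantaneous standard
deviation tracks the tether state:

    sigma_axis(t) = sigma0 + c_true * u(t)

where ``u(t)`` is the number of base pairs unwound.  With the scalar BM
amplitude defined downstream as sqrt((MSD_x + MSD_y)/2) — the per-axis RMS
excursion — the simulated BM time-course is ``sigma0 + c_true*u(t)`` by
construction, so calibration and velocity estimators can be validated
against known truth without committing to any particular tether polymer
physics.

Simulated features of real recordings:

* a recording dead time at the start (frames present but flagged unrecorded),
* slow linear stage drift,
* stochastic unwinding initiation, uniform over a configured window,
* optional pre-release pauses (BM plateau at partial unwinding),
* bead disappearance when the whole unwindable duplex is open
  (the trajectory simply ends),
* a minority of anisotropic beads that must fail the downstream symmetry QC.

Not modelled: hydrodynamic tether physics, force dependence (the assay is
nearly force-free), motion blur within an exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .substrate import SubstrateSpec

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "TrajectoryTruth",
    "Optics",
    "simulate_bead_trajectory",
    "simulate_cohort",
    "simulate_population",
    "render_frames",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic TPM recordings.

    Units: lengths nm, times s, velocities bp/s, rates Hz.
    """

    frame_rate: float = 30.0      #: camera frame rate
    duration: float = 600.0       #: recording length per bead
    sigma0: float = 9.90          #: baseline per-axis BM of the intact fork
    sigma0_sd: float = 2.18       #: bead-to-bead spread of the baseline BM
    c_true: float = 0.0718        #: BM increase per unwound base pair
    tau: float = 0.05             #: bead position relaxation time
    v_true: float = 3.58          #: unwinding velocity
    unwindable_bp: int = 90       #: duplex length whose opening releases the bead
    dead_time: float = 20.0       #: initial unrecorded span (solution exchange)
    t_bind_min: Optional[float] = None  #: earliest unwinding onset (default dead_time+100)
    t_bind_max: Optional[float] = None  #: latest unwinding onset (default dead_time+300)
    p_unwind: float = 0.17        #: fraction of tethers unwound during a recording
    drift: float = 0.1            #: per-axis linear stage drift, nm/s
    p_pause: float = 0.08         #: fraction of unwinding tethers that pause
    pause_dur: float = 30.0       #: pause duration
    pause_frac: Tuple[float, float] = (0.5, 0.85)  #: pause position, fraction of duplex
    asym_frac: float = 0.1        #: fraction of beads with 2:1 axis anisotropy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.c_true < 0:
            raise ValueError("c_true must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not 0.0 <= self.p_unwind <= 1.0:
            raise ValueError("p_unwind must be in [0, 1]")
        if self.t_bind_min is None:
            self.t_bind_min = self.dead_time + 100.0
        if self.t_bind_max is None:
            self.t_bind_max = self.dead_time + 300.0
        if self.t_bind_max < self.t_bind_min:
            raise ValueError("t_bind_max must be >= t_bind_min")


@dataclass(frozen=True)
class TrajectoryTruth:
    """Ground-truth record attached to simulated trajectories."""

    t_start: Optional[float] = None   #: unwinding onset, s (None if never)
    v_true: Optional[float] = None    #: bp/s
    t_release: Optional[float] = None #: bead disappearance, s
    paused: bool = False
    pause_start: Optional[float] = None
    pause_dur: Optional[float] = None
    asymmetric: bool = False
    sigma0: Optional[float] = None    #: this bead's baseline per-axis BM, nm


@dataclass
class Trajectory:
    """Per-bead centroid time series on a uniform frame grid.

    ``recorded`` is False during the dead time (positions are NaN there).
    The array simply ends when the bead disappears.
    """

    bead_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    recorded: np.ndarray
    frame_rate: float
    truth: Optional[TrajectoryTruth] = None
    drift_corrected: bool = False

    def __post_init__(self) -> None:
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-6):
            raise ValueError("times must be uniform at 1/frame_rate")
        rec = self.recorded
        if np.any(~np.isfinite(self.x[rec])) or np.any(~np.isfinite(self.y[rec])):
            raise ValueError("recorded frames must have finite positions")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def disappeared(self) -> bool:
        """True if the trace ends before the configured recording would."""
        return bool(self.truth is not None and self.truth.t_release is not None)


def _ou_unit(n: int, a: float, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary AR(1) path with unit marginal variance.

    ``a = exp(-dt/tau)`` is the one-frame autocorrelation.
    """
    w = rng.standard_normal(n)
    w[0] = rng.standard_normal()          # stationary start, var 1
    scale = np.ones(n)
    scale[1:] = np.sqrt(1.0 - a * a)
    return lfilter([1.0], [1.0, -a], w * scale)


def _unwound_profile(
    t: np.ndarray,
    t_start: float,
    v: float,
    unwindable_bp: int,
    pause_at_bp: Optional[float],
    pause_dur: float,
) -> np.ndarray:
    """Base pairs unwound vs time, with an optional plateau at pause_at_bp."""
    u = np.clip((t - t_start) * v, 0.0, None)
    if pause_at_bp is not None:
        t_pause = t_start + pause_at_bp / v
        after = t > t_pause
        u[after] = pause_at_bp + np.clip((t[after] - t_pause - pause_dur) * v, 0.0, None)
    return np.minimum(u, unwindable_bp)


def simulate_bead_trajectory(
    config: SimulationConfig,
    substrate: Optional[SubstrateSpec] = None,
    rng: Optional[np.random.Generator] = None,
    bead_id: str = "bead0000",
    unwinds: bool = True,
    t_start: Optional[float] = None,
    sigma0: Optional[float] = None,
    asymmetric: bool = False,
    paused: bool = False,
) -> Trajectory:
    """Simulate one bead.

    With ``unwinds`` the per-axis amplitude ramps from ``sigma0`` at
    ``t_start`` (drawn uniformly over the binding window if not given) with
    slope ``c_true*v_true`` until the unwindable duplex is fully open, at
    which point the bead is released and the trajectory ends.  Identical
    config + rng state give bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    unwindable = substrate.unwindable_bp if substrate is not None else config.unwindable_bp
    dt = 1.0 / config.frame_rate
    n = int(round(config.duration * config.frame_rate))
    t = np.arange(n) * dt

    if sigma0 is None:
        sigma0 = max(0.5, config.sigma0 + config.sigma0_sd * rng.standard_normal())

    truth_kwargs = dict(asymmetric=asymmetric, sigma0=sigma0)
    if unwinds and config.v_true > 0:
        if t_start is None:
            t_start = rng.uniform(config.t_bind_min, config.t_bind_max)
        pause_at = None
        if paused:
            pause_at = unwindable * rng.uniform(*config.pause_frac)
        u = _unwound_profile(t, t_start, config.v_true, unwindable,
                             pause_at, config.pause_dur)
        done = u >= unwindable
        if done.any():
            i_rel = int(np.argmax(done))
            t_release = t[i_rel]
            t, u = t[:i_rel], u[:i_rel]
            n = len(t)
        else:
            t_release = None
        truth_kwargs.update(
            t_start=t_start, v_true=config.v_true, t_release=t_release,
            paused=paused,
            pause_start=(t_start + pause_at / config.v_true) if pause_at is not None else None,
            pause_dur=config.pause_dur if paused else None,
        )
    else:
        u = np.zeros(n)

    sigma = sigma0 + config.c_true * u
    a = float(np.exp(-dt / config.tau))
    # 2:1 axis-variance anisotropy keeps the mean of the two axis variances.
    fx, fy = (np.sqrt(4.0 / 3.0), np.sqrt(2.0 / 3.0)) if asymmetric else (1.0, 1.0)
    x = fx * sigma * _ou_unit(n, a, rng) + config.drift * t
    y = fy * sigma * _ou_unit(n, a, rng) + config.drift * t

    recorded = t >= config.dead_time
    x = np.where(recorded, x, np.nan)
    y = np.where(recorded, y, np.nan)

    return Trajectory(
        bead_id=bead_id,
        times=t,
        x=x,
        y=y,
        recorded=recorded,
        frame_rate=config.frame_rate,
        truth=TrajectoryTruth(**truth_kwargs),
    )


def simulate_cohort(
    config: SimulationConfig,
    n: int,
    substrate: Optional[SubstrateSpec] = None,
    rng: Optional[np.random.Generator] = None,
    all_unwind: bool = False,
) -> List[Trajectory]:
    """Simulate a field of view of ``n`` independent tethers.

    Each tether unwinds with probability ``p_unwind`` (or always, with
    ``all_unwind``, for velocity-cohort studies of molecules that were seen
    to unwind); ``asym_frac`` of beads are anisotropic; ``p_pause`` of
    unwinding beads pause before release.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seeds = rng.bit_generator._seed_seq.spawn(n) if hasattr(
        rng.bit_generator, "_seed_seq") else None
    trajs = []
    for i in range(n):
        sub_rng = (np.random.default_rng(seeds[i]) if seeds is not None
                   else np.random.default_rng(rng.integers(2**31)))
        unwinds = all_unwind or (sub_rng.uniform() < config.p_unwind)
        asym = sub_rng.uniform() < config.asym_frac
        paused = unwinds and (sub_rng.uniform() < config.p_pause)
        trajs.append(
            simulate_bead_trajectory(
                config,
                substrate=substrate,
                rng=sub_rng,
                bead_id=f"bead{i:04d}",
                unwinds=unwinds,
                asymmetric=asym,
                paused=paused,
            )
        )
    return trajs


def simulate_population(
    config: SimulationConfig,
    n: int,
    bm_mean: float,
    bm_sd: float,
    rng: Optional[np.random.Generator] = None,
) -> List[Trajectory]:
    """Stationary cohort for population BM measurements.

    Per-bead baseline amplitudes are drawn from N(bm_mean, bm_sd) (truncated
    at 0.5 nm), emulating the tether-to-tether spread of a population
    histogram; no unwinding occurs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trajs = []
    for i in range(n):
        s0 = max(0.5, rng.normal(bm_mean, bm_sd))
        trajs.append(
            simulate_bead_trajectory(
                config,
                rng=rng,
                bead_id=f"bead{i:04d}",
                unwinds=False,
                sigma0=s0,
            )
        )
    return trajs


# ---------------------------------------------------------------------------
# Optional image rendering (Gaussian spot + shot noise), for exercising the
# localization stage.
# ---------------------------------------------------------------------------

@dataclass
class Optics:
    pixel_nm: float = 100.0
    psf_sigma_px: float = 1.2
    photons: float = 5000.0
    background: float = 10.0
    image_size: Tuple[int, int] = (32, 32)


def render_frames(
    traj: Trajectory,
    optics: Optics,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a trajectory as an image stack (frames, rows, cols).

    The bead is a 2-D Gaussian spot centred at the true position (nm mapped
    to pixels about the image centre) with Poisson shot noise on spot and
    background.  Unrecorded frames contain background only.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ny, nx = optics.image_size
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cx0, cy0 = (nx - 1) / 2.0, (ny - 1) / 2.0
    frames = np.empty((traj.n_frames, ny, nx), dtype=float)
    s2 = 2.0 * optics.psf_sigma_px**2
    norm = 2.0 * np.pi * optics.psf_sigma_px**2
    for i in range(traj.n_frames):
        if traj.recorded[i]:
            cx = cx0 + traj.x[i] / optics.pixel_nm
            cy = cy0 + traj.y[i] / optics.pixel_nm
            if not (0 <= cx < nx and 0 <= cy < ny):
                raise ValueError(
                    f"bead position outside field of view at frame {i}"
                )
            spot = optics.photons / norm * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / s2
            )
        else:
            spot = 0.0
        mean = spot + optics.background
        frames[i] = rng.poisson(mean) if optics.photons > 0 or optics.background > 0 else mean
    return frames
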