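"""Unwinding onset detection and per-molecule velocity estimation.

A tether being unwound shows a BM time-course that is flat at the baseline,
rises linearly while the duplex is converted to single strands, and ends when
the bead is released.  Detection and estimation proceed in four steps:

1. **Derivative band test** — the BM series is decimated to non-overlapping
   analysis windows, the first derivative is estimated as a sliding
   least-squares slope over ``deriv_span_s`` seconds, and a 95% marginal band
   (empirical 2.5/97.5 percentiles about the mean) is taken from the initial
   flat baseline segment.  Unwinding is declared when the derivative exceeds
   the upper bound for at least ``persistence`` consecutive decimated points;
   a shorter terminal run (``end_persistence``) is accepted when the bead is
   known to have disappeared, because release truncates the evidence.

2. **Onset refinement** — around the first band crossing the onset is located
   precisely by a least-squares hinge fit (flat baseline followed by a ramp
   of non-negative slope), which is unbiased in the onset time regardless of
   the unwinding speed, unlike the raw crossing time.

3. **Velocity estimation** — two estimators per molecule:
   ``v_slope`` from an ordinary least-squares line over the increasing BM
   section [t_start, t_max] divided by the conversion factor c (nm/bp), and
   ``v_dwell`` = unwindable_bp / (t_max - t_start) from the dwell time to the
   last recorded window before release.

4. **Exclusion rules** — molecules showing a BM plateau (pause) between onset
   and release, and beads that do not disappear or do not rise beforehand,
   are flagged and excluded from velocity statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .processing import BMSeries
from .simulate import Trajectory

__all__ = [
    "DerivativeBand",
    "UnwindEvent",
    "UnwindingDetector",
    "detect_unwind_start",
    "fit_velocity_slope",
    "velocity_dwell",
    "flag_pause",
    "qualify_event",
    "analyze_trajectory",
    "events_table",
]


@dataclass(frozen=True)
class DerivativeBand:
    """Baseline derivative statistics: mean (≈0) and 95% marginal bounds."""

    mean: float   # nm/s
    lower: float  # nm/s
    upper: float  # nm/s
    persistence: int

    def __post_init__(self):
        if not (self.lower < self.mean < self.upper):
            raise ValueError("band must satisfy lower < mean < upper")


@dataclass
class UnwindEvent:
    """Per-molecule unwinding summary."""

    bead_id: str
    t_start: Optional[float]   # s
    t_max: Optional[float]     # s, last recorded window before disappearance
    slope: Optional[float]     # nm/s
    v_slope: Optional[float]   # bp/s
    v_dwell: Optional[float]   # bp/s
    paused: bool
    qualifies: bool
    detected: bool


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    t = t - t.mean()
    return float(t @ (y - y.mean()) / (t @ t))


def _sliding_slope(
    y: np.ndarray, k: int, dt: float, fill_tail: bool = False
) -> np.ndarray:
    """Least-squares slope over a centred sliding window of k samples.

    Returns an array aligned with y; edges (half-window) are NaN.  With
    ``fill_tail``, the trailing edge is filled with right-aligned window
    slopes so the derivative stays estimable up to the final sample (needed
    when bead release truncates the series mid-rise).
    """
    j = np.arange(k) - (k - 1) / 2.0
    w = j / (j @ j) / dt
    out = np.full(len(y), np.nan)
    if len(y) >= k:
        vals = np.convolve(y, w[::-1], mode="valid")
        lo = (k - 1) // 2
        out[lo : lo + len(vals)] = vals
        if fill_tail:
            # right-aligned windows: slope of y[i-k+1 .. i] assigned at i
            for i in range(lo + len(vals), len(y)):
                seg = y[i - k + 1 : i + 1]
                out[i] = w @ seg
    return out


def _decimate(series: BMSeries):
    """Resample a (possibly dense, overlapping-window) BM series onto
    non-overlapping windows so successive points are nearly independent."""
    step = max(1, int(round(series.window_frames / max(1, series.stride))))
    return series.times[::step], series.bm[::step]


class UnwindingDetector(BaseEstimator):
    """Detect unwinding onset and estimate per-molecule velocities.

    Parameters
    ----------
    c : float
        BM->bp conversion factor, nm per base pair.
    unwindable_bp : int
        Duplex length whose complete opening releases the bead.
    deriv_span_s : float
        Span of the sliding least-squares derivative estimate.  Must be long
        enough that the baseline band is narrow compared with the expected
        unwinding slope (c * v).
    baseline_s : float
        Initial flat segment used for the derivative band.
    persistence : int
        Consecutive decimated points required above the upper bound.
    end_persistence : int
        Relaxed persistence for a run that touches the end of the series,
        used only when the bead is known to have disappeared.
    refine_span_s : float
        Half-width of the hinge-fit neighbourhood around the band crossing.
    plateau_min_s, slope_tol : float
        A pause is a span of at least ``plateau_min_s`` with local slope
        magnitude <= ``slope_tol`` (nm/s) below the final BM level.
    qualify_alpha : float
        One-sided significance level for the increasing-BM qualification.
    min_windows : int
        Minimum number of decimated windows required.
    """

    def __init__(
        self,
        c: float = 0.0718,
        unwindable_bp: int = 90,
        deriv_span_s: float = 20.0,
        baseline_s: float = 100.0,
        persistence: int = 30,
        end_persistence: int = 8,
        end_span_s: float = 15.0,
        refine_span_s: float = 40.0,
        plateau_min_s: float = 15.0,
        slope_tol: float = 0.08,
        level_margin_nm: float = 0.5,
        qualify_alpha: float = 0.05,
        min_windows: int = 50,
    ):
        self.c = c
        self.unwindable_bp = unwindable_bp
        self.deriv_span_s = deriv_span_s
        self.baseline_s = baseline_s
        self.persistence = persistence
        self.end_persistence = end_persistence
        self.end_span_s = end_span_s
        self.refine_span_s = refine_span_s
        self.plateau_min_s = plateau_min_s
        self.slope_tol = slope_tol
        self.level_margin_nm = level_margin_nm
        self.qualify_alpha = qualify_alpha
        self.min_windows = min_windows

    # -- helpers ----------------------------------------------------------

    def _band(self, deriv: np.ndarray, t: np.ndarray) -> DerivativeBand:
        base = deriv[(t <= t[0] + self.baseline_s) & np.isfinite(deriv)]
        if len(base) < 10:
            raise ValueError("baseline segment too short for a derivative band")
        lo, hi = np.percentile(base, [2.5, 97.5])
        mean = float(np.mean(base))
        return DerivativeBand(
            mean=mean,
            lower=float(min(lo, mean - 1e-9)),
            upper=float(max(hi, mean + 1e-9)),
            persistence=self.persistence,
        )

    def _first_run(
        self, above: np.ndarray, finite: np.ndarray, disappeared: bool
    ) -> Optional[int]:
        """Index of the first sample of an accepted above-band run.

        A run must last ``persistence`` consecutive points, except that a run
        reaching the last finite derivative sample of a disappearing bead is
        accepted at ``end_persistence`` (release truncates the evidence).
        """
        idx = np.nonzero(above)[0]
        if len(idx) == 0:
            return None
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        last_finite = int(np.nonzero(finite)[0][-1])
        # an instantaneous step elevates a span-k derivative for at most
        # k-1 consecutive samples, so persistence is capped accordingly
        persistence = min(self.persistence, self._k_ - 1)
        for s, e in zip(starts, ends):
            length = idx[e] - idx[s] + 1
            if length >= persistence:
                return int(idx[s])
            if disappeared and idx[e] >= last_finite and length >= self.end_persistence:
                return int(idx[s])
        return None

    def _hinge_refine(
        self, t: np.ndarray, y: np.ndarray, t_cand: float, t_hi: float
    ) -> float:
        """Least-squares hinge (flat, then non-negative ramp) onset estimate."""
        lo = t_cand - self.refine_span_s
        hi = min(t_cand + self.refine_span_s, t_hi)
        sel = (t >= lo - self.refine_span_s) & (t <= t_hi)
        tt, yy = t[sel], y[sel]
        grid = tt[(tt >= lo) & (tt <= hi)]
        if len(grid) == 0 or len(tt) < 8:
            return t_cand
        best_sse, best_t0 = np.inf, t_cand
        for t0 in grid:
            ramp = np.clip(tt - t0, 0.0, None)
            step = (tt >= t0).astype(float)
            # hinge: y = b0 + m*(t-t0)+ ; step: y = b0 + h*1[t>=t0]
            for regressor in (ramp, step):
                A = np.column_stack((np.ones_like(tt), regressor))
                coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
                if coef[1] < 0:
                    continue
                r = yy - A @ coef
                sse = float(r @ r)
                if sse < best_sse:
                    best_sse, best_t0 = sse, float(t0)
        return best_t0

    # -- estimator API ----------------------------------------------------

    def fit(self, series: BMSeries, disappeared: bool = False):
        """Analyze one BM series; set fitted attributes (trailing underscore).

        ``disappeared`` tells the detector that the trace ended with bead
        release (known from the trajectory), enabling the relaxed terminal
        persistence rule and the dwell-time velocity.
        """
        td, yd = _decimate(series)
        if len(td) < self.min_windows:
            raise ValueError(
                f"series {series.bead_id!r}: {len(td)} analysis windows "
                f"< min_windows={self.min_windows}"
            )
        dt = float(np.median(np.diff(td)))
        k = max(5, int(round(self.deriv_span_s / dt)))
        k = min(k, len(td) - 1)
        self._k_ = k
        deriv = _sliding_slope(yd, k, dt, fill_tail=disappeared)
        finite = np.isfinite(deriv)
        self.band_ = self._band(deriv, td)
        above = finite & (deriv > self.band_.upper)
        i0 = self._first_run(above, finite, disappeared)

        terminal = False
        if i0 is None and disappeared:
            # Fast unwinding truncates the evidence: the above-band run can be
            # structurally shorter than any persistence requirement.  Test the
            # terminal rise directly: OLS slope over the last end_span_s must
            # exceed the band and be significantly positive.
            sel = td >= td[-1] - self.end_span_s
            if sel.sum() >= 5:
                res = stats.linregress(td[sel], yd[sel])
                p_pos = res.pvalue / 2.0 if res.slope > 0 else 1.0
                if res.slope > self.band_.upper and p_pos < self.qualify_alpha:
                    i0 = int(np.argmax(sel))
                    terminal = True

        self.detected_ = i0 is not None
        # Maximum BM is achieved at release; the best available estimate is
        # the last frame of the last fully recorded window.
        self.t_max_ = float(
            series.times[-1] + (series.window_frames - 1) / (2.0 * series.frame_rate)
        )
        self.t_start_ = None
        self.slope_ = None
        self.v_slope_ = None
        self.v_dwell_ = None
        self.paused_ = False

        if self.detected_:
            t_cand = float(td[i0])
            self.t_start_ = self._hinge_refine(td, yd, t_cand, self.t_max_)
            if self.t_max_ > self.t_start_:
                sel = (series.times >= self.t_start_) & (series.times <= self.t_max_)
                if sel.sum() >= 5 and self.c > 0:
                    self.slope_ = _ols_slope(series.times[sel], series.bm[sel])
                    self.v_slope_ = self.slope_ / self.c
                if disappeared:
                    self.v_dwell_ = self.unwindable_bp / (self.t_max_ - self.t_start_)
            self.paused_ = flag_pause(
                series,
                self.t_start_,
                self.t_max_,
                plateau_min_s=self.plateau_min_s,
                slope_tol=self.slope_tol,
                level_margin_nm=self.level_margin_nm,
            )
        self.qualifies_ = bool(
            self.detected_
            and disappeared
            and self.slope_ is not None
            and self._increasing_before_end(series)
        )
        return self

    def _increasing_before_end(self, series: BMSeries) -> bool:
        """One-sided test that the pre-disappearance section rises."""
        td, yd = _decimate(series)
        sel = td >= (self.t_start_ if self.t_start_ is not None else td[0])
        tt, yy = td[sel], yd[sel]
        if len(tt) < 5:
            return False
        res = stats.linregress(tt, yy)
        # one-sided p-value for slope > 0
        p = res.pvalue / 2.0 if res.slope > 0 else 1.0 - res.pvalue / 2.0
        return bool(p < self.qualify_alpha)

    def event(self, bead_id: Optional[str] = None) -> UnwindEvent:
        return UnwindEvent(
            bead_id=bead_id or "",
            t_start=self.t_start_,
            t_max=self.t_max_ if self.detected_ else None,
            slope=self.slope_,
            v_slope=self.v_slope_,
            v_dwell=self.v_dwell_,
            paused=self.paused_,
            qualifies=self.qualifies_,
            detected=self.detected_,
        )


def detect_unwind_start(series: BMSeries, disappeared: bool = False, **params) -> Optional[float]:
    """Onset time of unwinding, or None if the derivative never leaves the
    baseline band persistently."""
    det = UnwindingDetector(**params).fit(series, disappeared=disappeared)
    return det.t_start_


def fit_velocity_slope(
    series: BMSeries, t_start: float, t_end: float, c: float
):
    """OLS line over the increasing BM section; returns (slope nm/s, v bp/s)."""
    if c <= 0:
        raise ValueError("conversion factor c must be > 0")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    sel = (series.times >= t_start) & (series.times <= t_end)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 BM windows in the fit section")
    slope = _ols_slope(series.times[sel], series.bm[sel])
    return slope, slope / c


def velocity_dwell(unwindable_bp: int, t_start: float, t_max: float) -> float:
    """Dwell-time velocity: duplex length / (time from onset to maximum BM)."""
    if t_max <= t_start:
        raise ValueError("t_max must exceed t_start")
    return unwindable_bp / (t_max - t_start)


def flag_pause(
    series: BMSeries,
    t_start: float,
    t_max: float,
    plateau_min_s: float = 15.0,
    slope_tol: float = 0.08,
    level_margin_nm: float = 0.5,
) -> bool:
    """True iff a flat span of >= plateau_min_s occurs between onset and
    release at a BM level strictly between baseline and final (a pre-release
    pause).  The level conditions stop flat stretches that merely belong to
    the baseline (onset estimated slightly early) or to the final plateau.
    """
    td, yd = _decimate(series)
    base = yd[td < t_start]
    base_level = float(np.mean(base)) if len(base) >= 3 else -np.inf
    sel = (td >= t_start) & (td <= t_max)
    tt, yy = td[sel], yd[sel]
    if len(tt) < 5:
        return False
    dt = float(np.median(np.diff(tt)))
    k = max(3, int(round(plateau_min_s / dt)))
    if len(tt) < k:
        return False
    slopes = _sliding_slope(yy, k, dt)
    levels = pd.Series(yy).rolling(k, center=True, min_periods=1).mean().to_numpy()
    final_level = float(np.mean(yy[-max(3, k // 3):]))
    flat = (
        (np.abs(slopes) <= slope_tol)
        & (levels < final_level - level_margin_nm)
        & (levels > base_level + level_margin_nm)
    )
    return bool(np.any(flat[np.isfinite(slopes)]))


def qualify_event(
    traj: Trajectory,
    series: BMSeries,
    detector: Optional[UnwindingDetector] = None,
) -> bool:
    """Keep only beads that disappeared with a rising BM section beforehand."""
    det = detector or UnwindingDetector()
    det.fit(series, disappeared=traj.disappeared)
    return det.qualifies_


def analyze_trajectory(
    traj: Trajectory,
    series: BMSeries,
    detector: Optional[UnwindingDetector] = None,
) -> UnwindEvent:
    det = detector or UnwindingDetector()
    det.fit(series, disappeared=traj.disappeared)
    return det.event(bead_id=traj.bead_id)


def events_table(events: Sequence[UnwindEvent]) -> pd.DataFrame:
    """Events as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "bead_id": e.bead_id,
                "t_start_s": e.t_start,
                "t_max_s": e.t_max,
                "slope_nm_s": e.slope,
                "v_slope_bp_s": e.v_slope,
                "v_dwell_bp_s": e.v_dwell,
                "paused": e.paused,
                "qualifies": e.qualifies,
            }
            for e in events
        ]
    )
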