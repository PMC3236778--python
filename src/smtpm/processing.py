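"""Trajectory -> Brownian-motion amplitude processing and BM->bp calibration.

The analysis chain is:

1. drift correction — subtract a centred moving average from each axis,
2. symmetry QC — keep only beads whose x/y MSD ratio is in [0.9, 1.1]
   (a bead tethered by more than one DNA molecule moves anisotropically),
3. windowed BM series — within sliding windows of ``window_frames`` frames,
   MSD per axis is the within-window variance <x^2>-<x>^2 and the scalar
   amplitude is BM = sqrt((MSD_x + MSD_y)/2), i.e. the per-axis RMS excursion,
4. population BM — one value per bead from a single block of 1000 consecutive
   frames, summarized by a Gaussian mean/sd across beads,
5. calibration — the BM difference between a mimicked-unwound and an intact
   fork population divided by their duplex-length difference gives the
   conversion factor c in nm per unwound base pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import Optics, Trajectory

__all__ = [
    "BeadQC",
    "BMSeries",
    "BMPopulation",
    "CalibrationResult",
    "DriftCorrector",
    "BMAnalyzer",
    "SymmetryFilter",
    "correct_drift",
    "bm_series",
    "qc_symmetry",
    "population_bm",
    "calibrate",
    "localize_centroids",
]


@dataclass(frozen=True)
class BeadQC:
    bead_id: str
    msd_x: float     # nm^2
    msd_y: float     # nm^2
    ratio: float     # msd_x / msd_y
    symmetric: bool  # ratio within the closed interval [lower, upper]
    n_frames: int


@dataclass
class BMSeries:
    """Windowed BM amplitude vs time (window centres)."""

    bead_id: str
    times: np.ndarray      # s
    bm: np.ndarray         # nm
    window_frames: int
    frame_rate: float
    stride: int = 1

    @property
    def window_s(self) -> float:
        return self.window_frames / self.frame_rate

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class BMPopulation:
    """Per-bead BM values of a substrate population and their Gaussian fit."""

    values: np.ndarray
    mean: float
    sd: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class CalibrationResult:
    c: float           # nm per bp
    bm_initial: float  # nm
    bm_final: float    # nm
    delta_bp: int


class DriftCorrector(BaseEstimator, TransformerMixin):
    """Remove slow stage drift by subtracting a centred moving average.

    The averaging window (default 10 s) is long compared with the BM
    analysis window (0.67 s) so bead fluctuations are preserved while
    drift on many-second scales is removed.
    """

    def __init__(self, drift_window_s: float = 10.0):
        self.drift_window_s = drift_window_s

    def fit(self, X=None, y=None):
        return self

    def _transform_one(self, traj: Trajectory) -> Trajectory:
        n_win = int(round(self.drift_window_s * traj.frame_rate))
        n_rec = int(traj.recorded.sum())
        if n_rec < n_win:
            raise ValueError(
                f"trajectory {traj.bead_id!r}: {n_rec} recorded frames, "
                f"shorter than the {n_win}-frame drift window"
            )
        out = {}
        for axis in ("x", "y"):
            v = pd.Series(getattr(traj, axis))
            baseline = v.rolling(n_win, center=True, min_periods=max(2, n_win // 4)).mean()
            out[axis] = (v - baseline).to_numpy()
        return Trajectory(
            bead_id=traj.bead_id,
            times=traj.times,
            x=out["x"],
            y=out["y"],
            recorded=traj.recorded.copy(),
            frame_rate=traj.frame_rate,
            truth=traj.truth,
            drift_corrected=True,
        )

    def transform(self, X: Union[Trajectory, Sequence[Trajectory]]):
        if isinstance(X, Trajectory):
            return self._transform_one(X)
        return [self._transform_one(t) for t in X]


class BMAnalyzer(BaseEstimator, TransformerMixin):
    """Sliding-window BM amplitude of a (drift-corrected) trajectory.

    Per window of ``window_frames`` frames the per-axis MSD is the
    population-form within-window variance; BM = sqrt((MSD_x+MSD_y)/2).
    Windows advance by ``stride`` frames; any window overlapping an
    unrecorded frame is dropped.
    """

    def __init__(self, window_frames: int = 20, stride: int = 1):
        self.window_frames = window_frames
        self.stride = stride

    def fit(self, X=None, y=None):
        return self

    def _transform_one(self, traj: Trajectory) -> BMSeries:
        w = self.window_frames
        if w < 2:
            raise ValueError("window_frames must be >= 2")
        if int(traj.recorded.sum()) < w:
            raise ValueError(
                f"trajectory {traj.bead_id!r} has fewer than "
                f"{w} recorded frames"
            )
        x = pd.Series(np.where(traj.recorded, traj.x, np.nan))
        y = pd.Series(np.where(traj.recorded, traj.y, np.nan))
        # min_periods=w: a single NaN (unrecorded frame) invalidates the window
        vx = x.rolling(w).var(ddof=0).to_numpy()
        vy = y.rolling(w).var(ddof=0).to_numpy()
        bm = np.sqrt((vx + vy) / 2.0)
        centers = traj.times - (w - 1) / (2.0 * traj.frame_rate)
        valid = np.isfinite(bm)
        idx = np.nonzero(valid)[0][:: self.stride]
        return BMSeries(
            bead_id=traj.bead_id,
            times=centers[idx],
            bm=bm[idx],
            window_frames=w,
            frame_rate=traj.frame_rate,
            stride=self.stride,
        )

    def transform(self, X: Union[Trajectory, Sequence[Trajectory]]):
        if isinstance(X, Trajectory):
            return self._transform_one(X)
        return [self._transform_one(t) for t in X]


class SymmetryFilter(BaseEstimator, TransformerMixin):
    """Single-tether QC: the x/y MSD ratio over ``n_frames`` recorded frames
    must fall in the closed interval [lower, upper] (default [0.9, 1.1])."""

    def __init__(self, n_frames: int = 1000, lower: float = 0.9, upper: float = 1.1):
        self.n_frames = n_frames
        self.lower = lower
        self.upper = upper

    def fit(self, X=None, y=None):
        return self

    def qc(self, traj: Trajectory) -> BeadQC:
        rec = np.nonzero(traj.recorded)[0]
        if len(rec) < self.n_frames:
            raise ValueError(
                f"trajectory {traj.bead_id!r}: {len(rec)} recorded frames "
                f"< n_frames={self.n_frames}"
            )
        sel = rec[: self.n_frames]
        msd_x = float(np.var(traj.x[sel]))
        msd_y = float(np.var(traj.y[sel]))
        ratio = msd_x / msd_y if msd_y > 0 else np.inf
        return BeadQC(
            bead_id=traj.bead_id,
            msd_x=msd_x,
            msd_y=msd_y,
            ratio=ratio,
            symmetric=bool(self.lower <= ratio <= self.upper),
            n_frames=self.n_frames,
        )

    def transform(self, X: Sequence[Trajectory]) -> List[Trajectory]:
        return [t for t in X if self.qc(t).symmetric]


def correct_drift(traj: Trajectory, drift_window_s: float = 10.0) -> Trajectory:
    return DriftCorrector(drift_window_s).transform(traj)


def bm_series(traj: Trajectory, window_frames: int = 20, stride: int = 1) -> BMSeries:
    return BMAnalyzer(window_frames, stride).transform(traj)


def qc_symmetry(traj: Trajectory, n_frames: int = 1000) -> BeadQC:
    return SymmetryFilter(n_frames).qc(traj)


def population_bm(
    trajs: Sequence[Trajectory],
    n_frames: int = 1000,
    qc: bool = True,
) -> BMPopulation:
    """One BM value per bead from its first ``n_frames`` consecutive recorded
    frames; the population is summarized by the sample mean and sd of the
    per-bead values (the unbinned equivalent of a Gaussian histogram fit).

    With ``qc`` (default), beads failing the symmetry filter are excluded
    before anything is computed.
    """
    if qc:
        trajs = SymmetryFilter(n_frames).transform(trajs)
    values = []
    for traj in trajs:
        rec = np.nonzero(traj.recorded)[0]
        if len(rec) < n_frames:
            raise ValueError(
                f"trajectory {traj.bead_id!r} has < {n_frames} recorded frames"
            )
        sel = rec[:n_frames]
        bm = np.sqrt((np.var(traj.x[sel]) + np.var(traj.y[sel])) / 2.0)
        values.append(bm)
    if len(values) < 2:
        raise ValueError("need at least 2 beads for a population fit")
    values = np.asarray(values)
    sd = float(np.std(values, ddof=1))
    return BMPopulation(
        values=values,
        mean=float(np.mean(values)),
        sd=sd,
        n=len(values),
        degenerate=sd == 0.0,
    )


def calibrate(
    initial: Union[BMPopulation, float],
    final: Union[BMPopulation, float],
    delta_bp: int,
) -> CalibrationResult:
    """BM->bp conversion factor from two substrate populations.

    c = (final mean BM - initial mean BM) / delta_bp, where ``delta_bp`` is
    the duplex-length difference between the two substrates (71 bp for the
    fork vs mimicked-unwound pair).
    """
    if delta_bp <= 0:
        raise ValueError("delta_bp must be > 0")
    bm_i = initial.mean if isinstance(initial, BMPopulation) else float(initial)
    bm_f = final.mean if isinstance(final, BMPopulation) else float(final)
    c = (bm_f - bm_i) / delta_bp
    if c < 0:
        warnings.warn("negative conversion factor: final BM below initial BM")
    return CalibrationResult(c=c, bm_initial=bm_i, bm_final=bm_f, delta_bp=delta_bp)


def localize_centroids(
    stack: np.ndarray,
    optics: Optics,
    threshold: Optional[float] = None,
    frame_rate: float = 30.0,
    bead_id: str = "bead0000",
) -> Trajectory:
    """Track the bead in an image stack by intensity-weighted centroids.

    Per frame, the background (median intensity) is subtracted, pixels above
    ``threshold`` (default 5x the background MAD-scale) are segmented into
    spots, and the spot nearest the previous position is kept; its
    intensity-weighted centroid, converted via ``optics.pixel_nm``, is the
    bead position (relative to the image centre).  Frames with no spot are
    marked unrecorded.  Two candidate spots in the very first frame are
    ambiguous and raise an error.
    """
    from skimage.measure import label, regionprops

    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or len(stack) == 0:
        raise ValueError("stack must be a non-empty (frames, ny, nx) array")
    ny, nx = stack.shape[1:]
    cx0, cy0 = (nx - 1) / 2.0, (ny - 1) / 2.0

    xs = np.full(len(stack), np.nan)
    ys = np.full(len(stack), np.nan)
    recorded = np.zeros(len(stack), dtype=bool)
    prev = None
    for i, frame in enumerate(stack):
        bg = np.median(frame)
        resid = frame - bg
        thr = threshold if threshold is not None else 5.0 * max(
            1.0, 1.4826 * np.median(np.abs(resid)))
        mask = resid > thr
        if not mask.any():
            continue
        labels = label(mask)
        props = regionprops(labels, intensity_image=np.clip(resid, 0, None))
        # drop noise specks: keep regions within 5% of the brightest one
        brightest = max(p.intensity_mean * p.area for p in props)
        props = [
            p for p in props if p.intensity_mean * p.area >= 0.05 * brightest
        ]
        if len(props) > 1:
            if prev is None:
                raise ValueError(
                    f"frame {i}: multiple candidate spots before any "
                    "track is established"
                )
            props = sorted(
                props,
                key=lambda p: (p.centroid_weighted[1] - prev[0]) ** 2
                + (p.centroid_weighted[0] - prev[1]) ** 2,
            )
        cy, cx = props[0].centroid_weighted
        prev = (cx, cy)
        xs[i] = (cx - cx0) * optics.pixel_nm
        ys[i] = (cy - cy0) * optics.pixel_nm
        recorded[i] = True
    if not recorded.any():
        raise ValueError("no spot found in any frame")
    return Trajectory(
        bead_id=bead_id,
        times=np.arange(len(stack)) / frame_rate,
        x=xs,
        y=ys,
        recorded=recorded,
        frame_rate=frame_rate,
    )
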