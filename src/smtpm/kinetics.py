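"""Cohort- and ensemble-level kinetics.

Covers the statistics layered on top of per-molecule velocities and on the
ensemble assays run alongside a TPM experiment:

* ordinary nonparametric bootstrap of the cohort mean velocity,
* Michaelis–Menten fit of the ATP dependence, v = Vmax*S/(Km+S),
* coupled-assay ATPase rates from A340 absorbance slopes
  (rate [µM/min] = |dA340/dt| [1/s] * 9820),
* gel-shift unwinding normalization
  %Unwound = (%U_S - %U_0) / (%U_100C - %U_0) * 100,
* fold changes relative to a reference condition,
* cumulative tether-disappearance time-courses with a saturating
  exponential fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "VelocityCohort",
    "BootstrapResult",
    "MMKinetics",
    "MichaelisMentenModel",
    "AtpaseResult",
    "GelResult",
    "DisappearanceCurve",
    "ATPASE_SCALE",
    "bootstrap_mean",
    "fit_michaelis_menten",
    "atpase_rate",
    "percent_unwound",
    "fold_change",
    "disappearance_curve",
]

#: Conversion from |dA340/dt| (1/s) to ATP hydrolysis rate (µM/min) for the
#: pyruvate-kinase / lactate-dehydrogenase coupled assay; embeds the NADH
#: extinction coefficient and path length and is taken as a fixed constant.
ATPASE_SCALE = 9820.0


@dataclass
class VelocityCohort:
    """Per-molecule unwinding velocities of one condition (qualifying,
    non-paused molecules only)."""

    label: str
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        if np.any(self.velocities <= 0):
            raise ValueError("velocities must be positive")

    @property
    def n(self) -> int:
        return len(self.velocities)

    @property
    def mean(self) -> float:
        return float(np.mean(self.velocities))

    @property
    def sd(self) -> float:
        return float(np.std(self.velocities, ddof=1))


@dataclass
class BootstrapResult:
    resamples: int
    means: np.ndarray  # one mean per resample
    mean: float
    sd: float
    seed: int

    def percentile_interval(self, level: float = 0.95) -> Tuple[float, float]:
        a = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(self.means, [a, 100.0 - a])
        return float(lo), float(hi)


def bootstrap_mean(
    cohort: Union[VelocityCohort, Sequence[float]],
    resamples: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Ordinary nonparametric bootstrap of the cohort mean.

    Each resample draws n values with replacement and records the resample
    mean; the summary is the mean and sd of the resample means.  Fixed seed
    gives identical output.
    """
    values = cohort.velocities if isinstance(cohort, VelocityCohort) else np.asarray(cohort, float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(resamples, n))
    means = values[idx].mean(axis=1)
    return BootstrapResult(
        resamples=resamples,
        means=means,
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Michaelis–Menten
# ---------------------------------------------------------------------------

class MichaelisMentenModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S).

    Initialization: Vmax0 = max(v), Km0 = median(S); both parameters bounded
    positive.  ``sample_weight`` (1/sd^2 style weights) is optional; the
    default is an unweighted fit.
    """

    def __init__(self, vmax0: Optional[float] = None, km0: Optional[float] = None):
        self.vmax0 = vmax0
        self.km0 = km0

    @staticmethod
    def _model(S, vmax, km):
        return vmax * S / (km + S)

    def fit(self, S, v, sample_weight=None):
        S = np.asarray(S, dtype=float).ravel()
        v = np.asarray(v, dtype=float).ravel()
        if len(S) != len(v):
            raise ValueError("S and v must have equal length")
        if len(np.unique(S)) < 3:
            raise ValueError("need at least 3 distinct substrate concentrations")
        if np.any(v < 0) or np.any(S <= 0):
            raise ValueError("require S > 0 and v >= 0")
        p0 = (
            self.vmax0 if self.vmax0 is not None else float(np.max(v)),
            self.km0 if self.km0 is not None else float(np.median(S)),
        )
        sigma = None
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
            sigma = 1.0 / np.sqrt(w)
        try:
            popt, pcov = curve_fit(
                self._model,
                S,
                v,
                p0=p0,
                sigma=sigma,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
            )
        except RuntimeError as err:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"Michaelis-Menten fit did not converge (p0={p0}): {err}"
            ) from err
        self.Vmax_, self.Km_ = float(popt[0]), float(popt[1])
        self.covariance_ = pcov
        self.converged_ = True
        return self

    def predict(self, S):
        S = np.asarray(S, dtype=float)
        return self._model(S, self.Vmax_, self.Km_)


@dataclass
class MMKinetics:
    Vmax: float  # bp/s
    Km: float    # mM
    points: pd.DataFrame  # columns: S, v (and optionally n, sd)
    covariance: np.ndarray
    converged: bool

    def predict(self, S):
        return self.Vmax * np.asarray(S, float) / (self.Km + np.asarray(S, float))


def fit_michaelis_menten(
    points: Union[pd.DataFrame, Sequence[Tuple[float, float]]],
    weights: Optional[np.ndarray] = None,
) -> MMKinetics:
    """Fit the ATP dependence of the unwinding velocity.

    ``points`` is a DataFrame with columns S (mM) and v (bp/s), or a sequence
    of (S, v) pairs.  Unweighted by default.
    """
    if isinstance(points, pd.DataFrame):
        df = points.copy()
    else:
        df = pd.DataFrame(points, columns=["S", "v"])
    model = MichaelisMentenModel().fit(df["S"], df["v"], sample_weight=weights)
    return MMKinetics(
        Vmax=model.Vmax_,
        Km=model.Km_,
        points=df,
        covariance=model.covariance_,
        converged=model.converged_,
    )


# ---------------------------------------------------------------------------
# ATPase and gel shift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtpaseResult:
    slope_a340: float  # |dA340/dt|, 1/s
    rate: float        # µM/min


def atpase_rate(
    times_s: Sequence[float],
    a340: Sequence[float],
    window: Optional[Tuple[float, float]] = None,
) -> AtpaseResult:
    """ATP hydrolysis rate from the linear decrease of NADH absorbance.

    The least-squares A340 slope over ``window`` (default: the whole trace)
    is converted as rate = |slope| * 9820 µM/min.  An increasing A340 means
    no NADH consumption; the rate is reported as 0 with a warning.
    """
    t = np.asarray(times_s, dtype=float)
    a = np.asarray(a340, dtype=float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, a = t[sel], a[sel]
    if len(t) < 2:
        raise ValueError("need at least 2 points in the fit window")
    slope = float(np.polyfit(t, a, 1)[0])
    if slope > 0:
        warnings.warn("A340 increases over the window; ATPase rate reported as 0")
        return AtpaseResult(slope_a340=0.0, rate=0.0)
    return AtpaseResult(slope_a340=abs(slope), rate=abs(slope) * ATPASE_SCALE)


def percent_unwound(us: float, u0: float, u100: float) -> float:
    """Gel-shift normalization: (%U_S - %U_0)/(%U_100C - %U_0) * 100.

    ``us``, ``u0``, ``u100`` are raw percent-unwound signals of the sample,
    the unreacted substrate and the boiled substrate.  Values outside
    [0, 100] are reported as-is (see GelResult.clipped for a flag).
    """
    if u100 == u0:
        raise ValueError("boiled and unreacted controls are equal; cannot normalize")
    return (us - u0) / (u100 - u0) * 100.0


@dataclass(frozen=True)
class GelResult:
    Us: float
    U0: float
    U100: float
    unwound: float          # normalized %
    clipped: bool           # True if unwound fell outside [0, 100]
    fold_vs_ref: Optional[float] = None


def gel_result(us: float, u0: float, u100: float,
               reference_unwound: Optional[float] = None) -> GelResult:
    p = percent_unwound(us, u0, u100)
    return GelResult(
        Us=us,
        U0=u0,
        U100=u100,
        unwound=p,
        clipped=not (0.0 <= p <= 100.0),
        fold_vs_ref=(p / reference_unwound) if reference_unwound else None,
    )


def fold_change(value: float, reference: float) -> float:
    """Ratio of a measure to its reference-condition value."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return value / reference


# ---------------------------------------------------------------------------
# Tether disappearance
# ---------------------------------------------------------------------------

@dataclass
class DisappearanceCurve:
    times: np.ndarray      # sorted bead-loss times, s
    total: int
    fraction: np.ndarray   # cumulative percent disappeared at `times`
    y0: Optional[float] = None
    amplitude: Optional[float] = None
    t_const: Optional[float] = None
    residuals: Optional[np.ndarray] = None
    model: str = "amplitude"


def disappearance_curve(
    loss_times: Sequence[float],
    total: int,
    model: str = "amplitude",
) -> DisappearanceCurve:
    """Cumulative percent of disappeared tethers vs time, with a saturating
    exponential fit.

    Models:

    * ``"amplitude"`` (default): y = y0 + A*(1 - exp(-t/tc)) with free
      amplitude A — the well-posed form for a percent axis.
    * ``"unit"``: y = y0 + (1 - (1/tc)*exp(-t/tc)), the fixed-amplitude
      variant with a 1/tc prefactor, available for comparison.

    With zero events the empirical curve is returned and the fit skipped.
    """
    times = np.sort(np.asarray(loss_times, dtype=float))
    if total < len(times):
        raise ValueError("total tether count below number of loss events")
    frac = 100.0 * np.arange(1, len(times) + 1) / total
    curve = DisappearanceCurve(times=times, total=total, fraction=frac, model=model)
    if len(times) < 3:
        return curve

    if model == "amplitude":
        def f(t, y0, a, tc):
            return y0 + a * (1.0 - np.exp(-t / tc))
        # amplitude cannot exceed the percent axis
        p0 = (0.0, max(frac[-1], 1.0), max(np.median(times), 1e-6))
        bounds = ([-100.0, 0.0, 1e-9], [100.0, 100.0, np.inf])
    elif model == "unit":
        def f(t, y0, tc):
            return y0 + (1.0 - np.exp(-t / tc) / tc)
        p0 = (0.0, max(np.median(times), 1e-6))
        bounds = ([-100.0, 1e-9], [100.0, np.inf])
    else:
        raise ValueError(f"unknown disappearance model {model!r}")

    popt, _ = curve_fit(f, times, frac, p0=p0, bounds=bounds, maxfev=20000)
    fitted = f(times, *popt)
    curve.y0 = float(popt[0])
    curve.t_const = float(popt[-1])
    curve.amplitude = float(popt[1]) if model == "amplitude" else 1.0
    curve.residuals = frac - fitted
    return curve
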