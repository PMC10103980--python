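"""Tumor/tumoroid geometry, exponential growth fits, and response calls.

Projected tumor area is the elliptical approximation A = pi/4 * L * W from two
perpendicular caliper measurements. Growth series are fit by nonlinear least
squares to A = A0*e^(k*t) (tumors) or A = A1*e^(k*(t-1)) (tumoroids, whose
areas are indexed from day 1). An area of 125 mm^2 is the default terminal
burden for survival bookkeeping, and a subject is a partial responder when it
survives at least a week beyond the reference cohort's median survival.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

TERMINAL_AREA_MM2 = 125.0
REF_MEDIAN_SURVIVAL_DAYS = 13.0
PARTIAL_MARGIN_DAYS = 7.0
OBSERVATION_WINDOW_DAYS = 100.0


@dataclass(frozen=True)
class GrowthSeries:
    """Per-subject (day, projected area mm^2) time series."""

    subject_id: str
    time: np.ndarray
    area: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.area, dtype=float)
        if t.size != a.size:
            raise ValueError("time and area must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("areas must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "area", a)


@dataclass(frozen=True)
class ExponentialFit:
    """Fitted exponential growth parameters for one subject."""

    prefactor: float     # A0 (tumor) or A1 (tumoroid), mm^2
    k: float             # exponential growth rate, per day
    rss: float           # residual sum of squares, mm^4
    model: str           # {"tumor", "tumoroid"}
    converged: bool
    n_points: int


@dataclass(frozen=True)
class ResponseCall:
    subject_id: str
    category: str        # {"complete", "partial", "none"}
    survival_days: float
    reached_terminal: bool


def projected_area(L: float, W: float) -> float:
    """Elliptical projected area pi/4 * L * W (mm^2) from caliper axes.

    ``L`` is the length along the longest axis and ``W`` the perpendicular
    width, so ``L >= W > 0`` is required.
    """
    if W <= 0 or L <= 0:
        raise ValueError("axes must be positive")
    if W > L:
        raise ValueError("W > L: axes swapped (L is the longest axis)")
    return math.pi / 4 * L * W


def terminal_burden(area: float, threshold: float = TERMINAL_AREA_MM2) -> bool:
    """True when the projected area has reached the terminal threshold (>=)."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return area >= threshold


def _model_time(t: np.ndarray, model: str) -> np.ndarray:
    if model == "tumor":
        return t
    if model == "tumoroid":
        return t - 1.0
    raise ValueError(f"unknown model: {model!r}")


def fit_exponential(series: GrowthSeries, model: str = "tumor") -> ExponentialFit:
    """Nonlinear least-squares fit of the exponential growth model.

    Zero-area time points (fully regressed tumors) are excluded; at least
    three positive points are required. The fit is initialized from ordinary
    least squares on log areas, then refined by Levenberg-Marquardt on the
    untransformed areas. Non-convergence is reported via ``converged=False``
    with the best available parameters, not raised.
    """
    pos = series.area > 0
    t = _model_time(series.time[pos], model)
    a = series.area[pos]
    if a.size < 3:
        raise ValueError(
            f"subject {series.subject_id!r}: need >= 3 positive-area points, "
            f"have {a.size}")
    slope, intercept = np.polyfit(t, np.log(a), 1)
    p0 = (math.exp(intercept), slope)
    converged = True
    try:
        popt, _ = curve_fit(lambda tt, A, k: A * np.exp(k * tt), t, a,
                            p0=p0, maxfev=10_000)
    except RuntimeError:
        warnings.warn(
            f"exponential fit did not converge for {series.subject_id!r}; "
            "reporting log-linear initialization", RuntimeWarning)
        popt, converged = p0, False
    rss = float(np.sum((a - popt[0] * np.exp(popt[1] * t)) ** 2))
    return ExponentialFit(prefactor=float(popt[0]), k=float(popt[1]),
                          rss=rss, model=model, converged=converged,
                          n_points=int(a.size))


def classify_response(survival_days: float, reached_terminal: bool,
                      ref_median: float = REF_MEDIAN_SURVIVAL_DAYS,
                      margin: float = PARTIAL_MARGIN_DAYS,
                      subject_id: str = "") -> ResponseCall:
    """Classify a subject as complete / partial / no responder.

    A complete responder never reached terminal burden within the observation
    window; a partial responder reached it but survived at least ``margin``
    days beyond the reference cohort's median survival.
    """
    if survival_days <= 0:
        raise ValueError("survival_days must be > 0")
    if not reached_terminal:
        category = "complete"
    elif survival_days >= ref_median + margin:
        category = "partial"
    else:
        category = "none"
    return ResponseCall(subject_id=subject_id, category=category,
                        survival_days=float(survival_days),
                        reached_terminal=bool(reached_terminal))
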