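"""Four-parameter-logistic (4PL) calibration of the colorimetric response.

Enzyme/HRP colorimetric assays saturate at high substrate-binding, so the
standard curve relating detection-reagent (cholesterol-bound) concentration
to the instrument's retrieved signal is nonlinear.  The standard model for
such assays is the four-parameter logistic in log10 concentration:

    f(c) = lower + (upper - lower) / (1 + 10**(slope * (mid - log10(c))))

with lower < upper and slope > 0 so signal increases with concentration.
The curve is a monotone bijection between concentration and the open
interval (lower, upper), and its inverse is closed-form, which is how a
measured signal is converted back into cholesterol content.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    FitQualityWarning,
    InsufficientDataError,
    OutOfRangeError,
    ValidationError,
)

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "fit_calibration_curve",
    "predict_signal",
    "invert_to_concentration",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration standard: concentration (ug/ml) and measured signal."""

    concentration: float
    signal: float
    replicate_sd: float | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValidationError("calibration concentration must be positive")
        if self.replicate_sd is not None and self.replicate_sd < 0:
            raise ValidationError("replicate_sd must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted 4PL standard curve (parameters in log10-concentration space).

    ``invertible`` is False when the fitted span (upper - lower) is too
    small to support a meaningful inverse (near-flat data).
    """

    lower: float
    upper: float
    midpoint_log10: float
    slope: float
    conc_range: tuple[float, float]
    rss: float
    units: str = "a.u."
    invertible: bool = True

    def __post_init__(self) -> None:
        if self.invertible and not self.lower < self.upper:
            raise ValidationError("lower asymptote must lie below upper asymptote")
        if self.slope < 0:
            raise ValidationError("slope must be non-negative (signal increases with c)")

    @property
    def midpoint_concentration(self) -> float:
        return 10.0 ** self.midpoint_log10

    def to_dict(self) -> dict:
        return {
            "model": "4PL-log10",
            "lower": self.lower,
            "upper": self.upper,
            "midpoint_log10": self.midpoint_log10,
            "slope": self.slope,
            "conc_range": list(self.conc_range),
            "rss": self.rss,
            "units": self.units,
            "invertible": self.invertible,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            lower=d["lower"],
            upper=d["upper"],
            midpoint_log10=d["midpoint_log10"],
            slope=d["slope"],
            conc_range=tuple(d["conc_range"]),
            rss=d["rss"],
            units=d.get("units", "a.u."),
            invertible=d.get("invertible", True),
        )


def _four_pl(x: np.ndarray, lower: float, span: float, mid: float, slope: float):
    return lower + span / (1.0 + 10.0 ** (slope * (mid - x)))


def fit_calibration_curve(
    points: Sequence[CalibrationPoint], units: str = "a.u."
) -> CalibrationCurve:
    """Nonlinear least-squares 4PL fit in log10-concentration space.

    Initialization is self-starting: asymptotes from the signal extremes,
    midpoint from the concentration whose signal is nearest mid-signal,
    unit slope.  Monotonicity is enforced by construction (span >= 0,
    slope >= 0).  Poorly described data (relative residual above 20% of the
    signal variance, or a near-flat fit) emits :class:`FitQualityWarning`;
    a near-flat curve is additionally flagged non-invertible.
    """
    if len(points) < 5:
        raise InsufficientDataError("need at least 5 calibration points")
    conc = np.array([p.concentration for p in points], dtype=float)
    sig = np.array([p.signal for p in points], dtype=float)
    if np.unique(conc).size < 5:
        raise InsufficientDataError("need at least 5 distinct concentrations")

    x = np.log10(conc)
    span0 = float(sig.max() - sig.min())
    scale = max(float(np.abs(sig).max()), 1.0)
    flat_tol = 1e-10 * scale

    if span0 <= flat_tol:
        warnings.warn(
            "calibration signals are constant; curve is flat and non-invertible",
            FitQualityWarning,
            stacklevel=2,
        )
        level = float(sig.mean())
        return CalibrationCurve(
            lower=level,
            upper=level,
            midpoint_log10=float(np.median(x)),
            slope=1.0,
            conc_range=(float(conc.min()), float(conc.max())),
            rss=float(np.sum((sig - level) ** 2)),
            units=units,
            invertible=False,
        )

    mid0 = float(x[np.argmin(np.abs(sig - (sig.min() + span0 / 2.0)))])
    p0 = [float(sig.min()), span0, mid0, 1.0]
    bounds = ([-np.inf, 1e-12, -np.inf, 1e-6], [np.inf, np.inf, np.inf, 1e3])
    popt, _ = curve_fit(
        _four_pl,
        x,
        sig,
        p0=p0,
        bounds=bounds,
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=50_000,
    )
    lower, span, mid, slope = (float(v) for v in popt)
    rss = float(np.sum((_four_pl(x, *popt) - sig) ** 2))
    total_ss = float(np.sum((sig - sig.mean()) ** 2))
    invertible = span > flat_tol
    if not invertible or (total_ss > 0 and rss > 0.2 * total_ss):
        warnings.warn(
            f"calibration fit quality is poor (rss={rss:.4g}, total ss={total_ss:.4g})",
            FitQualityWarning,
            stacklevel=2,
        )
    return CalibrationCurve(
        lower=lower,
        upper=lower + span,
        midpoint_log10=mid,
        slope=slope,
        conc_range=(float(conc.min()), float(conc.max())),
        rss=rss,
        units=units,
        invertible=invertible,
    )


def predict_signal(curve: CalibrationCurve, concentration: float) -> float:
    """Evaluate the fitted 4PL at a positive concentration."""
    if concentration <= 0:
        raise ValidationError("concentration must be positive")
    return float(
        _four_pl(
            np.log10(concentration),
            curve.lower,
            curve.upper - curve.lower,
            curve.midpoint_log10,
            curve.slope,
        )
    )


def invert_to_concentration(curve: CalibrationCurve, signal: float) -> float:
    """Closed-form 4PL inverse: the unique c with predict_signal(c) = signal.

    Valid only for signals strictly inside the open asymptote interval
    (lower, upper); anything else raises :class:`OutOfRangeError`.
    """
    if not curve.invertible:
        raise OutOfRangeError("curve is flagged non-invertible (near-flat fit)")
    if not (curve.lower < signal < curve.upper):
        raise OutOfRangeError(
            f"signal {signal:g} outside invertible interval "
            f"({curve.lower:g}, {curve.upper:g})"
        )
    span = curve.upper - curve.lower
    # y = L + span / (1 + 10**(b(m-x)))  =>  x = m - log10(span/(y-L) - 1)/b
    x = curve.midpoint_log10 - math.log10(span / (signal - curve.lower) - 1.0) / curve.slope
    return 10.0 ** x
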