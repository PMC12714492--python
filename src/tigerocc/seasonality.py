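"""Seasonality of rescue events: monthly aggregation and sinusoid fitting.

Rescues are totalled by calendar month over the analysis window and a
single-harmonic sinusoid with a fixed 12-month period,

    f(m) = a0 + a1 sin(2*pi*m/12) + a2 cos(2*pi*m/12),

is fitted by ordinary least squares at month midpoints m in {0.5, ...,
11.5}.  On the sin/cos basis this is the closed-form minimum-MSE fit over
level, amplitude and phase.  The derived amplitude is sqrt(a1^2 + a2^2);
the fitted peak and trough are a0 +/- amplitude, exactly six months apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey_data import filter_window

__all__ = ["monthly_counts", "fit_sinusoid", "peak_trough", "SinusoidFit",
           "MONTH_NAMES"]

MONTH_NAMES = ("January", "February", "March", "April", "May", "June",
               "July", "August", "September", "October", "November",
               "December")

_MIDPOINTS = np.arange(12) + 0.5
_DEGENERATE_TOL = 1e-9


def monthly_counts(rescues: pd.DataFrame,
                   window: tuple[str, str] | None = None) -> np.ndarray:
    """Rescues per calendar month (summed across years) within the window.

    Returns a length-12 integer array (January first).  Rescues outside the
    window are excluded (and logged by the window filter).
    """
    df = rescues
    if window is not None:
        df, _ = filter_window(rescues, *window)
    months = pd.DatetimeIndex(df["date"]).month
    return np.bincount(months - 1, minlength=12).astype(int)


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares single-harmonic fit to the 12 monthly totals.

    ``peak``/``trough`` are month fractions in [0, 12) on the midpoint time
    axis (0 = start of January); ``degenerate`` flags an amplitude of
    (numerically) zero, for which peak timing is undefined.
    """

    a0: float
    a1: float
    a2: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.a1, self.a2))

    @property
    def degenerate(self) -> bool:
        return self.amplitude < _DEGENERATE_TOL * max(1.0, abs(self.a0))

    @property
    def peak(self) -> float:
        # f(m) = a0 + A*sin(theta + phi), theta = 2*pi*m/12; maximum where
        # theta = pi/2 - phi, i.e. where (sin, cos)(theta) align with (a1, a2)
        theta = np.arctan2(self.a2, self.a1)
        return float((12 * (np.pi / 2 - theta) / (2 * np.pi)) % 12)

    @property
    def trough(self) -> float:
        return float((self.peak + 6.0) % 12)

    @property
    def fitted_max(self) -> float:
        return self.a0 + self.amplitude

    @property
    def fitted_min(self) -> float:
        return self.a0 - self.amplitude

    def predict(self, m) -> np.ndarray:
        theta = 2 * np.pi * np.asarray(m, dtype=float) / 12
        return self.a0 + self.a1 * np.sin(theta) + self.a2 * np.cos(theta)


def fit_sinusoid(counts) -> SinusoidFit:
    """Closed-form least-squares fit of the period-12 sinusoid to the 12
    monthly totals (evaluated at month midpoints)."""
    y = np.asarray(counts, dtype=float)
    if y.shape != (12,):
        raise ValueError("expected 12 monthly counts")
    theta = 2 * np.pi * _MIDPOINTS / 12
    X = np.column_stack([np.ones(12), np.sin(theta), np.cos(theta)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SinusoidFit(*map(float, coef))


def _calendar_label(month_fraction: float) -> str:
    month = int(month_fraction) % 12
    frac = month_fraction - int(month_fraction)
    part = "start" if frac < 1 / 3 else ("middle" if frac < 2 / 3 else "end")
    return f"{part} of {MONTH_NAMES[month]}"


def peak_trough(fit: SinusoidFit) -> dict:
    """Human-readable peak/trough timing and fitted extreme values.

    Raises on a degenerate (flat) fit, where phase is undefined.
    """
    if fit.degenerate:
        raise ValueError("fit is degenerate (zero amplitude); no peak/trough")
    return {
        "peak_month_fraction": fit.peak,
        "peak_label": _calendar_label(fit.peak),
        "fitted_max": fit.fitted_max,
        "trough_month_fraction": fit.trough,
        "trough_label": _calendar_label(fit.trough),
        "fitted_min": fit.fitted_min,
    }
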