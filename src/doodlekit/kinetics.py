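"""Two-phase kinetics of isothermal untemplated DNA synthesis.

Real-time SYBR fluorescence of an isothermal synthesis reaction shows two
linear stages: an initial slow accumulation, then — around 30 min into the
reaction — a transition to a phase with a 3-3.5x higher synthesis rate that
stays linear for roughly another 1.5 h before the rate decays and synthesis
stops about 3 h in. This module normalizes raw curves (baseline-subtract,
divide by the maximum) and quantifies that behaviour with a continuous
two-segment piecewise-linear fit (exhaustive breakpoint search refined by
golden-section) plus a moving-window slope rule for the stop time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "KineticsCurve",
    "TwoPhaseFit",
    "load_curve_tsv",
    "normalize_fluorescence",
    "fit_two_phase",
    "saturation_stop_time",
]


@dataclass
class KineticsCurve:
    time: np.ndarray  # minutes, strictly increasing
    sybr: np.ndarray  # fluorescence, arbitrary units
    rox: Optional[np.ndarray] = None  # reference dye, stored but unused by default

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sybr = np.asarray(self.sybr, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.sybr.shape:
            raise ValueError("time and sybr must be 1-D and the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.rox is not None:
            self.rox = np.asarray(self.rox, dtype=float)
            if self.rox.shape != self.time.shape:
                raise ValueError("rox must match time length")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class TwoPhaseFit:
    breakpoint_min: float
    slow_rate: float
    fast_rate: float
    rss: float
    intercept: float
    low_confidence: bool  # RSS improvement over a single line < 5%

    @property
    def rate_ratio(self) -> float:
        return self.fast_rate / self.slow_rate

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.intercept
            + self.slow_rate * t
            + (self.fast_rate - self.slow_rate) * np.clip(t - self.breakpoint_min, 0, None)
        )


def load_curve_tsv(path: str | Path) -> KineticsCurve:
    """Read a curve table with columns time_min, sybr[, rox]."""
    df = pd.read_csv(path, sep="\t")
    rox = df["rox"].to_numpy() if "rox" in df.columns else None
    return KineticsCurve(df["time_min"].to_numpy(), df["sybr"].to_numpy(), rox)


def normalize_fluorescence(curve: KineticsCurve, subtract_baseline: bool = True) -> KineticsCurve:
    """Scale SYBR to a maximum of 1, optionally after baseline subtraction.

    The baseline is the mean of the first three points. Idempotent: applying
    twice changes nothing beyond floating-point noise.
    """
    sybr = curve.sybr.astype(float)
    if subtract_baseline:
        sybr = sybr - sybr[: min(3, len(sybr))].mean()
    peak = sybr.max()
    if peak <= 0:
        raise ValueError("degenerate curve: non-positive maximum after baseline subtraction")
    return KineticsCurve(curve.time.copy(), sybr / peak, None if curve.rox is None else curve.rox.copy())


def _fit_at_breakpoint(t: np.ndarray, y: np.ndarray, b: float) -> tuple[float, np.ndarray]:
    """Least-squares continuous hinge fit y ~ c + a*t + d*max(t-b, 0)."""
    X = np.column_stack([np.ones_like(t), t, np.clip(t - b, 0, None)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def fit_two_phase(curve: KineticsCurve, window_min: tuple[float, float] = (0.0, 120.0)) -> TwoPhaseFit:
    """Continuous two-segment piecewise-linear fit inside ``window_min``.

    The breakpoint is located by exhaustive search over interior grid points
    (at least three points on each side), then refined by bounded
    minimization of the residual sum of squares over the continuous
    breakpoint between the neighbouring grid points. Deterministic.
    """
    sel = (curve.time >= window_min[0]) & (curve.time <= window_min[1])
    t, y = curve.time[sel], curve.sybr[sel]
    if len(t) < 6:
        raise ValueError("need at least 6 points inside the fit window")
    candidates = t[3:-2]  # >= 3 points on each side of the hinge
    rss_grid = np.array([_fit_at_breakpoint(t, y, b)[0] for b in candidates])
    i = int(np.argmin(rss_grid))
    lo = candidates[max(0, i - 1)]
    hi = candidates[min(len(candidates) - 1, i + 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda b: _fit_at_breakpoint(t, y, b)[0],
            bounds=(float(lo), float(hi)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        b_best = float(res.x)
        if _fit_at_breakpoint(t, y, b_best)[0] > rss_grid[i]:
            b_best = float(candidates[i])
    else:
        b_best = float(candidates[i])
    rss, coef = _fit_at_breakpoint(t, y, b_best)
    # single-line fit for the identifiability check
    X1 = np.column_stack([np.ones_like(t), t])
    c1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    r1 = y - X1 @ c1
    rss1 = float(r1 @ r1)
    # a single line already fitting to numerical precision means the hinge
    # adds nothing and the breakpoint is unidentifiable
    floor = 1e-12 * (float(y @ y) + 1.0)
    low_conf = rss1 <= floor or (rss1 - rss) / rss1 < 0.05
    return TwoPhaseFit(
        breakpoint_min=b_best,
        slow_rate=float(coef[1]),
        fast_rate=float(coef[1] + coef[2]),
        rss=rss,
        intercept=float(coef[0]),
        low_confidence=bool(low_conf),
    )


def _windowed_slopes(t: np.ndarray, y: np.ndarray, half_width: float) -> np.ndarray:
    """Centered moving-window least-squares slope at every sample."""
    slopes = np.empty_like(y)
    for i in range(len(t)):
        sel = np.abs(t - t[i]) <= half_width
        tt, yy = t[sel], y[sel]
        if len(tt) < 2:
            slopes[i] = 0.0
            continue
        tt = tt - tt.mean()
        denom = float(tt @ tt)
        slopes[i] = float(tt @ (yy - yy.mean())) / denom if denom > 0 else 0.0
    return slopes


def saturation_stop_time(
    curve: KineticsCurve,
    slope_tol: float = 0.05,
    window_min: float = 15.0,
    fit: TwoPhaseFit | None = None,
) -> Optional[float]:
    """Earliest time after which the local slope stays below ``slope_tol`` x fast rate.

    The local slope is a centered least-squares slope over a ``window_min``
    window. "Stays below" tolerates brief noise excursions: a candidate time
    qualifies when its own slope, and the mean slope of the whole remainder,
    are below threshold and no re-rise lasts 3 or more consecutive samples.
    Returns None when synthesis never stops within the record; a curve flat
    from the start returns its first time point.
    """
    if fit is None:
        fit = fit_two_phase(curve, (float(curve.time[0]), float(min(curve.time[-1], curve.time[0] + 120.0))))
    t, y = curve.time, curve.sybr
    slopes = _windowed_slopes(t, y, window_min / 2.0)
    threshold = slope_tol * abs(fit.fast_rate) + 1e-12
    below = slopes <= threshold

    def longest_false_run(arr: np.ndarray) -> int:
        worst = run = 0
        for ok in arr:
            run = 0 if ok else run + 1
            worst = max(worst, run)
        return worst

    for idx in np.nonzero(below)[0]:
        if t[-1] > t[idx]:
            mean_tail = (y[-1] - y[idx]) / (t[-1] - t[idx])
            if mean_tail > threshold:
                continue
        if longest_false_run(below[idx:]) < 3:
            return float(t[idx])
    return None
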