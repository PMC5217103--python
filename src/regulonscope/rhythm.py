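"""Rhythmicity analysis of reporter time series by sine-vs-line model selection.

A trace is preprocessed (first-day exclusion, moving-average detrending),
fitted with both a straight line (slope, intercept) and a sinusoid (period,
phase, amplitude, offset), and the two fits are compared with the
small-sample-corrected Akaike criterion (AICc).  The Akaike weight of the
sine model is read as the probability that a sine fits better than a line;
a trace is called rhythmic when the weight reaches a threshold (default
0.95).  The residual variance counts as a model parameter, so the line has
k = 3 and the sine k = 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import TimeSeries

__all__ = [
    "LineFit",
    "SineFit",
    "RhythmCall",
    "preprocess",
    "fit_line",
    "fit_sine",
    "rhythm_test",
    "summarize_replicates",
]


@dataclass
class LineFit:
    slope: float
    intercept: float
    rss: float
    n: int
    k_params: int = 3


@dataclass
class SineFit:
    period: float      # h
    phase: float       # h, time of first model peak in [0, period)
    amplitude: float   # >= 0
    offset: float
    rss: float
    n: int
    k_params: int = 5
    converged: bool = True

    def predict(self, t: np.ndarray) -> np.ndarray:
        omega = 2 * np.pi / self.period
        # peak at t = phase  =>  argument pi/2 there
        return self.offset + self.amplitude * np.sin(omega * (t - self.phase) + np.pi / 2)


@dataclass
class RhythmCall:
    p_sine_better: float
    rhythmic: bool
    line: LineFit
    sine: SineFit
    threshold: float = 0.95


def preprocess(ts: TimeSeries, drop_before_h: float = 24.0,
               detrend_window_h: float = 24.0, min_samples: int = 12) -> TimeSeries:
    """Drop the first day and subtract a centered moving average.

    Samples with t < ``drop_before_h`` are removed (transfer artifacts), then
    a centered moving average with a time window of ``detrend_window_h`` is
    subtracted, removing baseline drift and slow amplitude decay; the output
    is approximately mean-zero.  Near the edges the window shrinks
    symmetrically so it stays centered, which removes a linear trend exactly
    at every sample (at the cost of less smoothing at the very ends).
    """
    keep = ts.t >= drop_before_h
    t, y = ts.t[keep], ts.y[keep]
    if len(t) < min_samples:
        raise ValueError(
            f"only {len(t)} samples after dropping t < {drop_before_h} h (need >= {min_samples})"
        )
    half = detrend_window_h / 2
    trend = np.empty_like(y)
    for i, ti in enumerate(t):
        h = min(half, ti - t[0], t[-1] - ti)
        w = (t >= ti - h - 1e-9) & (t <= ti + h + 1e-9)
        trend[i] = y[w].mean()
    return TimeSeries(t=t, y=y - trend, replicate_id=ts.replicate_id)


def fit_line(ts: TimeSeries) -> LineFit:
    """Ordinary least squares y = a*t + b."""
    if len(ts) < 4:
        raise ValueError("need at least 4 samples for a line fit")
    if np.ptp(ts.t) == 0:
        raise ValueError("degenerate time axis: all time points equal")
    A = np.column_stack([ts.t, np.ones(len(ts))])
    coef, *_ = np.linalg.lstsq(A, ts.y, rcond=None)
    resid = ts.y - A @ coef
    return LineFit(slope=float(coef[0]), intercept=float(coef[1]),
                   rss=float(resid @ resid), n=len(ts))


def _harmonic_ls(t: np.ndarray, y: np.ndarray, period: float,
                 ) -> tuple[float, np.ndarray]:
    """Exact least squares of y = c + a sin(wt) + b cos(wt) for fixed period."""
    omega = 2 * np.pi / period
    A = np.column_stack([np.ones_like(t), np.sin(omega * t), np.cos(omega * t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef


def fit_sine(ts: TimeSeries, period_bounds: tuple[float, float] = (16.0, 32.0),
             ) -> SineFit:
    """Least-squares sinusoid fit with a period grid plus 1-D refinement.

    For fixed period the model is linear in (amplitude, phase, offset), so
    each trial period on a 1 h grid over ``period_bounds`` is solved exactly
    by harmonic regression; the best grid period seeds a bounded continuous
    minimization of the profiled RSS.  The reported phase is the time of the
    first model peak, normalized to [0, period); the amplitude is
    non-negative (sign absorbed into the phase).
    """
    lo, hi = period_bounds
    if not 0 < lo < hi:
        raise ValueError("period bounds must satisfy 0 < lower < upper")
    if len(ts) < 8:
        raise ValueError("need at least 8 samples for a sine fit")
    if np.ptp(ts.t) < 1.5 * lo:
        raise ValueError("time span shorter than 1.5x the lower period bound")
    t, y = ts.t, ts.y
    grid = np.arange(lo, hi + 1e-9, 1.0)
    rss_grid = [_harmonic_ls(t, y, T)[0] for T in grid]
    T0 = float(grid[int(np.argmin(rss_grid))])
    blo, bhi = max(lo, T0 - 1.0), min(hi, T0 + 1.0)
    converged = True
    try:
        res = minimize_scalar(lambda T: _harmonic_ls(t, y, T)[0],
                              bounds=(blo, bhi), method="bounded",
                              options={"xatol": 1e-8})
        T = float(res.x) if res.success else T0
        converged = bool(res.success)
    except Exception:
        T, converged = T0, False
    rss, coef = _harmonic_ls(t, y, T)
    c, a, b = float(coef[0]), float(coef[1]), float(coef[2])
    amplitude = math.hypot(a, b)
    # y = c + A sin(wt + psi), psi = atan2(b, a); peak where wt + psi = pi/2
    psi = math.atan2(b, a)
    omega = 2 * np.pi / T
    phase = ((np.pi / 2 - psi) / omega) % T
    return SineFit(period=T, phase=float(phase), amplitude=amplitude, offset=c,
                   rss=rss, n=len(ts), converged=converged)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)  # a perfect fit gives -inf; keep the comparison finite
    if n - k - 1 <= 0:
        raise ValueError(f"too few samples (n={n}) for AICc with k={k}")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def rhythm_test(ts: TimeSeries, threshold: float = 0.95,
                period_bounds: tuple[float, float] = (16.0, 32.0)) -> RhythmCall:
    """Two-model Akaike-weight comparison of sine vs line fits.

    p_sine_better = exp(-dAICc_sine/2) / (exp(-dAICc_sine/2) + exp(-dAICc_line/2))
    with differences taken from the smaller AICc.  Rhythmic when the weight
    reaches ``threshold`` and the sine fit converged.
    """
    line = fit_line(ts)
    sine = fit_sine(ts, period_bounds)
    a_line = _aicc(line.rss, line.n, line.k_params)
    a_sine = _aicc(sine.rss, sine.n, sine.k_params)
    best = min(a_line, a_sine)
    w_sine = math.exp(-(a_sine - best) / 2)
    w_line = math.exp(-(a_line - best) / 2)
    p = w_sine / (w_sine + w_line)
    return RhythmCall(p_sine_better=p,
                      rhythmic=bool(p >= threshold and sine.converged),
                      line=line, sine=sine, threshold=threshold)


def summarize_replicates(calls: list[RhythmCall]) -> dict:
    """Replicate-level period mean +/- sd and circular mean phase.

    Only rhythmic replicates contribute.  The phase is averaged circularly
    modulo the mean period (phases near 0 and near the period average to ~0,
    not to half a period).
    """
    rhythmic = [c for c in calls if c.rhythmic]
    if not rhythmic:
        raise ValueError("no rhythmic replicates to summarize")
    periods = np.array([c.sine.period for c in rhythmic])
    mean_period = float(periods.mean())
    single = len(periods) == 1
    sd_period = 0.0 if single else float(periods.std(ddof=1))
    angles = 2 * np.pi * np.array([c.sine.phase for c in rhythmic]) / mean_period
    mean_angle = math.atan2(float(np.sin(angles).mean()), float(np.cos(angles).mean()))
    mean_phase = (mean_angle / (2 * np.pi) * mean_period) % mean_period
    return {
        "n_rhythmic": len(rhythmic),
        "n_total": len(calls),
        "mean_period": mean_period,
        "sd_period": sd_period,
        "single_replicate": single,
        "mean_phase": mean_phase,
    }
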