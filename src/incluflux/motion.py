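"""Mean squared displacement and anomalous-diffusion analysis.

For a 2D random walk the MSD grows linearly with lag time,
MSD(Δt) = 4·D·Δt; in general MSD ∝ Δt^α with α = 1 for free diffusion,
α > 1 for superdiffusion (a signature of active transport) and α = 2 in
the ballistic limit.  This module computes per-track MSD curves over frame
lags 1–16 using all overlapping intervals, fits α as the slope of
log₁₀ MSD vs log₁₀ Δt by ordinary least squares, estimates D from a
zero-intercept linear fit of MSD against Δt, classifies the motion, and
compares particle populations with Welch's t test.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .types import MotionClass, MotionEstimate, MSDCurve, Track

__all__ = [
    "compute_msd",
    "fit_alpha",
    "estimate_D",
    "classify_motion",
    "compare_groups",
    "welch_t_from_summary",
    "analyze_track",
]

DEFAULT_MAX_LAG = 16


def compute_msd(track: Track, max_lag: int = DEFAULT_MAX_LAG) -> MSDCurve:
    """Per-track MSD at frame lags 1..max_lag using all overlapping windows.

    For lag k the MSD is the mean over every start frame i of the squared
    2D displacement |r(i+k) − r(i)|²; Δt per lag is the mean of the
    corresponding timestamp differences.  Tracks shorter than
    ``max_lag + 1`` points truncate the lag range with a warning.
    """
    n = len(track)
    if n < 2:
        raise ValueError("track must have at least 2 points")
    if n < max_lag + 1:
        warnings.warn(
            f"track of {n} points supports lags up to {n - 1}; truncating max_lag",
            stacklevel=2,
        )
        max_lag = n - 1
    pos = track.positions_um
    t = track.t_s
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    dts = np.empty(len(lags))
    n_int = np.empty(len(lags), dtype=int)
    for i, k in enumerate(lags):
        d = pos[k:] - pos[:-k]
        msd[i] = np.mean(np.sum(d * d, axis=1))
        dts[i] = np.mean(t[k:] - t[:-k])
        n_int[i] = n - k
    return MSDCurve(lag_frames=lags, dt_s=dts, msd_um2=msd, n_intervals=n_int)


def fit_alpha(msd: MSDCurve) -> MotionEstimate:
    """Fit the anomalous-diffusion exponent α.

    Ordinary least squares of log₁₀ MSD on log₁₀ Δt; α is the slope and the
    fit r² is reported.  Lags with zero MSD are excluded with a warning;
    fewer than 3 positive lags is not estimable.
    """
    keep = msd.msd_um2 > 0
    if keep.sum() < len(msd.msd_um2):
        warnings.warn("excluding zero-MSD lags from log-log fit", stacklevel=2)
    if keep.sum() < 3:
        raise ValueError("need >= 3 lags with positive MSD to fit alpha")
    x = np.log10(msd.dt_s[keep])
    y = np.log10(msd.msd_um2[keep])
    res = stats.linregress(x, y)
    return MotionEstimate(
        alpha=float(res.slope),
        D_um2_s=estimate_D(msd),
        r_squared=float(res.rvalue**2),
        n_lags_used=int(keep.sum()),
    )


def estimate_D(msd: MSDCurve) -> float:
    """Diffusion coefficient from MSD(Δt) = 4·D·Δt.

    D is the slope of the zero-intercept least-squares fit of MSD against
    Δt over the curve's lags, divided by 4.  An all-zero MSD gives D = 0.
    """
    if len(msd.msd_um2) < 1:
        raise ValueError("need at least one lag")
    if np.all(msd.msd_um2 == 0):
        return 0.0
    dt = msd.dt_s
    slope = float(np.dot(msd.msd_um2, dt) / np.dot(dt, dt))
    return slope / 4.0


def classify_motion(est: MotionEstimate, boundary: float = 1.0,
                    dead_band: float = 0.05) -> MotionClass:
    """Label motion by comparing α to ``boundary`` with a dead-band.

    α within ``boundary ± dead_band`` is diffusive; above is
    superdiffusive; below is subdiffusive.
    """
    if not np.isfinite(est.alpha):
        raise ValueError("alpha must be finite")
    if est.alpha > boundary + dead_band:
        return MotionClass.SUPERDIFFUSIVE
    if est.alpha < boundary - dead_band:
        return MotionClass.SUBDIFFUSIVE
    return MotionClass.DIFFUSIVE


def compare_groups(alphas_a: Sequence[float], alphas_b: Sequence[float]):
    """Welch's unpaired two-tailed t test between two exponent samples.

    Returns ``(t, p, df, summary)`` where ``summary`` holds each group's
    mean ± SEM.  Two groups with zero variance and equal means give
    t = 0, p = 1.
    """
    a = np.asarray(alphas_a, dtype=float)
    b = np.asarray(alphas_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    summary = {
        "mean_a": a.mean(), "sem_a": a.std(ddof=1) / np.sqrt(len(a)),
        "mean_b": b.mean(), "sem_b": b.std(ddof=1) / np.sqrt(len(b)),
    }
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float(len(a) + len(b) - 2), summary
        return np.inf, 0.0, float(len(a) + len(b) - 2), summary
    res = stats.ttest_ind(a, b, equal_var=False)
    se_a2 = a.var(ddof=1) / len(a)
    se_b2 = b.var(ddof=1) / len(b)
    df = (se_a2 + se_b2) ** 2 / (
        se_a2**2 / (len(a) - 1) + se_b2**2 / (len(b) - 1)
    )
    return float(res.statistic), float(res.pvalue), float(df), summary


def welch_t_from_summary(mean_a: float, sem_a: float, n_a: int,
                         mean_b: float, sem_b: float, n_b: int):
    """Welch's t and Satterthwaite df from group summary statistics."""
    se2 = sem_a**2 + sem_b**2
    t = (mean_a - mean_b) / np.sqrt(se2)
    df = se2**2 / (sem_a**4 / (n_a - 1) + sem_b**4 / (n_b - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def analyze_track(track: Track, max_lag: int = DEFAULT_MAX_LAG):
    """Convenience: MSD, motion estimate and class for one track."""
    msd = compute_msd(track, max_lag=max_lag)
    est = fit_alpha(msd)
    return msd, est, classify_motion(est)
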