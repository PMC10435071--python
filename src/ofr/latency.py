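"""Onset-latency estimation from trial-averaged eye speed profiles.

The primary estimator fits a two-part piecewise linear model to the mean
speed trace in a 30-150 ms window after motion onset:

    y(t) = a*c + b   for t < c
    y(t) = a*t + b   for t >= c

so the trace is flat until the onset latency c and then ramps at slope a.
The least-squares solution is found by an exhaustive scan of c over the
2-ms sample grid (closed-form solve for a, b at each candidate) followed by
continuous refinement of c between the best grid point's neighbours; the
procedure is deterministic, and ties are broken toward the smallest c.

Two alternative estimators are included: a sustained acceleration-threshold
crossing, and the first deviation of speed above baseline mean + k*SD. The
deviation method is provided for completeness; it is noise-sensitive and not
recommended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .kinematics import MeanSpeedProfile, sg_differentiate

#: default fit window, ms after motion onset
FIT_WINDOW = (30.0, 150.0)


@dataclass
class PiecewiseFit:
    """Piecewise-linear latency fit: slope a (deg/s per ms), intercept b
    (deg/s), onset latency c (ms), residual sum of squares, and diagnostics.

    ``c_grid`` is the best changepoint restricted to the sample grid (the
    continuous refinement is reported in ``c``). ``identifiable`` is False
    for degenerate (flat) profiles, in which case a = 0 and c is NaN.
    """

    a: float
    b: float
    c: float
    rss: float
    fit_window: tuple[float, float]
    n_points: int
    c_grid: float | None = None
    identifiable: bool = True


def _piecewise_rss(t: np.ndarray, y: np.ndarray, c: float) -> tuple[float, float, float]:
    """Closed-form least squares of (a, b) at fixed changepoint c.

    The model is linear in (a, b) given c via the regressor u = max(t, c).
    Returns (a, b, rss).
    """
    u = np.maximum(t, c)
    n = len(t)
    su, suu = u.sum(), (u * u).sum()
    sy, suy = y.sum(), (u * y).sum()
    denom = n * suu - su * su
    if denom <= 1e-12 * max(suu, 1.0):
        a = 0.0
        b = sy / n
    else:
        a = (n * suy - su * sy) / denom
        b = (sy - a * su) / n
    resid = y - (a * u + b)
    return a, b, float(resid @ resid)


def fit_piecewise_latency(
    profile: MeanSpeedProfile,
    fit_window: tuple[float, float] = FIT_WINDOW,
    refine: bool = True,
) -> PiecewiseFit:
    """Global least-squares piecewise-linear (flat-then-ramp) fit.

    Scans every sample time in ``fit_window`` as a candidate changepoint with
    a closed-form 2-parameter solve, then refines c continuously between the
    best grid candidate's neighbours. Among equal-RSS candidates the smallest
    c is kept (earliest-onset convention).
    """
    lo, hi = fit_window
    mask = (profile.t_aligned >= lo) & (profile.t_aligned <= hi)
    t = profile.t_aligned[mask]
    y = profile.mean[mask]
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    n = len(t)
    if n < 4:
        raise ValueError(f"need >= 4 valid timepoints in {fit_window}, got {n}")

    if np.ptp(y) < 1e-12:
        return PiecewiseFit(
            a=0.0, b=float(y.mean()), c=np.nan, rss=0.0,
            fit_window=(lo, hi), n_points=n, c_grid=None, identifiable=False,
        )

    # vectorized scan: candidates are the sample times (excluding the last,
    # where u = max(t, c) degenerates to a constant regressor)
    cand = t[:-1]
    U = np.maximum(t[None, :], cand[:, None])
    su = U.sum(axis=1)
    suu = (U * U).sum(axis=1)
    sy = y.sum()
    suy = U @ y
    syy = float(y @ y)
    denom = n * suu - su * su
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (n * suy - su * sy) / denom
        b = (sy - a * su) / n
        rss = syy + a * a * suu + n * b * b - 2 * a * suy - 2 * b * sy + 2 * a * b * su
    bad = denom <= 1e-12 * np.maximum(suu, 1.0)
    rss[bad] = np.inf
    i_best = int(np.argmin(rss))  # argmin keeps the first (smallest-c) tie

    c_grid = float(cand[i_best])
    a_best, b_best, rss_best = _piecewise_rss(t, y, c_grid)
    c_best = c_grid

    if refine:
        c_lo = float(cand[max(i_best - 1, 0)])
        c_hi = float(cand[min(i_best + 1, len(cand) - 1)])
        if c_hi > c_lo:
            res = optimize.minimize_scalar(
                lambda c: _piecewise_rss(t, y, c)[2],
                bounds=(c_lo, c_hi), method="bounded",
                options={"xatol": 1e-6},
            )
            if res.fun <= rss_best + 1e-12:
                c_best = float(res.x)
                a_best, b_best, rss_best = _piecewise_rss(t, y, c_best)

    return PiecewiseFit(
        a=float(a_best), b=float(b_best), c=c_best, rss=rss_best,
        fit_window=(lo, hi), n_points=n, c_grid=c_grid, identifiable=True,
    )


def acceleration_threshold_latency(
    profile: MeanSpeedProfile,
    threshold: float = 40.0,
    min_consecutive: int = 3,
    search_from: float = 0.0,
) -> float | None:
    """First sustained crossing of an eye-acceleration threshold.

    The mean speed trace is differentiated with the same Savitzky-Golay
    filter used for velocity, giving acceleration in deg/s^2. Returns the
    first aligned time >= ``search_from`` at which acceleration meets or
    exceeds ``threshold`` for at least ``min_consecutive`` samples, or None
    if it never does.
    """
    accel = sg_differentiate(profile.mean)  # deg/s per s = deg/s^2
    t = profile.t_aligned
    above = np.isfinite(accel) & (accel >= threshold) & (t >= search_from)
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            return float(t[i - min_consecutive + 1])
    return None


def deviation_latency(
    profile: MeanSpeedProfile,
    k_sd: float = 1.5,
    baseline_window: tuple[float, float] = (-50.0, 30.0),
) -> float | None:
    """First time mean speed exceeds baseline mean + k_sd * baseline SD.

    The baseline statistics are taken over ``baseline_window`` (half-open,
    pre-response). Returns None if the trace never exceeds the level. This
    estimator is noise-sensitive and included only for comparison.
    """
    t = profile.t_aligned
    lo, hi = baseline_window
    base = profile.mean[(t >= lo) & (t < hi)]
    base = base[np.isfinite(base)]
    if len(base) < 2:
        raise ValueError("baseline window not covered")
    sd = float(np.std(base, ddof=1))
    if sd == 0.0:
        raise ValueError("zero baseline SD: deviation latency undefined")
    level = float(np.mean(base)) + k_sd * sd
    after = (t >= hi) & np.isfinite(profile.mean)
    idx = np.nonzero(after & (profile.mean > level))[0]
    return float(t[idx[0]]) if len(idx) else None
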