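"""Resampling inference for ocular-following analyses.

Randomization (permutation) tests for regression slopes across condition
levels and for latency differences between two groups, bootstrap standard
errors of the mean, the pooled-variance two-sample t test, and the
direction-pooling transform for the congruence experiment.

Permutation p values use (1 + b) / (1 + B), which is strictly positive and
valid under exchangeability; tests are two-sided by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .kinematics import MeanSpeedProfile, VelocityTrace, component_matrix, default_grid
from .latency import FIT_WINDOW, fit_piecewise_latency


@dataclass
class RandomizationResult:
    """A permutation test outcome: the empirical statistic, the permutation
    null distribution, and the (1+b)/(1+B) two-sided p value. ``n_failed``
    counts shuffles whose statistic could not be computed (e.g. an
    unfittable pseudocondition trace); those are excluded from the null."""

    statistic_name: str
    empirical_value: float
    null_values: np.ndarray
    p_value: float
    n_shuffles: int
    seed: int
    n_failed: int = 0


def _perm_p(empirical: float, null: np.ndarray) -> float:
    return float((1 + np.sum(np.abs(null) >= abs(empirical))) / (1 + len(null)))


def _mean_profiles_by_label(
    V: np.ndarray, labels: np.ndarray, levels: np.ndarray, grid: np.ndarray
) -> list[MeanSpeedProfile]:
    out = []
    for lev in levels:
        rows = V[labels == lev]
        mean = np.nanmean(rows, axis=0)
        out.append(
            MeanSpeedProfile(key=lev, t_aligned=grid, mean=mean,
                             se=np.zeros_like(mean), n_trials=rows.shape[0])
        )
    return out


def _latency_per_level(
    profiles: Sequence[MeanSpeedProfile], fit_window: tuple[float, float]
) -> np.ndarray:
    cs = []
    for prof in profiles:
        fit = fit_piecewise_latency(prof, fit_window=fit_window)
        if not fit.identifiable:
            raise ValueError("unidentifiable latency for a pseudocondition")
        cs.append(fit.c)
    return np.array(cs)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def randomization_slope_test(
    trials: Sequence[VelocityTrace],
    condition_variable: str,
    response: str = "latency",
    n_shuffles: int = 1000,
    seed: int = 0,
    component: str = "along",
    fit_window: tuple[float, float] = FIT_WINDOW,
    window_start: float | None = None,
    window_len: float = 50.0,
    grid: np.ndarray | None = None,
) -> RandomizationResult:
    """Permutation test for the slope of a response against a condition value.

    The empirical statistic is the OLS slope of the per-condition response
    (onset latency fitted on each condition-mean trace, or mean speed in a
    fixed window) regressed on the condition value, one point per level. The
    null is built by permuting whole-trial condition labels; p is two-sided.
    """
    if response not in ("latency", "window_speed"):
        raise ValueError(f"unknown response {response!r}")
    labels = np.array([tr.meta[condition_variable] for tr in trials], dtype=float)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("need at least 2 condition levels")
    counts = np.array([(labels == lev).sum() for lev in levels])
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per condition level")
    if grid is None:
        grid = default_grid()

    if response == "window_speed":
        if window_start is None:
            raise ValueError("window_speed response requires window_start")
        # per-condition mean of per-trial window speeds; averaging commutes,
        # so shuffles only permute scalars
        _, V = component_matrix(trials, component, grid)
        wmask = (grid >= window_start) & (grid < window_start + window_len)
        per_trial = np.nanmean(V[:, wmask], axis=1)

        def statistic(lab: np.ndarray) -> float:
            means = np.array([per_trial[lab == lev].mean() for lev in levels])
            return _ols_slope(levels, means)

    else:
        _, V = component_matrix(trials, component, grid)

        def statistic(lab: np.ndarray) -> float:
            profiles = _mean_profiles_by_label(V, lab, levels, grid)
            return _ols_slope(levels, _latency_per_level(profiles, fit_window))

    empirical = statistic(labels)
    rng = np.random.default_rng(seed)
    null, n_failed = [], 0
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        try:
            null.append(statistic(perm))
        except (ValueError, RuntimeError):
            n_failed += 1
    null = np.array(null)
    return RandomizationResult(
        statistic_name=f"{response}_slope_vs_{condition_variable}",
        empirical_value=empirical,
        null_values=null,
        p_value=_perm_p(empirical, null),
        n_shuffles=n_shuffles,
        seed=seed,
        n_failed=n_failed,
    )


def randomization_latency_difference_test(
    trials: Sequence[VelocityTrace],
    in_group_a: Sequence[bool],
    n_shuffles: int = 1000,
    seed: int = 0,
    component: str = "along",
    fit_window: tuple[float, float] = FIT_WINDOW,
    grid: np.ndarray | None = None,
) -> RandomizationResult:
    """Permutation test for the latency difference between two trial groups.

    The statistic is c_a - c_b from piecewise fits on the two group-mean
    traces; the null is built by permuting group membership across trials.
    """
    in_a = np.asarray(in_group_a, dtype=bool)
    if len(in_a) != len(trials):
        raise ValueError("in_group_a must label every trial")
    if in_a.all() or not in_a.any():
        raise ValueError("both groups must be non-empty")
    if grid is None:
        grid = default_grid()
    _, V = component_matrix(trials, component, grid)

    def statistic(mask: np.ndarray) -> float:
        profs = _mean_profiles_by_label(
            V, mask.astype(float), np.array([1.0, 0.0]), grid
        )
        c_a, c_b = _latency_per_level(profs, fit_window)
        return c_a - c_b

    empirical = statistic(in_a)
    rng = np.random.default_rng(seed)
    null, n_failed = [], 0
    for _ in range(n_shuffles):
        perm = rng.permutation(in_a)
        try:
            null.append(statistic(perm))
        except (ValueError, RuntimeError):
            n_failed += 1
    null = np.array(null)
    return RandomizationResult(
        statistic_name="latency_difference",
        empirical_value=empirical,
        null_values=null,
        p_value=_perm_p(empirical, null),
        n_shuffles=n_shuffles,
        seed=seed,
        n_failed=n_failed,
    )


def bootstrap_sd_of_mean(
    values: Sequence[float], n_boot: int = 1000, seed: int = 0
) -> float:
    """SD of the bootstrap distribution of the sample mean (n_boot resamples)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    return float(np.std(means, ddof=1))


def two_sample_t(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Student's pooled-variance two-sample t test (two-sided).

    df = n_a + n_b - 2. Raises on zero pooled variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return {"t": float(t), "df": df, "p": float(2 * sps.t.sf(abs(t), df))}


def invert_for_pooling(trace: VelocityTrace) -> VelocityTrace:
    """Sign-invert velocity components for stimulus directions 180/270 deg.

    Maps every trial onto a common "positive = stimulus direction" axis
    convention: horizontal-axis trials with leftward (180 deg) stimuli get
    vx negated, vertical-axis trials with downward (270 deg) stimuli get vy
    negated. Applying the inversion twice restores the input.
    """
    stim = float(trace.meta.get("stim_dir_deg")) % 360.0
    if stim not in (0.0, 90.0, 180.0, 270.0):
        raise ValueError(f"unknown stimulus direction code {stim!r}")
    vx, vy = trace.vx, trace.vy
    if stim == 180.0:
        vx = -vx
    elif stim == 270.0:
        vy = -vy
    return replace(trace, vx=vx, vy=vy)


def pool_directions(trials: Sequence[VelocityTrace]) -> dict:
    """Pool congruence-experiment trials into axis x identical/opposite groups.

    After sign inversion (see :func:`invert_for_pooling`), horizontal-axis
    (stimulus 0/180 deg) and vertical-axis (90/270 deg) trials are pooled
    into identical vs opposite saccade/stimulus-direction groups. Returns
    ``{"horizontal": {"identical": [...], "opposite": [...]},
    "vertical": {...}}``.
    """
    pooled: dict = {
        "horizontal": {"identical": [], "opposite": []},
        "vertical": {"identical": [], "opposite": []},
    }
    for tr in trials:
        stim = float(tr.meta.get("stim_dir_deg")) % 360.0
        sacc = float(tr.meta.get("saccade_dir_deg")) % 360.0
        if stim not in (0.0, 90.0, 180.0, 270.0) or sacc not in (0.0, 90.0, 180.0, 270.0):
            raise ValueError(f"unknown direction codes (stim={stim}, sacc={sacc})")
        axis = "horizontal" if stim in (0.0, 180.0) else "vertical"
        sacc_axis = "horizontal" if sacc in (0.0, 180.0) else "vertical"
        if axis != sacc_axis:
            raise ValueError(
                f"trial {tr.trial_id}: saccade and stimulus on different axes"
            )
        relative = "identical" if stim == sacc else "opposite"
        pooled[axis][relative].append(invert_for_pooling(tr))
    return pooled
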