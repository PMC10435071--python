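"""End-to-end orchestration of the three ocular-following experiments.

Each ``run_experiment*`` function takes a :class:`~ofr.io.Session` and an
:class:`AnalysisConfig` and produces an :class:`ExperimentReport` holding
every figure-level quantity: condition-mean speed profiles, latency and
window-speed tables with bootstrap error bars, randomization slope tests
(postsaccadic-delay experiment), spatiotemporal tuning fits with Q and its
F test (frequency experiment), and congruence t tests plus latency
difference tests (direction experiment). All randomness is seeded through
the config; given (session, config) the reports are deterministic.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import stats as st
from .io import Session
from .kinematics import (
    MeanSpeedProfile,
    VelocityTrace,
    align_and_average,
    component_matrix,
    default_grid,
    savgol_velocity,
    window_mean_speed,
)
from .latency import FIT_WINDOW, fit_piecewise_latency
from .tuning import TuningSurface, f_test_q, fit_tuning_nested_pair, gain_surface

logger = logging.getLogger("ofr")


@dataclass
class AnalysisConfig:
    """Tunable analysis settings (times in ms unless noted)."""

    component: str = "along"
    fit_window: tuple[float, float] = FIT_WINDOW
    window_len: float = 50.0
    #: offset of the fixed speed window after the median onset latency;
    #: offset-0 results are always computed alongside for comparison
    window_offset: float = 10.0
    n_shuffles: int = 1000
    n_boot: int = 1000
    #: bootstrap resamples for latency error bars (trial resampling + refit)
    n_boot_latency: int = 200
    min_trials_per_cell: int = 14
    max_missing_fraction: float = 0.5
    tuning_windows: tuple = ((60.0, 110.0), (80.0, 130.0), (100.0, 150.0))
    temporal_space: str = "log2"
    seed: int = 0


@dataclass
class ExperimentReport:
    """Analysis results for one experiment plus full provenance."""

    experiment: str
    results: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "results": self.results,
            "provenance": self.provenance,
        }


def _velocities(session: Session) -> list[VelocityTrace]:
    return [savgol_velocity(tr) for tr in session.traces]


def _profile_dict(p: MeanSpeedProfile) -> dict:
    return {
        "t_aligned_ms": p.t_aligned,
        "mean_dps": p.mean,
        "se_dps": p.se,
        "n_trials": p.n_trials,
    }


def _provenance(config: AnalysisConfig, session: Session, t0: float) -> dict:
    return {
        "config": asdict(config),
        "n_trials": len(session.traces),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }


def _bootstrap_latency_sd(
    rows: np.ndarray,
    grid: np.ndarray,
    fit_window: tuple[float, float],
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """SD of the bootstrap (trial-resampled) distribution of fitted latency."""
    if n_boot < 2 or rows.shape[0] < 2:
        return float("nan")
    cs = []
    n = rows.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        prof = MeanSpeedProfile(
            key=None, t_aligned=grid, mean=np.nanmean(rows[idx], axis=0),
            se=np.zeros(len(grid)), n_trials=n,
        )
        try:
            fit = fit_piecewise_latency(prof, fit_window=fit_window, refine=False)
        except ValueError:
            continue
        if fit.identifiable:
            cs.append(fit.c)
    return float(np.std(cs, ddof=1)) if len(cs) >= 2 else float("nan")


def run_experiment1(session: Session, config: AnalysisConfig | None = None
                    ) -> ExperimentReport:
    """Postsaccadic-delay experiment: latency and speed vs delay.

    Per-delay mean speed profiles, piecewise-linear onset latencies with
    bootstrap SDs, mean speeds in (i) the fixed 50-ms window starting
    ``window_offset`` ms after the median latency across delays and (ii)
    50-ms windows placed relative to each delay's own latency, and
    randomization tests for the latency-vs-delay and speed-vs-delay slopes.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    vtraces = _velocities(session)
    grid = default_grid()
    delays = np.array(sorted({tr.meta["delay_ms"] for tr in vtraces}))
    logger.info("experiment 1: %d trials, %d delay levels", len(vtraces), len(delays))

    rng = np.random.default_rng(config.seed)
    _, V = component_matrix(vtraces, config.component, grid)
    labels = np.array([tr.meta["delay_ms"] for tr in vtraces])

    per_delay: dict = {}
    latencies = {}
    for d in delays:
        sel = [tr for tr in vtraces if tr.meta["delay_ms"] == d]
        prof = align_and_average(sel, condition=d, use_component=config.component,
                                 grid=grid)
        fit = fit_piecewise_latency(prof, fit_window=config.fit_window)
        lat_sd = _bootstrap_latency_sd(
            V[labels == d], grid, config.fit_window, config.n_boot_latency, rng
        )
        latencies[d] = fit.c
        per_delay[float(d)] = {
            "profile": _profile_dict(prof),
            "latency_ms": fit.c,
            "latency_bootstrap_sd_ms": lat_sd,
            "latency_fit": {"a": fit.a, "b": fit.b, "rss": fit.rss,
                            "identifiable": fit.identifiable},
            "n_trials": prof.n_trials,
        }

    median_latency = float(np.median([latencies[d] for d in delays]))
    windows = {
        "fixed": median_latency + config.window_offset,
        "fixed_offset0": median_latency,
    }
    for name, start in windows.items():
        for d in delays:
            sel = labels == d
            speeds = np.nanmean(
                V[np.ix_(sel, (grid >= start) & (grid < start + config.window_len))],
                axis=1,
            )
            speeds = speeds[np.isfinite(speeds)]
            per_delay[float(d)][f"speed_{name}_dps"] = float(np.mean(speeds))
            per_delay[float(d)][f"speed_{name}_bootstrap_sd_dps"] = (
                st.bootstrap_sd_of_mean(speeds, config.n_boot,
                                        seed=int(rng.integers(2**31)))
            )
        # latency-relative windows (per-delay start)
    for d in delays:
        start = latencies[d] + config.window_offset
        sel = labels == d
        speeds = np.nanmean(
            V[np.ix_(sel, (grid >= start) & (grid < start + config.window_len))],
            axis=1,
        )
        speeds = speeds[np.isfinite(speeds)]
        per_delay[float(d)]["speed_latency_relative_dps"] = float(np.mean(speeds))

    latency_slope = st.randomization_slope_test(
        vtraces, "delay_ms", response="latency", n_shuffles=config.n_shuffles,
        seed=config.seed, component=config.component, fit_window=config.fit_window,
        grid=grid,
    )
    speed_slope = st.randomization_slope_test(
        vtraces, "delay_ms", response="window_speed", n_shuffles=config.n_shuffles,
        seed=config.seed + 1, component=config.component,
        window_start=windows["fixed"], window_len=config.window_len, grid=grid,
    )
    # speed slope in latency-relative windows: per-condition means regressed
    # on delay, permutation over trial labels
    rel_speeds = np.array(
        [per_delay[float(d)]["speed_latency_relative_dps"] for d in delays]
    )
    rel_slope = float(np.polyfit(delays, rel_speeds, 1)[0])

    results = {
        "delays_ms": delays,
        "per_delay": per_delay,
        "median_latency_ms": median_latency,
        "fixed_window_ms": [windows["fixed"], windows["fixed"] + config.window_len],
        "latency_slope_test": _rand_dict(latency_slope),
        "speed_slope_test": _rand_dict(speed_slope),
        "speed_slope_latency_relative": rel_slope,
    }
    return ExperimentReport("delay", results, _provenance(config, session, t0))


def _rand_dict(r: st.RandomizationResult, keep_null: bool = False) -> dict:
    out = {
        "statistic": r.statistic_name,
        "value": r.empirical_value,
        "p": r.p_value,
        "n_shuffles": r.n_shuffles,
        "n_failed": r.n_failed,
        "seed": r.seed,
    }
    if keep_null:
        out["null_values"] = r.null_values
    return out


def run_experiment2(session: Session, config: AnalysisConfig | None = None
                    ) -> ExperimentReport:
    """Spatiotemporal-frequency experiment: speed/gain surfaces and Q.

    Builds condition-mean speed surfaces in each analysis window, fits the
    2-D Gaussian tuning model (full, and reduced with Q = 0) and runs the
    nested F test; gain surfaces (speed / stimulus speed) are reported
    without model fits. Cells with fewer than ``min_trials_per_cell`` trials
    are marked missing.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    vtraces = _velocities(session)
    grid = default_grid()
    sf_values = np.array(sorted({tr.meta["sf_cpd"] for tr in vtraces}))
    tf_values = np.array(sorted({tr.meta["tf_hz"] for tr in vtraces}))
    logger.info(
        "experiment 2: %d trials, %d x %d frequency grid",
        len(vtraces), len(sf_values), len(tf_values),
    )

    _, V = component_matrix(vtraces, config.component, grid)
    sf_lab = np.array([tr.meta["sf_cpd"] for tr in vtraces])
    tf_lab = np.array([tr.meta["tf_hz"] for tr in vtraces])

    windows_out = {}
    for lo, hi in config.tuning_windows:
        wmask = (grid >= lo) & (grid < hi)
        speed = np.full((len(sf_values), len(tf_values)), np.nan)
        n_cell = np.zeros_like(speed, dtype=int)
        for i, sf in enumerate(sf_values):
            for j, tf in enumerate(tf_values):
                sel = (sf_lab == sf) & (tf_lab == tf)
                n_cell[i, j] = int(sel.sum())
                if n_cell[i, j] >= config.min_trials_per_cell:
                    per_trial = np.nanmean(V[np.ix_(sel, wmask)], axis=1)
                    speed[i, j] = float(np.nanmean(per_trial))
        frac_missing = float(np.mean(~np.isfinite(speed)))
        if frac_missing > config.max_missing_fraction:
            raise RuntimeError(
                f"window {lo}-{hi} ms: {frac_missing:.0%} of cells missing "
                f"(> {config.max_missing_fraction:.0%}); aborting. "
                f"Cell counts: min={n_cell.min()}, median={int(np.median(n_cell))}"
            )
        surf = TuningSurface(sf_values, tf_values, speed, n_trials=n_cell,
                             time_window=(lo, hi))
        full, reduced = fit_tuning_nested_pair(
            surf, temporal_space=config.temporal_space
        )
        ftest = f_test_q(full, reduced)
        gains = gain_surface(surf)
        key = f"{lo:g}-{hi:g}"
        windows_out[key] = {
            "speed_surface_dps": speed,
            "gain_surface": gains.values,
            "n_trials": n_cell,
            "missing_cells": int(np.sum(~np.isfinite(speed))),
            "fit": {
                "A": full.A, "b": full.b, "sf0_cpd": full.sf0, "tf0_hz": full.tf0,
                "sigma_s": full.sigma_s, "sigma_t": full.sigma_t, "Q": full.Q,
                "rss": full.rss, "r_squared": full.r_squared,
                "n_cells": full.n_cells, "temporal_space": full.temporal_space,
            },
            "reduced_rss": reduced.rss,
            "f_test": ftest,
        }

    results = {
        "sf_values_cpd": sf_values,
        "tf_values_hz": tf_values,
        "windows": windows_out,
    }
    return ExperimentReport("tuning", results, _provenance(config, session, t0))


def run_experiment3(session: Session, config: AnalysisConfig | None = None
                    ) -> ExperimentReport:
    """Direction-congruence experiment: speeds and latencies by congruence.

    Pools the 4 x 2 saccade/stimulus-direction design onto horizontal and
    vertical axes (sign-inverting 180/270-degree stimulus directions),
    compares per-trial window speeds between identical and opposite groups
    with pooled-variance t tests, and tests latency differences with the
    randomization test.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    vtraces = _velocities(session)
    grid = default_grid()
    pooled = st.pool_directions(vtraces)
    logger.info("experiment 3: %d trials", len(vtraces))

    # animal-specific window: median piecewise latency over the four
    # axis x congruence group-mean traces
    group_fits = {}
    for axis in ("horizontal", "vertical"):
        comp = axis
        for relative in ("identical", "opposite"):
            sel = pooled[axis][relative]
            if not sel:
                continue
            prof = align_and_average(sel, condition=(axis, relative),
                                     use_component=comp, grid=grid)
            fit = fit_piecewise_latency(prof, fit_window=config.fit_window)
            group_fits[(axis, relative)] = (prof, fit)
    if not group_fits:
        raise ValueError("no analyzable axis in the direction design")
    median_latency = float(np.median([f.c for _, f in group_fits.values()]))
    win_start = median_latency + config.window_offset

    axes_out = {}
    for axis in ("horizontal", "vertical"):
        groups = pooled[axis]
        if not groups["identical"] or not groups["opposite"]:
            logger.warning("axis %s missing a congruence group; skipped", axis)
            continue
        comp = axis
        speeds = {}
        for relative in ("identical", "opposite"):
            speeds[relative] = np.array([
                window_mean_speed(tr, win_start, config.window_len, component=comp)
                for tr in groups[relative]
            ])
        ttest = st.two_sample_t(speeds["identical"], speeds["opposite"])
        axis_trials = groups["identical"] + groups["opposite"]
        in_identical = np.array(
            [True] * len(groups["identical"]) + [False] * len(groups["opposite"])
        )
        lat_diff = st.randomization_latency_difference_test(
            axis_trials, in_identical, n_shuffles=config.n_shuffles,
            seed=config.seed + (0 if axis == "horizontal" else 1),
            component=comp, fit_window=config.fit_window, grid=grid,
        )
        axes_out[axis] = {
            "profiles": {
                rel: _profile_dict(group_fits[(axis, rel)][0])
                for rel in ("identical", "opposite")
                if (axis, rel) in group_fits
            },
            "mean_speed_identical_dps": float(np.mean(speeds["identical"])),
            "mean_speed_opposite_dps": float(np.mean(speeds["opposite"])),
            "n_identical": len(speeds["identical"]),
            "n_opposite": len(speeds["opposite"]),
            "t_test": ttest,
            "latency_identical_ms": group_fits[(axis, "identical")][1].c,
            "latency_opposite_ms": group_fits[(axis, "opposite")][1].c,
            "latency_difference_test": _rand_dict(lat_diff),
        }

    results = {
        "median_latency_ms": median_latency,
        "window_ms": [win_start, win_start + config.window_len],
        "axes": axes_out,
    }
    return ExperimentReport("direction", results, _provenance(config, session, t0))


RUNNERS = {
    "delay": run_experiment1,
    "tuning": run_experiment2,
    "direction": run_experiment3,
}


def run_experiment(session: Session, experiment: str,
                   config: AnalysisConfig | None = None) -> ExperimentReport:
    """Dispatch to the appropriate experiment runner."""
    try:
        runner = RUNNERS[experiment]
    except KeyError:
        raise ValueError(
            f"unknown experiment {experiment!r}; expected one of {sorted(RUNNERS)}"
        ) from None
    return runner(session, config)
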