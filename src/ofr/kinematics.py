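"""Eye-movement kinematics: velocity estimation, alignment, and trial averaging.

Raw gaze traces (horizontal/vertical eye position in degrees, sampled at
500 Hz) are differentiated with a Savitzky-Golay filter, aligned to stimulus
motion onset, projected onto the stimulus motion axis, and averaged across
trials to give mean speed profiles with pointwise standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_coeffs

#: sampling interval of the eye tracker, ms (500 Hz)
DT_MS = 2.0
#: Savitzky-Golay differentiator: polynomial order 3, 21 points (42 ms)
SG_WINDOW = 21
SG_ORDER = 3
#: default grid for motion-onset-aligned averaging, ms relative to onset
ALIGN_START_MS = -50.0
ALIGN_STOP_MS = 300.0
#: a trial is dropped from averaging if more than this fraction of the
#: aligned grid is invalid (signal loss / filter edges)
MAX_INVALID_FRACTION = 0.25

# derivative coefficients in deg/ms per deg; dot with a 21-sample window
_SG_DERIV = savgol_coeffs(SG_WINDOW, SG_ORDER, deriv=1, delta=DT_MS, use="dot")
_HALF = SG_WINDOW // 2


def default_grid() -> np.ndarray:
    """The common 2-ms aligned time grid, -50 to +300 ms around motion onset."""
    return np.arange(ALIGN_START_MS, ALIGN_STOP_MS + DT_MS / 2, DT_MS)


@dataclass
class EyeTrace:
    """One trial's raw gaze samples with event timestamps.

    Attributes
    ----------
    trial_id : int
    t : ndarray
        Sample times in ms from trial start; strictly increasing, uniform
        2-ms step.
    x, y : ndarray
        Gaze position in degrees (x positive rightward, y positive upward).
        NaN marks signal loss.
    motion_onset : float
        Stimulus motion onset, ms from trial start.
    saccade_end : float
        End of the centering saccade, ms from trial start.
    meta : dict
        Condition labels copied from the trial design (experiment, delay_ms,
        sf_cpd, tf_hz, stim_speed_dps, saccade_dir_deg, stim_dir_deg).
    """

    trial_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    motion_onset: float
    saccade_end: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        dt = np.diff(self.t)
        if len(dt) and (np.any(dt <= 0) or np.any(np.abs(dt - DT_MS) > 1e-6)):
            raise ValueError("timestamps must increase uniformly at 2 ms (500 Hz)")
        if not (self.t[0] <= self.motion_onset <= self.t[-1]):
            raise ValueError("motion_onset outside the sampled interval")


@dataclass
class VelocityTrace:
    """Smoothed per-sample velocity aligned to motion onset.

    ``v_along`` is the signed velocity component along the stimulus motion
    direction (positive = with the stimulus):
    ``v_along = vx*cos(theta) + vy*sin(theta)``.
    """

    trial_id: int
    t_aligned: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    v_along: np.ndarray
    valid_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def component(self, which: str = "along") -> np.ndarray:
        if which == "along":
            return self.v_along
        if which == "horizontal":
            return self.vx
        if which == "vertical":
            return self.vy
        raise ValueError(f"unknown component {which!r}")


@dataclass
class MeanSpeedProfile:
    """Trial-averaged speed trace for one condition (pointwise mean, SE, n)."""

    key: object
    t_aligned: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_trials: int
    n_valid: np.ndarray | None = None


def sg_differentiate(values: np.ndarray) -> np.ndarray:
    """Savitzky-Golay first derivative of a uniformly sampled signal.

    Returns the derivative in (units of `values`) per second. Samples whose
    21-point window overlaps a NaN, and the 10 edge samples on either side,
    are NaN (masking, no padding).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = np.full(n, np.nan)
    if n < SG_WINDOW:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(values, SG_WINDOW)
    # NaN anywhere in the window propagates through the dot product
    out[_HALF : n - _HALF] = windows @ _SG_DERIV * 1000.0  # deg/ms -> deg/s
    return out


def savgol_velocity(trace: EyeTrace) -> VelocityTrace:
    """Differentiate an eye trace into a motion-onset-aligned velocity trace.

    Applies the order-3, 21-point (42 ms) Savitzky-Golay differentiator to x
    and y, scales to deg/s, and projects onto the stimulus direction. Edge
    samples and samples whose filter window overlaps signal loss are marked
    invalid rather than extrapolated.
    """
    if len(trace.t) < SG_WINDOW:
        raise ValueError(
            f"trace {trace.trial_id}: {len(trace.t)} samples, "
            f"need at least {SG_WINDOW} for the Savitzky-Golay window"
        )
    vx = sg_differentiate(trace.x)
    vy = sg_differentiate(trace.y)
    valid = np.isfinite(vx) & np.isfinite(vy)
    theta = np.deg2rad(float(trace.meta.get("stim_dir_deg", 0.0)))
    v_along = vx * np.cos(theta) + vy * np.sin(theta)
    return VelocityTrace(
        trial_id=trace.trial_id,
        t_aligned=trace.t - trace.motion_onset,
        vx=vx,
        vy=vy,
        v_along=v_along,
        valid_mask=valid,
        meta=dict(trace.meta),
    )


def component_matrix(
    traces: Sequence[VelocityTrace],
    component: str = "along",
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack velocity traces onto a common aligned grid.

    Returns ``(grid, V)`` where ``V[i, j]`` is trial i's chosen velocity
    component at grid time j (NaN where missing or invalid). Traces must be
    sampled on the same 2-ms phase as the grid; no interpolation is done.
    """
    if grid is None:
        grid = default_grid()
    V = np.full((len(traces), len(grid)), np.nan)
    for i, tr in enumerate(traces):
        v = np.where(tr.valid_mask, tr.component(component), np.nan)
        # locate this trace's samples on the grid
        offset = (grid[0] - tr.t_aligned[0]) / DT_MS
        if np.abs(offset - np.round(offset)) > 1e-6:
            raise ValueError(
                f"trial {tr.trial_id}: samples are off the common 2-ms grid"
            )
        offset = int(np.round(offset))
        src_lo = max(offset, 0)
        dst_lo = max(-offset, 0)
        n = min(len(tr.t_aligned) - src_lo, len(grid) - dst_lo)
        if n > 0:
            V[i, dst_lo : dst_lo + n] = v[src_lo : src_lo + n]
    return grid, V


def align_and_average(
    traces: Sequence[VelocityTrace],
    condition: object = None,
    use_component: str = "along",
    grid: np.ndarray | None = None,
    max_invalid_fraction: float = MAX_INVALID_FRACTION,
) -> MeanSpeedProfile:
    """Average motion-onset-aligned velocity traces into a mean speed profile.

    Invalid samples are excluded pointwise; whole trials are excluded when
    more than ``max_invalid_fraction`` of the grid is invalid. The SE is the
    pointwise standard error across trials.
    """
    if len(traces) == 0:
        raise ValueError("cannot average an empty trial list")
    grid, V = component_matrix(traces, use_component, grid)
    frac_bad = np.mean(~np.isfinite(V), axis=1)
    keep = frac_bad <= max_invalid_fraction
    if not np.any(keep):
        raise ValueError("no trial has enough valid samples in the window")
    V = V[keep]
    n_valid = np.sum(np.isfinite(V), axis=0)
    if np.any(n_valid == 0):
        t_bad = grid[np.argmax(n_valid == 0)]
        raise ValueError(f"zero valid trials at timepoint t={t_bad:g} ms")
    mean = np.nanmean(V, axis=0)
    if V.shape[0] > 1:
        sd = np.nanstd(V, axis=0, ddof=1)
    else:
        sd = np.zeros_like(mean)
    se = np.where(n_valid > 0, sd / np.sqrt(np.maximum(n_valid, 1)), np.nan)
    return MeanSpeedProfile(
        key=condition,
        t_aligned=grid,
        mean=mean,
        se=se,
        n_trials=int(V.shape[0]),
        n_valid=n_valid,
    )


def window_mean_speed(
    obj: MeanSpeedProfile | VelocityTrace,
    window_start: float,
    window_len: float = 50.0,
    component: str = "along",
) -> float:
    """Mean speed over the half-open window [start, start+len) ms.

    Times are relative to motion onset. For a :class:`VelocityTrace`, invalid
    samples inside the window are excluded; the window must lie fully inside
    the trace/profile and contain at least one valid sample.
    """
    if isinstance(obj, MeanSpeedProfile):
        t, v = obj.t_aligned, obj.mean
    else:
        t = obj.t_aligned
        v = np.where(obj.valid_mask, obj.component(component), np.nan)
    if window_start < t[0] or window_start + window_len > t[-1] + DT_MS:
        raise ValueError(
            f"window [{window_start}, {window_start + window_len}) outside "
            f"data range [{t[0]}, {t[-1]}]"
        )
    mask = (t >= window_start) & (t < window_start + window_len)
    vals = v[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no valid samples in the requested window")
    return float(np.mean(vals))
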