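"""Synthetic ocular-following sessions with known ground truth.

Each trial emulates the experimental sequence: eccentric fixation 5 degrees
from the screen center, a 30-ms raised-cosine centering saccade, a
postsaccadic hold of the specified delay, and then stimulus motion. The
tracking response along the stimulus axis is zero until an onset latency c
and then ramps linearly at slope a until it saturates at a plateau — the
same flat-then-ramp form the piecewise latency fit assumes — with

    c = base_latency + latency_delay_slope * delay,

and a multiplicative gain scale exp(-delay / gain_delay_decay), times the
congruence factor when saccade and stimulus directions are identical, times
(for gratings) the 2-D Gaussian tuning-surface value. The gain scale
multiplies both the ramp slope and the plateau, so the entire noiseless
post-onset speed trace scales with condition gain and the rise time is
condition-invariant (this keeps the ramp fittable inside the 30-150 ms
latency window at every delay). I.i.d. Gaussian position noise is added per
sample.

Three standard condition designs are provided, mirroring the behavioural
experiments: postsaccadic delay (6 levels x 2 directions), spatiotemporal
frequency (7 SF x 6 TF gratings at a fixed 50-ms delay), and
saccade/stimulus direction congruence (4 saccade directions x
identical/opposite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import DT_MS, EyeTrace
from .tuning import SF_GRID, TF_GRID, GaussianFit2D, eval_tuning

#: postsaccadic delay levels, ms
DELAY_LEVELS = (10.0, 30.0, 50.0, 100.0, 200.0, 300.0)
#: random-dot stimulus speed, deg/s
DOT_SPEED = 30.0
#: fixed delay for the tuning and direction designs, ms
FIXED_DELAY = 50.0

#: trial timeline constants (ms): fixation duration, saccade duration,
#: saccade amplitude (deg), and recording tail after stimulus motion ends
FIXATION_MS = 200.0
SACCADE_MS = 30.0
SACCADE_AMPLITUDE = 5.0
TAIL_MS = 70.0

EXPERIMENTS = ("delay", "tuning", "direction")


@dataclass
class TrialSpec:
    """Design parameters for one trial."""

    trial_id: int
    experiment: str
    postsaccadic_delay: float
    spatial_frequency: float | None
    temporal_frequency: float | None
    stimulus_speed: float
    saccade_direction: float
    stimulus_direction: float
    motion_duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        if self.postsaccadic_delay < 0:
            raise ValueError("postsaccadic_delay must be >= 0")
        if self.stimulus_speed <= 0:
            raise ValueError("stimulus_speed must be > 0")
        if self.spatial_frequency is not None:
            expected = self.temporal_frequency / self.spatial_frequency
            if not math.isclose(self.stimulus_speed, expected, rel_tol=1e-9):
                raise ValueError("for gratings stimulus_speed must equal tf/sf")

    @property
    def is_grating(self) -> bool:
        return self.spatial_frequency is not None


def _default_tuning() -> GaussianFit2D:
    # peak near 0.16 cpd / 16 Hz, peak speed ~5.5 deg/s, modest speed tuning
    return GaussianFit2D(
        A=5.0, b=0.5, sf0=0.16, tf0=16.0, sigma_s=2.0, sigma_t=2.0, Q=0.25
    )


@dataclass
class GroundTruth:
    """Generator-side truth for every effect the analysis estimates.

    Units: latencies and time constants in ms, ramp_slope in deg/s per ms,
    noise_sd in degrees of position per sample. ``gain_delay_decay`` is the
    exponential time constant of the postsaccadic-enhancement decay;
    ``congruence_factor`` multiplies the gain when saccade and stimulus
    directions are identical; ``plateau_fraction`` scales the saturation
    speed relative to gain * stimulus speed.
    """

    base_latency: float = 50.0
    latency_delay_slope: float = 0.05
    base_gain: float = 0.2
    gain_delay_decay: float = 200.0
    ramp_slope: float = 0.06
    tuning_params: GaussianFit2D = field(default_factory=_default_tuning)
    congruence_factor: float = 1.3
    noise_sd: float = 0.05
    plateau_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_gain <= 1.0):
            raise ValueError("base_gain must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.congruence_factor < 1:
            raise ValueError("congruence_factor must be >= 1")
        if self.gain_delay_decay <= 0:
            raise ValueError("gain_delay_decay must be > 0")


def truth_from_dict(cfg: dict) -> GroundTruth:
    """Build a GroundTruth from a flat key-value config.

    Tuning-surface parameters use a ``tuning_`` prefix (tuning_A, tuning_b,
    tuning_sf0, tuning_tf0, tuning_sigma_s, tuning_sigma_t, tuning_Q).
    """
    tuning_kwargs = {
        k[len("tuning_"):]: v for k, v in cfg.items() if k.startswith("tuning_")
    }
    plain = {k: v for k, v in cfg.items() if not k.startswith("tuning_")}
    truth = GroundTruth(**plain)
    if tuning_kwargs:
        truth = replace(truth, tuning_params=replace(truth.tuning_params, **tuning_kwargs))
    return truth


def make_design(
    experiment: str, trials_per_condition: int, seed: int = 0
) -> list[TrialSpec]:
    """Build a randomized trial list for one of the three standard designs.

    delay:     6 postsaccadic delays x 2 directions (saccade = stimulus).
    tuning:    42 SF x TF grating cells at a fixed 50-ms delay.
    direction: 4 saccade directions x identical/opposite stimulus direction.
    """
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    conditions: list[dict] = []
    if experiment == "delay":
        for delay in DELAY_LEVELS:
            for direction in (0.0, 180.0):
                conditions.append(
                    dict(postsaccadic_delay=delay, spatial_frequency=None,
                         temporal_frequency=None, stimulus_speed=DOT_SPEED,
                         saccade_direction=direction, stimulus_direction=direction)
                )
    elif experiment == "tuning":
        rng_dir = np.random.default_rng(seed)
        for sf in SF_GRID:
            for tf in TF_GRID:
                direction = float(rng_dir.choice((0.0, 180.0)))
                conditions.append(
                    dict(postsaccadic_delay=FIXED_DELAY, spatial_frequency=float(sf),
                         temporal_frequency=float(tf), stimulus_speed=float(tf / sf),
                         saccade_direction=direction, stimulus_direction=direction)
                )
    elif experiment == "direction":
        for sacc in (0.0, 90.0, 180.0, 270.0):
            for relative in ("identical", "opposite"):
                stim = sacc if relative == "identical" else (sacc + 180.0) % 360.0
                conditions.append(
                    dict(postsaccadic_delay=FIXED_DELAY, spatial_frequency=None,
                         temporal_frequency=None, stimulus_speed=DOT_SPEED,
                         saccade_direction=sacc, stimulus_direction=stim)
                )
    else:
        raise ValueError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conditions) * trials_per_condition)
    specs = []
    for trial_id, idx in enumerate(order):
        cond = conditions[idx % len(conditions)]
        specs.append(
            TrialSpec(trial_id=trial_id, experiment=experiment, seed=trial_id, **cond)
        )
    return specs


def derive_trial_seed(master_seed: int, trial_id: int) -> int:
    """Per-trial RNG seed: a stated counter scheme, reproducible per trial."""
    return (int(master_seed) * 1_000_003 + int(trial_id) + 1) % (2**31)


def _is_congruent(spec: TrialSpec) -> bool:
    return (spec.stimulus_direction - spec.saccade_direction) % 360.0 == 0.0


def response_params(spec: TrialSpec, truth: GroundTruth) -> tuple[float, float, float]:
    """Noiseless response parameters for one trial: (c, slope, plateau).

    c is the onset latency in ms after motion onset, slope the initial
    acceleration of the speed ramp (deg/s per ms), plateau the saturation
    speed (deg/s). Both slope and plateau carry the same multiplicative
    condition gain, so the speed trace is gain * min(a0*(t-c), v0).
    """
    c = truth.base_latency + truth.latency_delay_slope * spec.postsaccadic_delay
    scale = math.exp(-spec.postsaccadic_delay / truth.gain_delay_decay)
    if _is_congruent(spec):
        scale *= truth.congruence_factor
    if spec.is_grating:
        surface = float(
            eval_tuning(truth.tuning_params, spec.spatial_frequency,
                        spec.temporal_frequency)
        )
        peak = truth.tuning_params.A + truth.tuning_params.b
        rel = surface / peak if peak > 0 else 0.0
        slope = truth.ramp_slope * rel * scale
        plateau = truth.plateau_fraction * surface * scale
    else:
        slope = truth.ramp_slope * scale
        plateau = truth.plateau_fraction * truth.base_gain * spec.stimulus_speed * scale
    return c, slope, max(plateau, 0.0)


def _tracking_displacement(tau: np.ndarray, c: float, slope: float, plateau: float
                           ) -> np.ndarray:
    """Exact integral of the flat/ramp/plateau speed profile, in degrees."""
    s = np.zeros_like(tau)
    if slope <= 0.0 or plateau <= 0.0:
        return s
    ramp_ms = plateau / slope
    t1 = tau - c
    in_ramp = (t1 > 0) & (t1 <= ramp_ms)
    s[in_ramp] = 0.5 * slope * t1[in_ramp] ** 2 / 1000.0
    past = t1 > ramp_ms
    s[past] = (0.5 * slope * ramp_ms**2 + plateau * (t1[past] - ramp_ms)) / 1000.0
    return s


def ideal_speed_profile(
    spec: TrialSpec, truth: GroundTruth, t_aligned: np.ndarray
) -> np.ndarray:
    """Noiseless tracking speed along the stimulus axis on an aligned grid.

    Exactly piecewise linear: zero before the onset latency, then a ramp
    saturating at the plateau. Saccade kinematics are not included.
    """
    c, slope, plateau = response_params(spec, truth)
    tau = np.asarray(t_aligned, dtype=float)
    return np.clip(slope * (tau - c), 0.0, plateau)


def simulate_trial(spec: TrialSpec, truth: GroundTruth, rng_seed: int) -> EyeTrace:
    """Simulate one trial's 500-Hz gaze trace.

    Timeline (ms from trial start): fixation at the eccentric start position
    until 200, raised-cosine 5-degree centering saccade 200-230, hold for the
    postsaccadic delay, then stimulus motion for ``spec.motion_duration``
    plus a 70-ms recorded tail. Identical (spec, truth, rng_seed) triples
    produce bit-identical traces.
    """
    saccade_start = FIXATION_MS
    saccade_end = saccade_start + SACCADE_MS
    motion_onset = saccade_end + spec.postsaccadic_delay
    t_end = motion_onset + spec.motion_duration + TAIL_MS
    t = np.arange(0.0, t_end + DT_MS / 2, DT_MS)

    u_sacc = np.array(
        [math.cos(math.radians(spec.saccade_direction)),
         math.sin(math.radians(spec.saccade_direction))]
    )
    u_stim = np.array(
        [math.cos(math.radians(spec.stimulus_direction)),
         math.sin(math.radians(spec.stimulus_direction))]
    )

    # centering saccade: raised-cosine position profile from -5 deg to 0
    pos = np.zeros((len(t), 2))
    start = -SACCADE_AMPLITUDE * u_sacc
    pos[t <= saccade_start] = start
    during = (t > saccade_start) & (t < saccade_end)
    phase = (t[during] - saccade_start) / SACCADE_MS
    pos[during] = start * (0.5 * (1.0 + np.cos(np.pi * phase)))[:, None]

    # tracking: exact integral of the flat/ramp/plateau speed profile
    c, slope, plateau = response_params(spec, truth)
    disp = _tracking_displacement(t - motion_onset, c, slope, plateau)
    pos += disp[:, None] * u_stim[None, :]

    if truth.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        pos = pos + rng.normal(0.0, truth.noise_sd, size=pos.shape)

    return EyeTrace(
        trial_id=spec.trial_id,
        t=t,
        x=pos[:, 0],
        y=pos[:, 1],
        motion_onset=motion_onset,
        saccade_end=saccade_end,
        meta=dict(
            experiment=spec.experiment,
            delay_ms=spec.postsaccadic_delay,
            sf_cpd=spec.spatial_frequency,
            tf_hz=spec.temporal_frequency,
            stim_speed_dps=spec.stimulus_speed,
            saccade_dir_deg=spec.saccade_direction,
            stim_dir_deg=spec.stimulus_direction,
        ),
    )


def simulate_session(
    specs: list[TrialSpec], truth: GroundTruth, master_seed: int
) -> list[EyeTrace]:
    """Simulate every trial of a design with per-trial derived seeds."""
    return [
        simulate_trial(spec, truth, derive_trial_seed(master_seed, spec.trial_id))
        for spec in specs
    ]


def inject_nan_gap(trace: EyeTrace, start_ms: float, length_ms: float) -> EyeTrace:
    """Blank a [start, start+length) interval with NaN (signal-loss model)."""
    mask = (trace.t >= start_ms) & (trace.t < start_ms + length_ms)
    x, y = trace.x.copy(), trace.y.copy()
    x[mask] = np.nan
    y[mask] = np.nan
    return EyeTrace(
        trial_id=trace.trial_id, t=trace.t.copy(), x=x, y=y,
        motion_onset=trace.motion_onset, saccade_end=trace.saccade_end,
        meta=dict(trace.meta),
    )
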