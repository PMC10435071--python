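"""Session and results file formats.

A session is two delimited text files (UTF-8 CSV, comma separator, header
row) with ``#``-prefixed metadata lines declaring the format version,
sample rate, and units:

* samples table: trial_id, t_ms, x_deg, y_deg (one row per 2-ms sample)
* trials table: trial_id, experiment, delay_ms, sf_cpd, tf_hz,
  stim_speed_dps, saccade_dir_deg, stim_dir_deg, motion_onset_ms,
  saccade_end_ms

Coordinates are degrees of visual angle (x rightward, y upward), time is ms
from trial start; motion-relative alignment is always computed, never
stored. Validation enumerates problems and never silently fixes them.

Recorded datasets from other acquisition systems are adapted through
:func:`from_external`, which takes already-parsed dataframes plus an
explicit column mapping (native binary eye-tracker formats are converted
upstream of this package).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import DT_MS, EyeTrace

FORMAT_VERSION = 1
SAMPLE_RATE_HZ = 500.0

TRIAL_COLUMNS = [
    "trial_id", "experiment", "delay_ms", "sf_cpd", "tf_hz",
    "stim_speed_dps", "saccade_dir_deg", "stim_dir_deg",
    "motion_onset_ms", "saccade_end_ms",
]
SAMPLE_COLUMNS = ["trial_id", "t_ms", "x_deg", "y_deg"]

_META_KEYS = ("format_version", "sample_rate_hz", "units")


@dataclass
class Session:
    """An in-memory session: per-trial traces plus the trial metadata table."""

    traces: list[EyeTrace]
    format_version: int = FORMAT_VERSION
    sample_rate_hz: float = SAMPLE_RATE_HZ
    extra: dict = field(default_factory=dict)

    def trials_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            rows.append(
                dict(
                    trial_id=tr.trial_id,
                    experiment=tr.meta.get("experiment"),
                    delay_ms=tr.meta.get("delay_ms"),
                    sf_cpd=tr.meta.get("sf_cpd"),
                    tf_hz=tr.meta.get("tf_hz"),
                    stim_speed_dps=tr.meta.get("stim_speed_dps"),
                    saccade_dir_deg=tr.meta.get("saccade_dir_deg"),
                    stim_dir_deg=tr.meta.get("stim_dir_deg"),
                    motion_onset_ms=tr.motion_onset,
                    saccade_end_ms=tr.saccade_end,
                )
            )
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)

    def samples_table(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"trial_id": tr.trial_id, "t_ms": tr.t, "x_deg": tr.x, "y_deg": tr.y}
            )
            for tr in self.traces
        ]
        return pd.concat(frames, ignore_index=True)[SAMPLE_COLUMNS]


def _write_header(fh) -> None:
    fh.write(f"# format_version={FORMAT_VERSION}\n")
    fh.write(f"# sample_rate_hz={SAMPLE_RATE_HZ:g}\n")
    fh.write("# units=deg,ms\n")


def _read_header(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def write_session(session: Session, samples_path, trials_path) -> None:
    """Write a session as the two-CSV interchange format (lossless to 1e-9)."""
    for path, table in (
        (samples_path, session.samples_table()),
        (trials_path, session.trials_table()),
    ):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _write_header(fh)
            table.to_csv(fh, index=False, float_format="%.9g")


def _check_header(meta: dict, path) -> None:
    if meta.get("format_version") != str(FORMAT_VERSION):
        raise ValueError(
            f"{path}: unknown format_version {meta.get('format_version')!r}"
        )
    if float(meta.get("sample_rate_hz", "nan")) != SAMPLE_RATE_HZ:
        raise ValueError(f"{path}: sample rate must be {SAMPLE_RATE_HZ:g} Hz")
    if meta.get("units") != "deg,ms":
        raise ValueError(f"{path}: units must be 'deg,ms', got {meta.get('units')!r}")


def read_session(samples_path, trials_path) -> Session:
    """Read the two-CSV session format back into memory.

    Rejects unknown format versions, unit mismatches, and non-uniform
    timestamps with row-level diagnostics.
    """
    for path in (samples_path, trials_path):
        _check_header(_read_header(path), path)
    samples = pd.read_csv(samples_path, comment="#")
    trials = pd.read_csv(trials_path, comment="#")
    return _assemble(samples, trials)


def _assemble(samples: pd.DataFrame, trials: pd.DataFrame) -> Session:
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"samples table missing columns {sorted(missing)}")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns {sorted(missing)}")
    known = set(trials["trial_id"])
    orphans = set(samples["trial_id"]) - known
    if orphans:
        raise ValueError(
            f"samples reference trial_ids absent from trials table: {sorted(orphans)[:5]}"
        )
    traces = []
    for row in trials.itertuples():
        block = samples[samples["trial_id"] == row.trial_id]
        t = block["t_ms"].to_numpy(dtype=float)
        if len(t) >= 2:
            dt = np.diff(t)
            bad = np.nonzero(np.abs(dt - DT_MS) > 1e-6)[0]
            if len(bad):
                raise ValueError(
                    f"trial {row.trial_id}: non-uniform timestamp at sample row "
                    f"{bad[0] + 1} (dt={dt[bad[0]]:g} ms, expected {DT_MS:g})"
                )
        sf = None if pd.isna(row.sf_cpd) else float(row.sf_cpd)
        tf = None if pd.isna(row.tf_hz) else float(row.tf_hz)
        traces.append(
            EyeTrace(
                trial_id=int(row.trial_id),
                t=t,
                x=block["x_deg"].to_numpy(dtype=float),
                y=block["y_deg"].to_numpy(dtype=float),
                motion_onset=float(row.motion_onset_ms),
                saccade_end=float(row.saccade_end_ms),
                meta=dict(
                    experiment=row.experiment,
                    delay_ms=float(row.delay_ms),
                    sf_cpd=sf,
                    tf_hz=tf,
                    stim_speed_dps=float(row.stim_speed_dps),
                    saccade_dir_deg=float(row.saccade_dir_deg),
                    stim_dir_deg=float(row.stim_dir_deg),
                ),
            )
        )
    return Session(traces=traces)


def validate_session(samples: pd.DataFrame, trials: pd.DataFrame) -> list[str]:
    """Enumerate structural problems in raw session tables (never fixes them).

    Checks: required columns, orphan sample rows, trials without samples,
    duplicate trial ids, non-uniform timestamps, non-finite metadata.
    """
    issues: list[str] = []
    for name, table, cols in (
        ("samples", samples, SAMPLE_COLUMNS),
        ("trials", trials, TRIAL_COLUMNS),
    ):
        missing = set(cols) - set(table.columns)
        if missing:
            issues.append(f"{name} table missing columns {sorted(missing)}")
    if issues:
        return issues
    dup = trials["trial_id"][trials["trial_id"].duplicated()]
    for tid in dup:
        issues.append(f"duplicate trial_id {tid} in trials table")
    known = set(trials["trial_id"])
    for i, tid in enumerate(samples["trial_id"]):
        if tid not in known:
            issues.append(
                f"samples row {i}: trial_id {tid} absent from trials table"
            )
    for tid, block in samples.groupby("trial_id"):
        t = block["t_ms"].to_numpy(dtype=float)
        if len(t) >= 2:
            dt = np.diff(t)
            bad = np.nonzero(np.abs(dt - DT_MS) > 1e-6)[0]
            if len(bad):
                issues.append(
                    f"trial {tid}: non-uniform timestamps starting at sample "
                    f"{bad[0] + 1} (dt={dt[bad[0]]:g} ms, expected {DT_MS:g})"
                )
    for row in trials.itertuples():
        onset = row.motion_onset_ms
        if not np.isfinite(onset):
            issues.append(f"trial {row.trial_id}: non-finite motion_onset_ms")
    return issues


def from_external(
    samples: pd.DataFrame, trials: pd.DataFrame, column_map: dict[str, str]
) -> Session:
    """Adapt externally recorded tables to the session model.

    ``column_map`` maps this package's column names (see SAMPLE_COLUMNS and
    TRIAL_COLUMNS) to the external table's column names; unmapped names are
    assumed to match. Sample times must already be in ms on a uniform 2-ms
    grid and positions in degrees — unit conversion is the caller's contract.
    """
    inv = {v: k for k, v in column_map.items()}
    samples = samples.rename(columns=inv)
    trials = trials.rename(columns=inv)
    issues = validate_session(samples, trials)
    if issues:
        raise ValueError("external tables failed validation: " + "; ".join(issues[:5]))
    return _assemble(samples, trials)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path) -> None:
    """Serialize an analysis report as versioned JSON (NaN/inf become null)."""
    payload = {"report_version": FORMAT_VERSION, **_jsonable(report)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
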