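"""The 150-variable kinematic feature set.

For each of the five TUG subphases: three-plane range of motion (ROM) and
angular-velocity range for trunk, hip, knee and ankle (4 joints x 3 planes
x 2 measures x 5 phases = 120 variables), plus centre-of-mass displacement
and velocity range along the AP, ML and vertical axes (3 x 2 x 5 = 30).
Every variable is a max − min over the phase window, hence non-negative,
offset-invariant, and exactly |c|-homogeneous under channel scaling.

Feature names follow ``<signal>_<plane>_<measure>_<phase>``, e.g.
``hip_sagittal_rom_deg_walk_back`` or ``com_ml_displacement_m_turn``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import COM_AXES, JOINTS, PHASES, PLANES, CohortDataset, TrialRecording
from .segmentation import EventSet, NoEventError, SegmentationConfig, segment_trial

__all__ = [
    "feature_names",
    "parse_feature_name",
    "signal_range",
    "angular_velocity",
    "extract_features",
    "build_feature_table",
    "phase_columns",
    "flag_outliers",
]

logger = logging.getLogger(__name__)

_JOINT_MEASURES = ("rom_deg", "velocity_range_deg_s")
_COM_MEASURES = ("displacement_m", "velocity_range_m_s")


def feature_names() -> list:
    """The canonical, ordered list of the 150 feature names."""
    names = []
    for j in JOINTS:
        for p in PLANES:
            for measure in _JOINT_MEASURES:
                for phase in PHASES:
                    names.append(f"{j}_{p}_{measure}_{phase}")
    for a in COM_AXES:
        for measure in _COM_MEASURES:
            for phase in PHASES:
                names.append(f"com_{a}_{measure}_{phase}")
    return names


def parse_feature_name(name: str) -> tuple:
    """Split a feature name into (signal, plane_or_axis, measure, phase)."""
    for phase in PHASES:
        suffix = f"_{phase}"
        if name.endswith(suffix):
            stem = name[: -len(suffix)]
            break
    else:
        raise ValueError(f"no phase suffix in feature name {name!r}")
    sig, _, rest = stem.partition("_")
    plane, _, measure = rest.partition("_")
    return sig, plane, measure, phase


def phase_columns(phase: str) -> list:
    """The 30 feature names belonging to one phase."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    return [n for n in feature_names() if n.endswith(f"_{phase}")]


def signal_range(series: np.ndarray, window: tuple) -> float:
    """max − min of ``series`` over the half-open window [start, end)."""
    start, end = window
    if end <= start:
        raise ValueError(f"empty window: {window}")
    if start < 0 or end > len(series):
        raise ValueError(f"window {window} outside series of length {len(series)}")
    seg = np.asarray(series[start:end], dtype=float)
    return float(seg.max() - seg.min())


def angular_velocity(series: np.ndarray, sampling_rate: float) -> np.ndarray:
    """First-difference derivative scaled by the sampling rate.

    Central differences in the interior, one-sided at the edges; output has
    the same length as the input.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("derivative needs at least 2 samples")
    return np.gradient(series) * sampling_rate


def extract_features(recording: TrialRecording, events: EventSet) -> pd.Series:
    """Compute all 150 per-phase range features for one segmented trial."""
    windows = events.phase_windows()
    fs = recording.sampling_rate
    for ph, (a, b) in windows.items():
        if b - a < 2:
            raise ValueError(f"phase {ph!r} spans fewer than 2 samples")
        if b > recording.n_samples:
            raise ValueError(f"phase {ph!r} window exceeds the recording")
    values = {}
    for j in JOINTS:
        for p in PLANES:
            angle = recording.angles[(j, p)]
            vel = angular_velocity(angle, fs)
            for phase, win in windows.items():
                values[f"{j}_{p}_rom_deg_{phase}"] = signal_range(angle, win)
                values[f"{j}_{p}_velocity_range_deg_s_{phase}"] = signal_range(vel, win)
    for a in COM_AXES:
        pos = recording.com_position[a]
        vel = angular_velocity(pos, fs)  # same derivative operator as angles
        for phase, win in windows.items():
            values[f"com_{a}_displacement_m_{phase}"] = signal_range(pos, win)
            values[f"com_{a}_velocity_range_m_s_{phase}"] = signal_range(vel, win)
    return pd.Series(values).reindex(feature_names())


def build_feature_table(
    cohort: CohortDataset,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> pd.DataFrame:
    """One row of 150 features per subject (index = subject_id).

    Subjects with several trials are averaged feature-wise.  Subjects whose
    trials all fail segmentation are dropped with a logged reason; the drop
    list is attached as ``df.attrs["dropped_subjects"]`` and group labels as
    ``df.attrs["group_labels"]``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = {}
    labels = {}
    dropped = {}
    for subject in cohort:
        per_trial = []
        for k, rec in enumerate(subject.trials):
            try:
                events = segment_trial(rec, cfg)
                per_trial.append(extract_features(rec, events))
            except (NoEventError, ValueError) as exc:
                logger.warning(
                    "subject %s trial %d unsegmentable: %s",
                    subject.subject_id, k, exc,
                )
        if per_trial:
            rows[subject.subject_id] = pd.concat(per_trial, axis=1).mean(axis=1)
            labels[subject.subject_id] = subject.group_label
        else:
            dropped[subject.subject_id] = "no segmentable trial"
            logger.warning("subject %s dropped: no segmentable trial",
                           subject.subject_id)
    if not rows:
        raise ValueError("no subject produced a segmentable trial")
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    table.attrs["group_labels"] = labels
    table.attrs["dropped_subjects"] = dropped
    return table


def flag_outliers(table: pd.DataFrame, k: float = 3.0) -> dict:
    """Extreme-outlier screen: values beyond Q3 + k·IQR or Q1 − k·IQR.

    Quartiles use linear interpolation (type 7); a degenerate IQR of 0
    yields no flags for that variable.  Returns a dict with a long-format
    ``flags`` frame (subject, variable, value, bound) and a per-subject,
    per-phase count table ``counts`` for manual review — exclusion is a
    reported decision, not automatic.
    """
    if len(table) < 4:
        raise ValueError("outlier screen needs at least 4 subjects")
    q1 = table.quantile(0.25)
    q3 = table.quantile(0.75)
    iqr = q3 - q1
    hi = q3 + k * iqr
    lo = q1 - k * iqr
    nondegenerate = iqr > 0
    out_hi = table.gt(hi, axis=1) & nondegenerate
    out_lo = table.lt(lo, axis=1) & nondegenerate
    records = []
    for mask, bound in ((out_hi, "high"), (out_lo, "low")):
        for subject, row in mask.iterrows():
            for var in row.index[row]:
                records.append(
                    {"subject_id": subject, "variable": var,
                     "value": table.at[subject, var], "bound": bound}
                )
    flags = pd.DataFrame(
        records, columns=["subject_id", "variable", "value", "bound"]
    )
    counts = pd.DataFrame(
        0, index=table.index, columns=list(PHASES), dtype=int
    )
    for _, rec in flags.iterrows():
        phase = parse_feature_name(rec["variable"])[3]
        counts.at[rec["subject_id"], phase] += 1
    return {"flags": flags, "counts": counts}
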