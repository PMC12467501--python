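"""Trial recordings, cohort containers and the tab-separated trial format.

A :class:`TrialRecording` bundles the synchronized time series measured during
one Timed Up and Go (TUG) trial: 3-D joint angles for trunk, hip, knee and
ankle (degrees), whole-body centre-of-mass position (m), vertical ground
reaction force from the seat plate and the chair plate (N), the heel-marker
anteroposterior velocity and the left/right shoulder-marker mediolateral
velocities (m/s).

The on-disk format is a UTF-8 TSV with a '.' decimal separator: optional
``# key: value`` metadata lines, one header row, one row per sample.  Channel
columns are named ``<joint>_<plane>_deg``, ``com_<axis>_m``, ``grf_seat_n``,
``grf_chairplate_n``, ``heel_ap_velocity_m_s`` and
``shoulder_ml_velocity_{left,right}_m_s``; a leading ``time_s`` column holds
``index / sampling_rate``.

Fixtures of the published summary tables (group characterisation counts,
phase durations, the rotated loading matrix and the component-score
comparisons) ship with the package and are loaded with :func:`load_fixture`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .stats import DisabilityIndicators

__all__ = [
    "JOINTS",
    "PLANES",
    "COM_AXES",
    "PHASES",
    "SchemaError",
    "TrialRecording",
    "Subject",
    "CohortDataset",
    "read_trial",
    "write_trial",
    "load_fixture",
]

JOINTS = ("trunk", "hip", "knee", "ankle")
PLANES = ("sagittal", "frontal", "transverse")
COM_AXES = ("ap", "ml", "vertical")
#: The five TUG subphases, delimited by events T0..T5.
PHASES = ("sit_to_walk", "walk_forward", "turn", "walk_back", "turn_to_sit")

ANGLE_COLUMNS = tuple(f"{j}_{p}_deg" for j in JOINTS for p in PLANES)
COM_COLUMNS = tuple(f"com_{a}_m" for a in COM_AXES)
SCALAR_COLUMNS = (
    "grf_seat_n",
    "grf_chairplate_n",
    "heel_ap_velocity_m_s",
    "shoulder_ml_velocity_left_m_s",
    "shoulder_ml_velocity_right_m_s",
)
CHANNEL_COLUMNS = ANGLE_COLUMNS + COM_COLUMNS + SCALAR_COLUMNS

_FIXTURES = {
    "table1_counts": "table1_counts.tsv",
    "table1_summaries": "table1_summaries.tsv",
    "table2_durations": "table2_durations.tsv",
    "table3_loadings": "table3_loadings.tsv",
    "table4_stats": "table4_stats.tsv",
}


class SchemaError(ValueError):
    """A trial file does not match the documented channel schema."""


@dataclass
class TrialRecording:
    """Synchronized time-series bundle for a single TUG trial.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (the study's optoelectronic system ran at 100 Hz).
    angles : dict
        ``(joint, plane) -> ndarray`` of joint angles in degrees.
    com_position : dict
        ``axis -> ndarray`` of centre-of-mass position in metres
        (``ap`` = walking direction positive, ``ml`` = leftward positive,
        ``vertical`` = up positive).
    target_position : float
        Anteroposterior coordinate (m) of the 3 m turning line.
    """

    sampling_rate: float
    angles: dict
    com_position: dict
    grf_seat: np.ndarray
    grf_chairplate: np.ndarray
    heel_ap_velocity: np.ndarray
    shoulder_ml_velocity_left: np.ndarray
    shoulder_ml_velocity_right: np.ndarray
    target_position: float = 3.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.angles = {k: np.asarray(v, dtype=float) for k, v in self.angles.items()}
        self.com_position = {
            k: np.asarray(v, dtype=float) for k, v in self.com_position.items()
        }
        for name in (
            "grf_seat",
            "grf_chairplate",
            "heel_ap_velocity",
            "shoulder_ml_velocity_left",
            "shoulder_ml_velocity_right",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        missing_angles = [
            (j, p) for j in JOINTS for p in PLANES if (j, p) not in self.angles
        ]
        if missing_angles:
            raise SchemaError(f"missing angle channels: {missing_angles}")
        missing_axes = [a for a in COM_AXES if a not in self.com_position]
        if missing_axes:
            raise SchemaError(f"missing CoM axes: {missing_axes}")
        lengths = {len(s) for s in self._all_series()}
        if len(lengths) != 1:
            raise SchemaError(f"channel lengths differ: {sorted(lengths)}")
        (n,) = lengths
        if n < 2:
            raise SchemaError(f"trial must have >= 2 samples, got {n}")
        for name, series in zip(self.channel_names(), self._all_series()):
            if not np.all(np.isfinite(series)):
                raise SchemaError(f"channel {name!r} contains missing samples")

    def _all_series(self):
        return (
            [self.angles[(j, p)] for j in JOINTS for p in PLANES]
            + [self.com_position[a] for a in COM_AXES]
            + [
                self.grf_seat,
                self.grf_chairplate,
                self.heel_ap_velocity,
                self.shoulder_ml_velocity_left,
                self.shoulder_ml_velocity_right,
            ]
        )

    @staticmethod
    def channel_names() -> tuple:
        return CHANNEL_COLUMNS

    @property
    def n_samples(self) -> int:
        return len(self.grf_seat)

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time}
        for col, series in zip(CHANNEL_COLUMNS, self._all_series()):
            data[col] = series
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        sampling_rate: float = 100.0,
        target_position: float = 3.0,
    ) -> "TrialRecording":
        missing = [c for c in CHANNEL_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        angles = {
            (j, p): frame[f"{j}_{p}_deg"].to_numpy(float)
            for j in JOINTS
            for p in PLANES
        }
        com = {a: frame[f"com_{a}_m"].to_numpy(float) for a in COM_AXES}
        return cls(
            sampling_rate=sampling_rate,
            angles=angles,
            com_position=com,
            grf_seat=frame["grf_seat_n"].to_numpy(float),
            grf_chairplate=frame["grf_chairplate_n"].to_numpy(float),
            heel_ap_velocity=frame["heel_ap_velocity_m_s"].to_numpy(float),
            shoulder_ml_velocity_left=frame[
                "shoulder_ml_velocity_left_m_s"
            ].to_numpy(float),
            shoulder_ml_velocity_right=frame[
                "shoulder_ml_velocity_right_m_s"
            ].to_numpy(float),
            target_position=target_position,
        )


@dataclass
class Subject:
    """One participant: identifier, disability group and recorded trials."""

    subject_id: str
    group_label: str
    indicators: "DisabilityIndicators"
    trials: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group_label not in ("ND", "D"):
            raise ValueError(f"group_label must be 'ND' or 'D', got {self.group_label!r}")


@dataclass
class CohortDataset:
    """A collection of subjects with unique identifiers."""

    subjects: list

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def group_labels(self) -> pd.Series:
        return pd.Series(
            {s.subject_id: s.group_label for s in self.subjects}, name="group"
        )

    def counts(self) -> dict:
        labels = [s.group_label for s in self.subjects]
        return {"ND": labels.count("ND"), "D": labels.count("D")}


def _parse_metadata(path: Path) -> tuple:
    """Read leading '# key: value' lines; return (metadata, n_comment_lines)."""
    meta = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta, n


def read_trial(path, format: str = "tsv", interpolate_gaps: bool = False) -> TrialRecording:
    """Load a trial recording.

    Parameters
    ----------
    path : path-like
        File to read.
    format : {"tsv"}
        Only the documented TSV format is supported; ``"c3d"`` raises
        ``NotImplementedError`` (angle/CoM channels are expected to be
        precomputed upstream and exported to TSV).
    interpolate_gaps : bool
        If True, fill isolated missing samples by linear interpolation;
        otherwise any gap is rejected.
    """
    path = Path(path)
    if format == "c3d":
        raise NotImplementedError(
            "C3D input is not supported in this build; export channels to the "
            "documented TSV schema instead"
        )
    if format != "tsv":
        raise ValueError(f"unknown trial format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    meta, _ = _parse_metadata(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    for col in frame.columns:
        if frame[col].dtype == object:
            values = frame[col].astype(str)
            if values.str.contains(",").any():
                raise SchemaError(
                    f"column {col!r} contains ',' — the trial TSV dialect requires "
                    "'.' decimal separators"
                )
            raise SchemaError(f"column {col!r} is not numeric")
    if interpolate_gaps:
        frame = frame.interpolate(method="linear", limit_direction="both")
    elif frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise SchemaError(
            f"missing samples in column(s) {bad}; pass interpolate_gaps=True to fill"
        )
    sampling_rate = float(meta.get("sampling_rate_hz", 100.0))
    target_position = float(meta.get("target_position_m", 3.0))
    return TrialRecording.from_frame(
        frame, sampling_rate=sampling_rate, target_position=target_position
    )


def write_trial(recording: TrialRecording, path) -> None:
    """Write a trial in the documented TSV format (round-trips to 1e-9)."""
    path = Path(path)
    frame = recording.to_frame()
    buf = _io.StringIO()
    buf.write(f"# sampling_rate_hz: {recording.sampling_rate!r}\n")
    buf.write(f"# target_position_m: {recording.target_position!r}\n")
    frame.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def load_fixture(name: str) -> pd.DataFrame:
    """Return one of the published summary tables as a DataFrame.

    Known names: ``table1_counts`` (2x2 categorical counts with the printed
    chi-square values), ``table1_summaries`` (group mean/SD/n summaries),
    ``table2_durations`` (phase durations, mean +- SD per group),
    ``table3_loadings`` (rotated loading matrix, 30 parameters x 11
    components; the per-component explained-variance percentages are attached
    as ``df.attrs['explained_variance_pct']``) and ``table4_stats``
    (component-score comparisons).

    The loader is pure: repeated calls return equal frames.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    ref = resources.files("tugpcm.data") / _FIXTURES[name]
    with resources.as_file(ref) as fpath:
        df = pd.read_csv(fpath, sep="\t")
    if name == "table3_loadings":
        ev = df[df["parameter"] == "explained_variance_pct"].iloc[0, 1:].astype(float)
        df = df[df["parameter"] != "explained_variance_pct"].reset_index(drop=True)
        df = df.set_index("parameter").astype(float)
        df.attrs["explained_variance_pct"] = ev.to_numpy()
    return df
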