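"""Rule-based detection of the six TUG events and the five phase windows.

Event definitions:

* **T0 — initiation**: first sample at which the seat-plate vertical GRF
  falls to or below (baseline mean − 2 SD), the baseline being the leading
  window of the trial.
* **T1 — heel-off**: global maximum of the (smoothed) heel-marker
  anteroposterior velocity within a bounded window after T0.
* **T2 — start of turn**: first zero crossing of the smoothed CoM
  mediolateral velocity after T1.
* **T3 — end of turn**: next CoM ML velocity zero crossing at which the CoM
  anteroposterior position is within 0.7 m of the turning target.
* **T4 — gait-to-turn**: the left and right shoulder-marker mediolateral
  velocities equalize (their difference truly crosses zero).
* **T5 — end of movement**: first deflection of the chair-plate vertical
  GRF beyond (baseline mean ± 2 SD) of its own leading baseline.

Velocity channels are smoothed with a zero-phase low-pass Butterworth
filter (4th order, 6 Hz by default — the biomechanics convention; the
filter is configurable).  Zero crossings are sign changes between
consecutive samples, reported at the first sample of the new sign, earliest
index winning all ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .io import PHASES, TrialRecording

__all__ = [
    "EventSet",
    "SegmentationConfig",
    "NoEventError",
    "detect_initiation",
    "detect_heel_off",
    "detect_turn_bounds",
    "detect_gait_to_turn",
    "detect_end",
    "segment_trial",
    "phase_durations",
]


class NoEventError(RuntimeError):
    """A detector found no sample satisfying its event definition."""


@dataclass(frozen=True)
class EventSet:
    """The six event sample indices T0..T5 (strictly increasing)."""

    t0_initiation: int
    t1_heel_off: int
    t2_start_turn: int
    t3_end_turn: int
    t4_gait_to_turn: int
    t5_end: int

    def __post_init__(self) -> None:
        idx = self.as_tuple()
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"event indices must be strictly increasing: {idx}")
        if idx[0] < 0:
            raise ValueError("T0 must be >= 0")

    def as_tuple(self) -> tuple:
        return (
            self.t0_initiation,
            self.t1_heel_off,
            self.t2_start_turn,
            self.t3_end_turn,
            self.t4_gait_to_turn,
            self.t5_end,
        )

    def phase_windows(self) -> dict:
        idx = self.as_tuple()
        return {ph: (idx[k], idx[k + 1]) for k, ph in enumerate(PHASES)}

    def to_dict(self) -> dict:
        return dict(zip(("T0", "T1", "T2", "T3", "T4", "T5"), self.as_tuple()))


@dataclass(frozen=True)
class SegmentationConfig:
    """Detector parameters (defaults follow the published procedure)."""

    baseline_window: float = 0.5  # s, leading plate baseline for T0/T5
    baseline_k: float = 2.0  # SD multiplier of the plate threshold
    turn_distance_threshold: float = 0.7  # m, AP distance gate for T3
    shoulder_equalize_tol: float = 0.02  # m/s
    smoothing_cutoff: float = 6.0  # Hz, zero-phase low-pass on velocities
    smoothing_order: int = 4
    heel_search_window: float = 3.0  # s after T0 for the heel-off maximum
    heel_axis: str = "ap"  # "ap" (body text) or "vertical" (figure caption)

    def __post_init__(self) -> None:
        for name in (
            "baseline_window",
            "baseline_k",
            "turn_distance_threshold",
            "shoulder_equalize_tol",
            "smoothing_cutoff",
            "heel_search_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.smoothing_order < 1:
            raise ValueError("smoothing_order must be >= 1")


def _smooth(series: np.ndarray, fs: float, cfg: SegmentationConfig) -> np.ndarray:
    nyq = fs / 2.0
    if series.size < 3 * (cfg.smoothing_order + 1) or cfg.smoothing_cutoff >= nyq:
        return series
    b, a = butter(cfg.smoothing_order, cfg.smoothing_cutoff / nyq)
    return filtfilt(b, a, series)


def _derivative(series: np.ndarray, fs: float) -> np.ndarray:
    return np.gradient(series) * fs


def _zero_crossings(v: np.ndarray, start: int) -> np.ndarray:
    """Indices i > start where the sign of v changes; exact zeros carry the
    previous sign forward.  Each index is the first sample of the new sign."""
    s = np.sign(v)
    # propagate previous nonzero sign through exact zeros
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    change = np.nonzero(s[1:] * s[:-1] < 0)[0] + 1
    return change[change > start]


def detect_initiation(grf_seat: np.ndarray, cfg: SegmentationConfig,
                      fs: float = 100.0) -> int:
    """T0: first sample with seat GRF <= baseline mean − k·SD."""
    grf_seat = np.asarray(grf_seat, dtype=float)
    nb = int(round(cfg.baseline_window * fs))
    if grf_seat.size <= nb:
        raise NoEventError("seat GRF series shorter than the baseline window")
    base = grf_seat[:nb]
    threshold = base.mean() - cfg.baseline_k * base.std()
    if base.std() > 0:
        below = np.nonzero(grf_seat <= threshold)[0]
    else:
        # degenerate baseline: the threshold equals the mean, so the
        # comparison must be strict or every baseline sample would trigger
        below = np.nonzero(grf_seat < threshold)[0]
    if below.size == 0:
        raise NoEventError("seat GRF never drops below the baseline threshold")
    return int(below[0])


def detect_heel_off(heel_velocity: np.ndarray, after: int,
                    cfg: SegmentationConfig = SegmentationConfig(),
                    fs: float = 100.0) -> int:
    """T1: global maximum of the smoothed heel velocity in a window after T0."""
    heel_velocity = np.asarray(heel_velocity, dtype=float)
    if after >= heel_velocity.size - 1:
        raise NoEventError("no samples after the initiation event")
    stop = min(heel_velocity.size, after + 1 + int(round(cfg.heel_search_window * fs)))
    window = _smooth(heel_velocity, fs, cfg)[after + 1: stop]
    if np.ptp(window) == 0:
        raise NoEventError("heel velocity is flat after initiation")
    return int(after + 1 + np.argmax(window))  # argmax -> earliest tie wins


def detect_turn_bounds(com_ml_velocity: np.ndarray, com_ap_position: np.ndarray,
                       target_position: float, after: int,
                       cfg: SegmentationConfig = SegmentationConfig(),
                       fs: float = 100.0) -> tuple:
    """(T2, T3): CoM ML velocity zero crossings bounding the turn.

    T2 is the first signed zero crossing after ``after``; T3 the next
    crossing at which |AP position − target| <= the distance threshold.
    """
    v = _smooth(np.asarray(com_ml_velocity, dtype=float), fs, cfg)
    ap = np.asarray(com_ap_position, dtype=float)
    crossings = _zero_crossings(v, after)
    if crossings.size == 0:
        raise NoEventError("no CoM ML velocity zero crossing after heel-off")
    t2 = int(crossings[0])
    for c in crossings[1:]:
        if abs(ap[c] - target_position) <= cfg.turn_distance_threshold:
            return t2, int(c)
    raise NoEventError(
        "no second CoM ML velocity zero crossing within "
        f"{cfg.turn_distance_threshold} m of the target"
    )


def detect_gait_to_turn(shoulder_left: np.ndarray, shoulder_right: np.ndarray,
                        after: int, cfg: SegmentationConfig = SegmentationConfig(),
                        fs: float = 100.0) -> int:
    """T4: first sample after ``after`` where the shoulder ML velocities
    equalize — |vL − vR| within tolerance at a true sign crossing."""
    d = _smooth(
        np.asarray(shoulder_left, dtype=float) - np.asarray(shoulder_right, dtype=float),
        fs, cfg,
    )
    n = d.size
    candidates = np.nonzero(np.abs(d) <= cfg.shoulder_equalize_tol)[0]
    candidates = candidates[candidates > after]
    for i in candidates:
        lo, hi = max(0, i - 2), min(n, i + 3)
        signs = np.sign(d[lo:hi])
        signs = signs[signs != 0]
        if signs.size and signs.min() < 0 < signs.max():
            return int(i)
    raise NoEventError("shoulder ML velocities never equalize after the turn")


def detect_end(grf_chairplate: np.ndarray, after: int,
               cfg: SegmentationConfig = SegmentationConfig(),
               fs: float = 100.0) -> int:
    """T5: first chair-plate GRF deflection beyond baseline mean ± k·SD."""
    grf = np.asarray(grf_chairplate, dtype=float)
    nb = int(round(cfg.baseline_window * fs))
    if grf.size <= max(nb, after + 1):
        raise NoEventError("chair-plate series too short")
    base = grf[:nb]
    lo = base.mean() - cfg.baseline_k * base.std()
    hi = base.mean() + cfg.baseline_k * base.std()
    out = np.nonzero((grf < lo) | (grf > hi))[0]
    out = out[out > after]
    if out.size == 0:
        raise NoEventError("chair-plate GRF shows no deflection after the turn")
    return int(out[0])


def segment_trial(recording: TrialRecording,
                  cfg: SegmentationConfig = SegmentationConfig()) -> EventSet:
    """Compose the five detectors in order; each searches after the previous
    event.  Raises :class:`NoEventError` naming the failing phase."""
    fs = recording.sampling_rate

    def _stage(phase, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except NoEventError as exc:
            raise NoEventError(f"{phase}: {exc}") from exc

    t0 = _stage("sit-to-walk", detect_initiation, recording.grf_seat, cfg, fs)
    if cfg.heel_axis != "ap":
        # the event definition exists in two variants; the recorded schema
        # carries the anteroposterior channel only
        raise ValueError(
            "heel_axis='vertical' requires a vertical heel-velocity channel, "
            "which the trial schema does not record"
        )
    t1 = _stage("sit-to-walk", detect_heel_off, recording.heel_ap_velocity, t0, cfg, fs)
    ml_velocity = _derivative(recording.com_position["ml"], fs)
    t2, t3 = _stage(
        "turn", detect_turn_bounds, ml_velocity, recording.com_position["ap"],
        recording.target_position, t1, cfg, fs,
    )
    t4 = _stage(
        "walk-back", detect_gait_to_turn, recording.shoulder_ml_velocity_left,
        recording.shoulder_ml_velocity_right, t3, cfg, fs,
    )
    t5 = _stage("turn-to-sit", detect_end, recording.grf_chairplate, t4, cfg, fs)
    return EventSet(t0, t1, t2, t3, t4, t5)


def phase_durations(events: EventSet, sampling_rate: float = 100.0) -> dict:
    """Durations of the five phases plus the total, in seconds.

    The total is (T5 − T0)/rate, which telescopes to the sum of the parts.
    """
    idx = events.as_tuple()
    out = {
        ph: (idx[k + 1] - idx[k]) / sampling_rate for k, ph in enumerate(PHASES)
    }
    out["total"] = (idx[5] - idx[0]) / sampling_rate
    return out
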