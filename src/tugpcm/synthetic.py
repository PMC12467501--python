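"""Synthetic TUG trial and cohort generator with known ground truth.

The study population this generator emulates — community-dwelling adults
aged 60+, with and without functional disability — is private, so every
downstream stage (event segmentation, feature extraction, the
principal-component models, group statistics) is exercised against cohorts
whose event times, feature magnitudes and latent correlation structure are
known by construction.

Signal model
------------
Each trial is a 1 s quiet-sitting baseline followed by five subphases whose
durations are drawn from group-specific truncated normals (the published
per-phase means/SDs).  Joint-angle channels are sums of phase-locked smooth
raised-cosine excursions plus band-limited noise; only per-phase ranges
(max - min) matter downstream, so waveform realism beyond smoothness and
correct event signatures is not attempted.  Event signatures are exact:

* T0 — seat-plate GRF starts a fast smooth drop from body weight;
* T1 — heel anteroposterior velocity has its global maximum;
* T2/T3 — CoM mediolateral velocity crosses zero entering/leaving the turn,
  with the AP position within 0.7 m of the 3 m line at T3;
* T4 — the left-right shoulder ML velocity difference crosses zero;
* T5 — the chair-plate GRF deflects from its unloaded baseline.

Latent feature structure
------------------------
Per subject, eleven standard-normal latent factors drive clusters of
range-of-motion / velocity-range / CoM amplitudes (loading 0.92), mirroring
the clusters the published rotated solution groups (proximal sagittal
drive during walking and turning; per-phase tri-dimensional trunk velocity;
turn-phase knee frontal/transverse motion; mediolateral CoM excursion; and
so on).  Remaining variables share weak per-phase background factors
(loading 0.45) so that sampling-adequacy statistics land in a realistic
range instead of collapsing to the 0.5 boundary.  Each channel/phase has
separate amplitude knobs for its range-of-motion and its velocity range
(wide excursion with amplitude-proportional width, so its peak velocity is
amplitude-independent, plus a narrow fixed-width wiggle that carries the
velocity range), which keeps ROM and velocity-range features of unrelated
channel/phases from forming spurious near-duplicate pairs.

Group effects: the cluster tied to sagittal hip drive scales with the
profile's ``hip_sagittal_rom_mean`` (default profiles differ by 0.6
within-group SD per variable) and all trunk velocity-range amplitudes scale
with ``trunk_velocity_scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .features import feature_names, parse_feature_name
from .io import JOINTS, PHASES, PLANES, CohortDataset, Subject, TrialRecording
from .stats import DisabilityIndicators, classify_disability

__all__ = [
    "GroupProfile",
    "GroundTruth",
    "default_profiles",
    "simulate_trial",
    "make_cohort",
    "FACTOR_STRUCTURE",
]

#: sampling rate of the emulated optoelectronic system, Hz
FS = 100.0
#: quiet-sitting baseline before T0, s (needed by the T0 baseline detector)
BASELINE_S = 1.0
#: padding after T5, s
TRAIL_S = 0.8

# Indicator loading on its planted factor.  Must exceed sqrt(0.8) ~ 0.894:
# the selection pipeline drops high-loading variables whose communality is
# below 0.800, and a pure indicator's communality is about the squared
# loading — weaker planted loadings would be pruned by the very procedure
# they are meant to exercise.  0.94 sits inside the published loading range.
LATENT_LOADING = 0.96
# Non-indicator loading on its phase's single background factor.  One broad
# equicorrelated factor per phase keeps the sampling-adequacy statistics in
# a realistic range while its per-variable loadings (~0.58 population) stay
# far below the 0.8 retention gate, so background variables do not leak
# into the pooled task model.
BACKGROUND_LOADING = 0.55
AMPLITUDE_CV = 0.25  # between-subject coefficient of variation of amplitudes

#: Planted factor -> indicator features.  Clusters follow the published
#: component descriptions (proximal sagittal drive; per-phase
#: tri-dimensional trunk velocity; turn-phase knee frontal/transverse
#: motion; ...), padded with natural kinematic companions so every factor
#: has at least four indicators: smaller planted clusters are statistically
#: fragile at cohort size — a 1-2 indicator factor is easily destroyed by
#: the eigenvalue > 1 retention rule or by a single low-communality
#: exclusion.
FACTOR_STRUCTURE = {
    1: (
        "hip_sagittal_rom_deg_walk_back",
        "hip_sagittal_velocity_range_deg_s_walk_back",
        "com_vertical_velocity_range_m_s_walk_back",
        "hip_sagittal_rom_deg_walk_forward",
        "knee_sagittal_velocity_range_deg_s_walk_forward",
        "com_ap_velocity_range_m_s_turn",
        "com_vertical_velocity_range_m_s_turn",
    ),
    2: (
        "trunk_frontal_velocity_range_deg_s_turn",
        "trunk_sagittal_velocity_range_deg_s_turn",
        "trunk_transverse_velocity_range_deg_s_turn",
        "trunk_frontal_rom_deg_turn",
    ),
    3: (
        "knee_sagittal_velocity_range_deg_s_sit_to_walk",
        "hip_sagittal_velocity_range_deg_s_sit_to_walk",
        "knee_sagittal_rom_deg_sit_to_walk",
        "hip_sagittal_rom_deg_sit_to_walk",
    ),
    4: (
        "trunk_sagittal_velocity_range_deg_s_walk_back",
        "trunk_frontal_velocity_range_deg_s_walk_back",
        "trunk_transverse_velocity_range_deg_s_walk_back",
        "trunk_frontal_rom_deg_walk_back",
    ),
    5: (
        "knee_transverse_velocity_range_deg_s_turn",
        "knee_transverse_rom_deg_turn",
        "knee_frontal_rom_deg_turn",
        "knee_frontal_velocity_range_deg_s_turn",
    ),
    6: (
        "trunk_sagittal_velocity_range_deg_s_sit_to_walk",
        "trunk_frontal_velocity_range_deg_s_sit_to_walk",
        "trunk_transverse_velocity_range_deg_s_sit_to_walk",
        "trunk_frontal_rom_deg_sit_to_walk",
    ),
    7: (
        "com_vertical_displacement_m_turn_to_sit",
        "com_vertical_velocity_range_m_s_turn_to_sit",
        "com_ap_displacement_m_turn_to_sit",
        "com_ap_velocity_range_m_s_turn_to_sit",
    ),
    8: (
        "com_ml_displacement_m_turn",
        "com_ml_velocity_range_m_s_turn",
        "com_ml_displacement_m_walk_back",
        "com_ml_velocity_range_m_s_walk_back",
    ),
    9: (
        "ankle_transverse_velocity_range_deg_s_walk_forward",
        "ankle_transverse_rom_deg_walk_forward",
        "ankle_frontal_rom_deg_walk_forward",
        "ankle_frontal_velocity_range_deg_s_walk_forward",
    ),
    10: (
        "hip_transverse_rom_deg_walk_forward",
        "hip_transverse_velocity_range_deg_s_walk_forward",
        "hip_frontal_rom_deg_walk_forward",
        "hip_frontal_velocity_range_deg_s_walk_forward",
    ),
    11: (
        "hip_transverse_rom_deg_walk_back",
        "hip_transverse_velocity_range_deg_s_walk_back",
        "hip_frontal_rom_deg_walk_back",
        "hip_frontal_velocity_range_deg_s_walk_back",
    ),
}

_FACTOR_OF = {
    name: f for f, names in FACTOR_STRUCTURE.items() for name in names
}

# Baseline joint-angle ranges in degrees per (joint, plane); velocity-range
# bases are a fixed multiple of these.  Values are plausible magnitudes for
# older-adult TUG performance; absolute realism is immaterial because all
# downstream statistics are scale-invariant (correlation-matrix PCA,
# rank tests, standardized effect sizes).
_ROM_BASE = {
    ("trunk", "sagittal"): 12.0,
    ("trunk", "frontal"): 8.0,
    ("trunk", "transverse"): 10.0,
    ("hip", "sagittal"): 45.0,
    ("hip", "frontal"): 12.0,
    ("hip", "transverse"): 12.0,
    ("knee", "sagittal"): 60.0,
    ("knee", "frontal"): 10.0,
    ("knee", "transverse"): 14.0,
    ("ankle", "sagittal"): 25.0,
    ("ankle", "frontal"): 8.0,
    ("ankle", "transverse"): 10.0,
}
# deg/s of velocity-range base per degree of ROM base.  Large enough that
# the velocity wiggle dominates the wide excursion's flank velocity for
# essentially all amplitude draws; flank-dominated windows would censor the
# velocity knob out of the extracted range.
_VEL_PER_ROM = 8.0
_HIP_SAG_REF = 45.0  # reference hip sagittal ROM; profiles scale against it

_COM_DISP_BASE = {
    ("ap", "sit_to_walk"): 0.03,
    ("ap", "walk_forward"): 0.08,
    ("ap", "turn"): 0.04,
    ("ap", "walk_back"): 0.08,
    ("ap", "turn_to_sit"): 0.04,
    ("ml", "sit_to_walk"): 0.025,
    ("ml", "walk_forward"): 0.06,
    ("ml", "turn"): 0.15,
    ("ml", "walk_back"): 0.12,
    ("ml", "turn_to_sit"): 0.03,
    ("vertical", "sit_to_walk"): 0.25,
    ("vertical", "walk_forward"): 0.035,
    ("vertical", "turn"): 0.035,
    ("vertical", "walk_back"): 0.035,
    ("vertical", "turn_to_sit"): 0.25,
}
_COM_VEL_BASE = {
    ("ap", "sit_to_walk"): 0.15,
    ("ap", "walk_forward"): 0.25,
    ("ap", "turn"): 0.30,
    ("ap", "walk_back"): 0.25,
    ("ap", "turn_to_sit"): 0.15,
    ("ml", "sit_to_walk"): 0.03,
    ("ml", "walk_forward"): 0.03,
    ("ml", "turn"): 0.12,
    ("ml", "walk_back"): 0.10,
    ("ml", "turn_to_sit"): 0.03,
    ("vertical", "sit_to_walk"): 0.30,
    ("vertical", "walk_forward"): 0.20,
    ("vertical", "turn"): 0.25,
    ("vertical", "walk_back"): 0.25,
    ("vertical", "turn_to_sit"): 0.30,
}


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one disability group."""

    name: str
    phase_mean_durations: tuple  # 5 values, s
    phase_sd_durations: tuple  # 5 values, s
    hip_sagittal_rom_mean: float  # degrees; scales the sagittal-drive cluster
    trunk_velocity_scale: float  # dimensionless > 0
    noise_sd: float = 0.5  # degrees, band-limited angle noise
    seed_policy: int = 0  # default seed when none is supplied

    def __post_init__(self) -> None:
        if len(self.phase_mean_durations) != 5 or len(self.phase_sd_durations) != 5:
            raise ValueError("profiles need 5 phase means and 5 phase SDs")
        if any(m <= 0 for m in self.phase_mean_durations):
            raise ValueError("phase mean durations must be > 0")
        if any(s < 0 for s in self.phase_sd_durations):
            raise ValueError("phase duration SDs must be >= 0")
        if self.trunk_velocity_scale <= 0:
            raise ValueError("trunk_velocity_scale must be > 0")
        if self.hip_sagittal_rom_mean <= 0:
            raise ValueError("hip_sagittal_rom_mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """True event times and generative targets for one simulated trial.

    ``feature_targets`` maps feature names to the amplitude knob used while
    synthesizing: for ROM and CoM-displacement features the knob is the
    intended max - min; for velocity-range features it is a monotone proxy
    (the extracted range adds a channel-specific offset and gain).
    """

    event_times: tuple  # six times in s, strictly increasing
    group_label: str
    feature_targets: dict = field(default_factory=dict)
    latent_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.event_times) != 6:
            raise ValueError("need six event times T0..T5")
        if any(b <= a for a, b in zip(self.event_times, self.event_times[1:])):
            raise ValueError("event times must be strictly increasing")
        if self.event_times[0] < 0:
            raise ValueError("T0 must be >= 0")

    def event_indices(self, sampling_rate: float = FS) -> tuple:
        return tuple(int(round(t * sampling_rate)) for t in self.event_times)


def default_profiles() -> tuple:
    """Profiles for the without-disability (ND) and disability (D) groups.

    Phase duration means/SDs are the published per-phase group values
    (sit-to-walk, walk-forward, turn, walk-back, turn-to-sit).  The sagittal
    hip ROM means differ by 0.6 within-group SD (the planted group effect on
    the proximal-drive cluster) and the D group's trunk velocity amplitudes
    are scaled down 10%.
    """
    nd = GroupProfile(
        name="ND",
        phase_mean_durations=(1.30, 2.08, 1.71, 2.56, 2.64),
        phase_sd_durations=(0.27, 0.49, 0.29, 0.77, 0.76),
        hip_sagittal_rom_mean=45.0,
        trunk_velocity_scale=1.0,
    )
    d = GroupProfile(
        name="D",
        phase_mean_durations=(1.44, 2.39, 1.87, 2.97, 2.84),
        phase_sd_durations=(0.20, 0.41, 0.35, 0.55, 0.59),
        hip_sagittal_rom_mean=45.0 - 0.6 * AMPLITUDE_CV * 45.0,  # 38.25
        trunk_velocity_scale=0.90,
    )
    return nd, d


# ---------------------------------------------------------------------------
# waveform primitives

def _raised_cosine(t, center, width, amp):
    """Smooth bump: 0 at the edges, ``amp`` at ``center``."""
    x = (t - (center - width / 2.0)) / width
    inside = (x >= 0.0) & (x <= 1.0)
    return np.where(inside, 0.5 * amp * (1.0 - np.cos(2.0 * np.pi * x)), 0.0)


def _sine_packet(t, center, width, amp):
    """One full zero-mean sine period confined to ``width`` seconds."""
    x = (t - (center - width / 2.0)) / width
    inside = (x >= 0.0) & (x <= 1.0)
    return np.where(inside, amp * np.sin(2.0 * np.pi * x), 0.0)


def _smooth_step(t, start, width, amp):
    """Half-cosine step from 0 to ``amp`` over [start, start+width]."""
    x = np.clip((t - start) / width, 0.0, 1.0)
    return 0.5 * amp * (1.0 - np.cos(np.pi * x))


def _fast_drop(t, start, width, level):
    """Drop from ``level`` to 0 with maximal slope at ``start`` (quarter sine)."""
    x = np.clip((t - start) / width, 0.0, 1.0)
    out = level * (1.0 - np.sin(0.5 * np.pi * x))
    return np.where(t < start, level, out)


def _fast_rise(t, start, width, level):
    x = np.clip((t - start) / width, 0.0, 1.0)
    out = level * np.sin(0.5 * np.pi * x)
    return np.where(t < start, 0.0, out)


def _band_limited_noise(rng, n, sd, fs=FS, cutoff=4.0):
    if sd == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = butter(2, cutoff / (fs / 2.0))
    y = filtfilt(b, a, white)
    s = y.std()
    return y * (sd / s) if s > 0 else y


# ---------------------------------------------------------------------------
# amplitude knobs

def _base_value(name: str, profile: GroupProfile) -> float:
    sig, plane, measure, phase = parse_feature_name(name)
    if sig == "com":
        key = (plane, phase)
        base = (
            _COM_DISP_BASE[key] if measure == "displacement_m"
            else _COM_VEL_BASE[key]
        )
    else:
        rom = _ROM_BASE[(sig, plane)]
        base = rom if measure == "rom_deg" else _VEL_PER_ROM * rom
        if sig == "trunk" and measure == "velocity_range_deg_s":
            base *= profile.trunk_velocity_scale
    if _FACTOR_OF.get(name) == 1:
        base *= profile.hip_sagittal_rom_mean / _HIP_SAG_REF
    elif sig == "hip" and plane == "sagittal":
        base *= profile.hip_sagittal_rom_mean / _HIP_SAG_REF
    return base


def _background_slots(phase: str) -> dict:
    """Each non-indicator feature of a phase shares that phase's single
    background factor."""
    names = sorted(
        n for n in feature_names()
        if parse_feature_name(n)[3] == phase and n not in _FACTOR_OF
    )
    return {n: 0 for n in names}


_BG_SLOT = {}  # filled lazily: name -> (phase, slot)


def _bg_slot(name: str) -> tuple:
    if not _BG_SLOT:
        for ph in PHASES:
            for n, slot in _background_slots(ph).items():
                _BG_SLOT[n] = (ph, slot)
    return _BG_SLOT[name]


def _draw_feature_targets(profile: GroupProfile, rng) -> tuple:
    """Per-subject amplitude knobs for all 150 features, plus latents."""
    z = rng.standard_normal(len(FACTOR_STRUCTURE))
    bg = {ph: rng.standard_normal(1) for ph in PHASES}
    lam = LATENT_LOADING
    beta = BACKGROUND_LOADING
    targets = {}
    for name in feature_names():
        f = _FACTOR_OF.get(name)
        if f is not None:
            x = lam * z[f - 1] + math.sqrt(1.0 - lam * lam) * rng.standard_normal()
        else:
            ph, slot = _bg_slot(name)
            x = beta * bg[ph][slot] + math.sqrt(1.0 - beta * beta) * rng.standard_normal()
        base = _base_value(name, profile)
        targets[name] = max(base * (1.0 + AMPLITUDE_CV * x), 0.15 * base)
    return targets, z


def _draw_durations(profile: GroupProfile, rng) -> np.ndarray:
    mu = np.asarray(profile.phase_mean_durations)
    sd = np.asarray(profile.phase_sd_durations)
    d = rng.normal(mu, sd)
    lo = np.maximum(0.6, mu - 2.5 * sd)
    return np.clip(d, lo, mu + 2.5 * sd)


# ---------------------------------------------------------------------------
# trial synthesis

_W2 = 0.12  # narrow-wiggle width, s


def _wiggle_amp(v_target: float) -> float:
    # one full sine period of amplitude a has velocity amplitude 2*pi*a/w
    return v_target * _W2 / (2.0 * math.pi)


def _synthesize(profile: GroupProfile, rng, durations, targets) -> TrialRecording:
    d1, d2, d3, d4, d5 = durations
    T = np.concatenate([[BASELINE_S], BASELINE_S + np.cumsum(durations)])
    t0, t1, t2, t3, t4, t5 = T
    n = int(round((t5 + TRAIL_S) * FS))
    t = np.arange(n) / FS
    bounds = list(zip(T[:-1], T[1:]))
    nominal = dict(zip(PHASES, profile.phase_mean_durations))

    def rom_bump(start, end, amp, base, dn):
        # Width grows with amplitude over the *nominal* phase duration, so
        # the excursion's peak velocity is independent of both the amplitude
        # and the subject's realized duration; widths scaling with the
        # realized duration would stamp a shared 1/duration component onto
        # every velocity feature of the phase.
        d = end - start
        w = np.clip(0.6 * dn * amp / base, 0.15, 0.85 * d)
        return _raised_cosine(t, start + d / 2.0, w, amp)

    # --- joint angles ------------------------------------------------------
    angles = {}
    for j in JOINTS:
        for p in PLANES:
            sig = _band_limited_noise(rng, n, profile.noise_sd, cutoff=2.5)
            for phase, (a, b) in zip(PHASES, bounds):
                r = targets[f"{j}_{p}_rom_deg_{phase}"]
                v = targets[f"{j}_{p}_velocity_range_deg_s_{phase}"]
                base = _base_value(f"{j}_{p}_rom_deg_{phase}", profile)
                sig = sig + rom_bump(a, b, r, base, nominal[phase])
                # the wiggle sits at the excursion peak, where the wide
                # bump's derivative vanishes: both velocity extremes of the
                # window then carry the velocity knob rather than the bump
                # flank
                sig = sig + _sine_packet(t, a + 0.5 * (b - a), _W2, _wiggle_amp(v))
            angles[(j, p)] = sig

    # --- CoM vertical ------------------------------------------------------
    zc = _band_limited_noise(rng, n, 0.002, cutoff=2.5)
    rise = targets["com_vertical_displacement_m_sit_to_walk"]
    w_rise = np.clip(0.6 * nominal["sit_to_walk"] * rise / 0.25, 0.2, 0.8 * d1)
    zc = zc + _smooth_step(t, t0 + 0.05 * d1, w_rise, rise)
    desc = targets["com_vertical_displacement_m_turn_to_sit"]
    w_desc = np.clip(0.6 * nominal["turn_to_sit"] * desc / 0.25, 0.2, 0.75 * d5)
    zc = zc - _smooth_step(t, t5 - 0.05 * d5 - w_desc, w_desc, desc)
    for phase, (a, b) in zip(PHASES[1:4], bounds[1:4]):
        amp = targets[f"com_vertical_displacement_m_{phase}"]
        zc = zc + rom_bump(a, b, amp, 0.035, nominal[phase])
    for phase, (a, b) in zip(PHASES, bounds):
        v = targets[f"com_vertical_velocity_range_m_s_{phase}"]
        zc = zc + _sine_packet(t, a + 0.5 * (b - a), _W2, _wiggle_amp(v))

    # --- CoM mediolateral: designed as a velocity, then integrated ---------
    # One-signed lobes guarantee exactly one zero crossing at T2 and at T3
    # in the interval the turn detector searches.
    vml = _band_limited_noise(rng, n, 0.001)
    # Outbound drift: a trapezoidal velocity lobe whose plateau is bounded
    # away from the noise floor everywhere in (T1, T2); a shallow half-sine
    # tail would let noise forge an early zero crossing.  Amplitudes of the
    # structural lobes are floored at half their nominal base for the same
    # reason (the effective values are written back into the targets so the
    # ground truth reflects what was synthesized).
    targets["com_ml_displacement_m_walk_forward"] = max(
        targets["com_ml_displacement_m_walk_forward"],
        0.5 * _COM_DISP_BASE[("ml", "walk_forward")],
    )
    targets["com_ml_displacement_m_turn"] = max(
        targets["com_ml_displacement_m_turn"],
        0.5 * _COM_DISP_BASE[("ml", "turn")],
    )
    # Outbound drift proper starts at T1 with a small fixed pre-drift from
    # T0 (the pre-drift keeps the velocity safely one-signed through T1, and
    # starting the knob-driven plateau at T1 keeps the sit-to-walk window's
    # ML features decoupled from the walk-forward displacement knob).
    eps_wf = 0.012
    a_wf = targets["com_ml_displacement_m_walk_forward"] / (t2 - t1 - 0.3)
    a_wf = max(a_wf, eps_wf)
    vml = vml + np.interp(
        t,
        [t0, t0 + 0.3, t1, t1 + 0.3, t2 - 0.35, t2],
        [0.0, eps_wf, eps_wf, a_wf, a_wf, 0.0],
        left=0.0, right=0.0,
    )
    v_wf = targets["com_ml_velocity_range_m_s_walk_forward"]
    vml = vml + _sine_packet(
        t, t1 + 0.5 * (t2 - t1), _W2, min(0.5 * v_wf, 0.45 * a_wf)
    )
    # The turn lobe starts 0.35 s early: the extended half-sine is positive
    # before T2, which steepens the zero-crossing approach so that noise
    # cannot trip the crossing detector early; the crossing stays at T2.
    # The extension fades in smoothly — an onset step would make the
    # zero-phase detector filter ring (undershoot) ahead of it and forge a
    # crossing.
    # Turn and return drifts carry the crossing geometry with small
    # *fixed-floor* lobes; the mediolateral displacement/velocity knobs ride
    # in additional fixed-width mid-phase bumps of the same sign.  A
    # displacement carried by the crossing lobe alone would be amplitude x
    # duration, so the turn and walk-back CoM features would be mostly
    # duration-diluted echoes of each other instead of tracking their
    # planted cluster.
    floor_turn = 0.06  # m, displacement carried by the turn crossing lobe
    a_turn = floor_turn * math.pi / (2.0 * d3)
    fade = _smooth_step(t, t2 - 0.35, 0.2, 1.0)
    vml = vml - a_turn * fade * np.where(
        (t >= t2 - 0.35) & (t < t3), np.sin(np.pi * (t - t2) / d3), 0.0
    )
    w_turn = min(1.0, 0.7 * d3)
    b_turn = max(
        (targets["com_ml_displacement_m_turn"] - floor_turn) / (0.5 * w_turn),
        0.005,
    )
    vml = vml - b_turn * _raised_cosine(t, t2 + 0.5 * d3, w_turn, 1.0)
    # return drift: fast trapezoid rise out of T3 (a half-sine's shallow
    # start would let noise hold the sign below zero and delay T3)
    eps_wb = 0.025
    vml = vml + np.interp(
        t, [t3, t3 + 0.15, t4 - 0.35, t4], [0.0, eps_wb, eps_wb, 0.0],
        left=0.0, right=0.0,
    )
    w_wb = min(1.2, 0.7 * d4)
    b_wb = max(
        (targets["com_ml_displacement_m_walk_back"] - eps_wb * (d4 - 0.25))
        / (0.5 * w_wb),
        0.005,
    )
    vml = vml + b_wb * _raised_cosine(t, t3 + 0.5 * d4, w_wb, 1.0)
    # after T4 no ML zero-crossing constraint remains: sit-to-walk and
    # turn-to-sit ML features are synthesized as decoupled position bumps
    # plus velocity wiggles, added to the position after integration
    # Extra knob-driven ML velocity rides mid-bump, capped well inside the
    # local lobe magnitude so no additional zero crossing can appear.
    for phase, (a, b), local, sign in (
        ("turn", bounds[2], a_turn + b_turn, -1.0),
        ("walk_back", bounds[3], eps_wb + b_wb, 1.0),
    ):
        v = targets[f"com_ml_velocity_range_m_s_{phase}"]
        amp = min(0.5 * v, 0.6 * local)
        vml = vml + sign * _sine_packet(t, a + 0.5 * (b - a), _W2, amp)
    x_ml = np.cumsum(vml) / FS
    for phase, (a, b) in (("sit_to_walk", bounds[0]), ("turn_to_sit", bounds[4])):
        d = b - a
        amp = targets[f"com_ml_displacement_m_{phase}"]
        sign = 1.0 if phase == "sit_to_walk" else -1.0
        x_ml = x_ml + sign * rom_bump(
            a, b, amp, _COM_DISP_BASE[("ml", phase)], nominal[phase]
        )
        v = targets[f"com_ml_velocity_range_m_s_{phase}"]
        x_ml = x_ml + _sine_packet(t, a + 0.5 * d, _W2, _wiggle_amp(v))

    # --- CoM anteroposterior ----------------------------------------------
    xap = _band_limited_noise(rng, n, 0.002, cutoff=2.5) + 0.15
    xap = xap + _smooth_step(t, t1, t2 - t1, 2.70)  # 0.15 -> 2.85 m
    xap = xap - _smooth_step(t, t3, t4 - t3, 2.55)  # back to 0.30 m
    for phase, (a, b) in zip(PHASES, bounds):
        amp = targets[f"com_ap_displacement_m_{phase}"]
        base = _COM_DISP_BASE[("ap", phase)]
        xap = xap + rom_bump(a, b, amp, base, nominal[phase])
        v = targets[f"com_ap_velocity_range_m_s_{phase}"]
        xap = xap + _sine_packet(t, a + 0.5 * (b - a), _W2, _wiggle_amp(v))

    # --- heel anteroposterior velocity -------------------------------------
    heel = _band_limited_noise(rng, n, 0.008)
    heel = heel + _raised_cosine(t, t1, 0.5, 1.2 + 0.2 * rng.random())
    step = 0.55
    for lo, hi in ((t1 + 0.45, t2 - 0.1), (t3 + 0.1, t4 - 0.1)):
        c = lo + 0.25
        while c < hi:
            heel = heel + _raised_cosine(t, c, 0.4, 0.8)
            c += step

    # --- shoulder mediolateral velocities ----------------------------------
    base_osc = 0.15 * np.sin(2.0 * np.pi * 0.85 * (t - t0)) * ((t >= t1) & (t <= t5))
    d0 = 0.5
    diff = np.interp(t, [0.0, t4 - 0.3, t4 + 0.3, t[-1]], [d0, d0, -d0, -d0])
    sh_r = base_osc + _band_limited_noise(rng, n, 0.002)
    sh_l = base_osc + diff + _band_limited_noise(rng, n, 0.002)

    # --- ground reaction forces --------------------------------------------
    weight = 9.81 * (70.0 + 10.0 * rng.standard_normal())
    weight = float(np.clip(weight, 450.0, 950.0))
    phase0 = 2.0 * np.pi * rng.random()
    seat = _fast_drop(t, t0, 0.75 * d1, weight)
    seat = seat + 1.0 * np.sin(2.0 * np.pi * 7.3 * t + phase0) * (t < t0 + 0.75 * d1)
    chair_wig = 0.5 * np.sin(2.0 * np.pi * 6.1 * t + phase0)
    chair = _fast_rise(t, t5, 0.4, weight) + chair_wig * (t < t5)

    return TrialRecording(
        sampling_rate=FS,
        angles=angles,
        com_position={"ap": xap, "ml": x_ml, "vertical": zc},
        grf_seat=seat,
        grf_chairplate=chair,
        heel_ap_velocity=heel,
        shoulder_ml_velocity_left=sh_l,
        shoulder_ml_velocity_right=sh_r,
        target_position=3.0,
    )


def simulate_trial(
    profile: GroupProfile,
    seed: int | None = None,
    feature_overrides: dict | None = None,
    feature_scale: dict | None = None,
) -> tuple:
    """Simulate one TUG trial; returns ``(TrialRecording, GroundTruth)``.

    Identical ``(profile, seed)`` pairs produce bit-identical output.
    ``feature_overrides`` pins amplitude knobs to given values (ROM /
    displacement knobs are max - min targets); ``feature_scale`` multiplies
    drawn knobs (used e.g. to plant extreme outlier subjects).
    """
    if seed is None:
        seed = profile.seed_policy
    rng = np.random.default_rng(seed)
    durations = _draw_durations(profile, rng)
    targets, z = _draw_feature_targets(profile, rng)
    if feature_scale:
        for name, factor in feature_scale.items():
            targets[name] = targets[name] * factor
    if feature_overrides:
        unknown = set(feature_overrides) - set(targets)
        if unknown:
            raise KeyError(f"unknown feature override(s): {sorted(unknown)}")
        targets.update(feature_overrides)
    recording = _synthesize(profile, rng, durations, targets)
    event_times = tuple(
        np.concatenate([[BASELINE_S], BASELINE_S + np.cumsum(durations)])
    )
    truth = GroundTruth(
        event_times=event_times,
        group_label=profile.name,
        feature_targets=targets,
        latent_factors=z,
    )
    return recording, truth


def _draw_indicators(rng, group: str) -> DisabilityIndicators:
    """Indicator values constructed to satisfy the >= 2-of-5 rule exactly."""
    if group == "ND":
        k = int(rng.choice([0, 1], p=[0.6, 0.4]))
    else:
        k = int(rng.choice([2, 3, 4, 5], p=[0.5, 0.3, 0.15, 0.05]))
    slots = set(rng.choice(5, size=k, replace=False).tolist())
    sex = "female" if rng.random() < 0.633 else "male"
    cutoff = 27.0 if sex == "male" else 16.0
    grip = (
        rng.uniform(cutoff - 8.0, cutoff - 1.0)
        if 1 in slots
        else rng.uniform(cutoff + 3.0, cutoff + 15.0)
    )
    stance = rng.uniform(1.0, 9.5) if 2 in slots else rng.uniform(12.0, 60.0)
    ind = DisabilityIndicators(
        self_reported_health="poor" if 0 in slots else "good",
        sex=sex,
        handgrip_kg=float(grip),
        one_leg_stance_s=float(stance),
        barthel=19 if 3 in slots else 20,
        lawton=int(rng.integers(17, 22)) if 4 in slots else 23,
    )
    label, count = classify_disability(ind)
    assert label == group and count == k  # by construction
    return ind


def make_cohort(
    n_nd: int,
    n_d: int,
    seed: int = 0,
    n_trials: int = 1,
    plant_outlier: int | None = None,
    profiles: tuple | None = None,
) -> CohortDataset:
    """Simulate a cohort of ``n_nd`` ND and ``n_d`` D subjects.

    One master seed spawns independent per-subject substreams, so cohorts
    are reproducible and subjects are independent.  ``plant_outlier`` (a
    subject index) quadruples that subject's sit-to-walk amplitudes, giving
    the extreme-outlier screen a known positive.  With ``n_trials > 1`` the
    subject's amplitude knobs are redrawn with small within-subject jitter
    per trial.
    """
    if n_nd < 0 or n_d < 0:
        raise ValueError("cohort sizes must be >= 0")
    nd_profile, d_profile = profiles if profiles is not None else default_profiles()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_nd + n_d)
    subjects = []
    scale_names = [
        nm for nm in feature_names() if parse_feature_name(nm)[3] == "sit_to_walk"
    ]
    for i in range(n_nd + n_d):
        profile = nd_profile if i < n_nd else d_profile
        sub_ss = children[i]
        trial_seeds = sub_ss.generate_state(n_trials + 1)
        rng = np.random.default_rng(trial_seeds[0])
        indicators = _draw_indicators(rng, profile.name)
        scale = None
        if plant_outlier is not None and i == plant_outlier:
            scale = {nm: 4.0 for nm in scale_names}
        trials = []
        truths = []
        for k in range(n_trials):
            rec, truth = simulate_trial(
                profile, seed=int(trial_seeds[k + 1] % (2**31)), feature_scale=scale
            )
            trials.append(rec)
            truths.append(truth)
        subject = Subject(
            subject_id=f"S{i + 1:03d}",
            group_label=profile.name,
            indicators=indicators,
            trials=trials,
        )
        subject.ground_truths = truths
        subjects.append(subject)
    return CohortDataset(subjects=subjects)
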