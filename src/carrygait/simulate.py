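"""Seeded synthetic cohort generator for carrying-gait recordings.

The generator emulates the statistical structure the downstream analysis
relies on, not gait biomechanics per se.  Each joint-angle channel is a
truncated-Fourier waveform (3 harmonics of the stride frequency, fixed
per-channel phases) gated to the walking span between the first and last
heel strike, with quiet standing before and after.  Load-condition effects
are injected directly:

* frontal box carry — large elbow-flexion (and half-size shoulder-flexion)
  postural offset on both arms and near-zero arm-swing amplitude;
* a dumbbell of weight w on side s — arm-swing amplitude on side s scaled
  by ``max(0, 1 - armswing_suppression_per_lb * w)``, with an additional
  per-pound suppression of the wrist channels on that side (the reduced
  wrist-angle variability seen when a hand grips a load);
* asymmetric loads — a trunk lateral-bending offset proportional to the
  signed weight difference, positive lateral bending meaning a lean toward
  the right (the package's fixed sign convention).

EMG is a band-limited (20-450 Hz) Gaussian carrier amplitude-modulated by
one Gaussian burst per heel strike per muscle.  Burst amplitude is
``base + emg_load_gain_per_lb * own_side + emg_contralateral_gain_per_lb *
opposite_side + emg_asymmetry_gain_per_lb * |left - right|`` with the
contralateral term dominating by default, so the muscle opposite a
unilateral load works harder; the last term is a bilateral trunk
stabilization response that grows with load asymmetry, which is what lets
EMG inform the asymmetry-magnitude problems.  The MVC recording is a ~5 s
plateau contraction whose envelope exceeds any carrying trial's by
construction, so normalized trial envelopes lie in [0, 1] up to noise.

Randomness derives from one root seed: ``SeedSequence(seed)`` spawns one
child per participant; each participant's child spawns, in order, the
profile stream, the trial-order shuffle stream, the MVC stream, and one
stream per trial in canonical condition order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as _signal

from .io import (
    EMG_FS,
    KINEMATIC_CHANNELS,
    KINEMATIC_FS,
    EMGRecording,
    KinematicRecording,
    TrialRecord,
)
from .protocol import CarryMode, LoadCondition, enumerate_conditions

__all__ = [
    "GeneratorConfig",
    "ParticipantProfile",
    "Cohort",
    "default_config",
    "no_effect_config",
    "emg_dominant_config",
    "generate_profile",
    "generate_trial",
    "generate_mvc",
    "generate_cohort",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Effect sizes, noise levels and timing for the synthetic cohort.

    Units: degrees for postural effects, fractional amplitude per pound for
    suppression effects, MVC-scale amplitude per pound for EMG gains.
    """

    kinematic_fs: float = KINEMATIC_FS
    emg_fs: float = EMG_FS
    # condition effect sizes
    box_arm_posture_deg: float = 60.0
    box_armswing_residual: float = 0.1
    armswing_suppression_per_lb: float = 0.03
    wrist_variability_suppression: float = 0.02
    trunk_lean_deg_per_lb: float = 0.15
    emg_base_burst: float = 0.2
    emg_load_gain_per_lb: float = 0.012
    emg_contralateral_gain_per_lb: float = 0.03
    emg_asymmetry_gain_per_lb: float = 0.01
    # noise levels
    kinematic_noise_deg: float = 1.0
    emg_noise_level: float = 0.02
    heel_strike_jitter: float = 0.02
    # timing
    standstill_pad_s: float = 2.0
    mvc_duration_s: float = 5.0
    seed: int = 0

    def __post_init__(self):
        for name in ("kinematic_fs", "emg_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GeneratorConfig.{name} must be positive")
        if self.emg_fs <= 900.0:
            raise ValueError("GeneratorConfig.emg_fs must exceed 900 Hz")
        for name in (
            "box_arm_posture_deg",
            "box_armswing_residual",
            "armswing_suppression_per_lb",
            "wrist_variability_suppression",
            "trunk_lean_deg_per_lb",
            "emg_base_burst",
            "emg_load_gain_per_lb",
            "emg_contralateral_gain_per_lb",
            "emg_asymmetry_gain_per_lb",
            "kinematic_noise_deg",
            "emg_noise_level",
            "heel_strike_jitter",
            "standstill_pad_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"GeneratorConfig.{name} must be non-negative")
        if self.mvc_duration_s < 2.0:
            raise ValueError("GeneratorConfig.mvc_duration_s must be at least 2 s")


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions."""
    return GeneratorConfig(seed=seed, **overrides)


def no_effect_config(seed: int = 0) -> GeneratorConfig:
    """All load-condition effects zeroed: trials differ only by noise and
    participant idiosyncrasy, so every classification problem is at chance."""
    return GeneratorConfig(
        seed=seed,
        box_arm_posture_deg=0.0,
        box_armswing_residual=1.0,
        armswing_suppression_per_lb=0.0,
        wrist_variability_suppression=0.0,
        trunk_lean_deg_per_lb=0.0,
        emg_load_gain_per_lb=0.0,
        emg_contralateral_gain_per_lb=0.0,
        emg_asymmetry_gain_per_lb=0.0,
    )


def emg_dominant_config(seed: int = 0) -> GeneratorConfig:
    """Kinematic asymmetry effects weak, EMG load response intact.

    Isolates the EMG contribution to the asymmetry problems: the trunk-lean
    and wrist-suppression effects are removed and arm-swing suppression is
    reduced to a near-threshold level, while the (contralaterally dominant)
    EMG burst gains keep their defaults.
    """
    return GeneratorConfig(
        seed=seed,
        armswing_suppression_per_lb=0.005,
        wrist_variability_suppression=0.0,
        trunk_lean_deg_per_lb=0.0,
    )


@dataclass(frozen=True)
class ParticipantProfile:
    """Participant-level random effects (gait tempo, amplitudes, EMG scale).

    ``joint_gain`` and ``baseline_offset_deg`` are per-channel (66,) arrays,
    drawn per joint and mirrored left/right so that a participant's two sides
    are statistically exchangeable.
    """

    participant_id: str
    stride_period_s: float
    n_steps: int
    joint_gain: np.ndarray
    baseline_offset_deg: np.ndarray
    emg_gain: float
    mvc_max: float

    def __post_init__(self):
        if self.stride_period_s <= 0:
            raise ValueError("stride_period_s must be positive")
        if self.n_steps < 4:
            raise ValueError("n_steps must be at least 4")
        if self.emg_gain <= 0 or self.mvc_max <= 0:
            raise ValueError("emg_gain and mvc_max must be positive")


@dataclass
class Cohort:
    """A generated study dataset: profiles, per-participant trials and MVCs."""

    config: GeneratorConfig
    participants: list
    trials: dict  # participant_id -> list[TrialRecord], in presentation order
    mvc: dict  # participant_id -> EMGRecording

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def iter_trials(self):
        for p in self.participants:
            for record in self.trials[p.participant_id]:
                yield p, record


# ---------------------------------------------------------------------------
# channel parameter tables

_BASE_PARAMS = {  # (amplitude_deg, offset_deg) by joint kind and plane
    "hip": {"flexion/extension": (20, 10), "abduction/adduction": (5, 2), "internal/external rotation": (4, 0)},
    "knee": {"flexion/extension": (30, 20), "abduction/adduction": (3, 0), "internal/external rotation": (5, 2)},
    "ankle": {"flexion/extension": (15, 0), "abduction/adduction": (4, 0), "internal/external rotation": (4, 0)},
    "ball of foot": {"flexion/extension": (12, 5), "abduction/adduction": (3, 0), "internal/external rotation": (3, 0)},
    "shoulder": {"flexion/extension": (12, 3), "abduction/adduction": (4, 5), "internal/external rotation": (5, 0)},
    "T4-shoulder": {"flexion/extension": (4, 0), "abduction/adduction": (3, 2), "internal/external rotation": (3, 0)},
    "elbow": {"flexion/extension": (8, 25), "pronation/supination": (5, 10), "ulnar/radial deviation": (3, 0)},
    "wrist": {"flexion/extension": (8, 0), "pronation/supination": (10, 0), "ulnar/radial deviation": (5, 0)},
    "spine": {"lateral bending": (3, 0), "axial bending": (4, 0), "flexion/extension": (3, 5)},
}

_HARMONIC_AMPS = (1.0, 0.35, 0.12)


def _joint_kind(joint: str) -> str:
    for side in ("right ", "left "):
        if joint.startswith(side):
            return joint[len(side):]
    return "spine"


def _channel_side(channel: str) -> Optional[str]:
    if channel.startswith("right "):
        return "R"
    if channel.startswith("left "):
        return "L"
    return None


def _split(channel: str) -> tuple[str, str]:
    joint, plane = channel.rsplit("|", 1)
    return joint, plane


_CH_KIND = [ _joint_kind(_split(c)[0]) for c in KINEMATIC_CHANNELS ]
_CH_PLANE = [ _split(c)[1] for c in KINEMATIC_CHANNELS ]
_CH_SIDE = [ _channel_side(c) for c in KINEMATIC_CHANNELS ]
_CH_AMP = np.array([_BASE_PARAMS[k][p][0] for k, p in zip(_CH_KIND, _CH_PLANE)], float)
_CH_OFF = np.array([_BASE_PARAMS[k][p][1] for k, p in zip(_CH_KIND, _CH_PLANE)], float)

_ARM_KINDS = ("T4-shoulder", "shoulder", "elbow", "wrist")
_ARM_MASK = {
    s: np.array([k in _ARM_KINDS and sd == s for k, sd in zip(_CH_KIND, _CH_SIDE)])
    for s in ("L", "R")
}
_WRIST_MASK = {
    s: np.array([k == "wrist" and sd == s for k, sd in zip(_CH_KIND, _CH_SIDE)])
    for s in ("L", "R")
}
_ELBOW_FLEX = np.array(
    [k == "elbow" and p == "flexion/extension" for k, p in zip(_CH_KIND, _CH_PLANE)]
)
_SHOULDER_FLEX = np.array(
    [k == "shoulder" and p == "flexion/extension" for k, p in zip(_CH_KIND, _CH_PLANE)]
)
_TRUNK_LATERAL = np.array(
    [k == "spine" and p == "lateral bending" for k, p in zip(_CH_KIND, _CH_PLANE)]
)

# Fixed per-channel fundamental phases (golden-ratio spacing; right side in
# antiphase with left so arm/leg swing alternates).
_GOLDEN = 0.6180339887498949
_CH_PHASE = np.array(
    [
        2 * np.pi * ((i * _GOLDEN) % 1.0) + (np.pi if sd == "R" else 0.0)
        for i, sd in enumerate(_CH_SIDE)
    ]
)


# ---------------------------------------------------------------------------
# generation

def generate_profile(participant_id: str, seed) -> ParticipantProfile:
    """Draw one participant's random effects from a seed/SeedSequence."""
    rng = np.random.default_rng(seed)
    stride = float(rng.normal(1.1, 0.06))
    n_steps = int(rng.integers(10, 15))  # one lab crossing, 10-14 steps
    # per-joint-kind gains/offsets, mirrored onto both sides
    kinds = sorted(set(_CH_KIND))
    kind_gain = {k: float(rng.lognormal(0.0, 0.10)) for k in kinds}
    kind_off = {k: float(rng.normal(0.0, 2.0)) for k in kinds}
    joint_gain = np.array([kind_gain[k] for k in _CH_KIND])
    baseline = np.array([kind_off[k] for k in _CH_KIND])
    emg_gain = float(rng.lognormal(0.0, 0.20))
    return ParticipantProfile(
        participant_id=participant_id,
        stride_period_s=max(stride, 0.7),
        n_steps=n_steps,
        joint_gain=joint_gain,
        baseline_offset_deg=baseline,
        emg_gain=emg_gain,
        mvc_max=2.0,
    )


def _heel_strikes(profile, cfg, rng) -> list:
    half = profile.stride_period_s / 2.0
    t = cfg.standstill_pad_s
    events = []
    side = "L"
    for _ in range(profile.n_steps + 1):
        events.append((t, side))
        side = "R" if side == "L" else "L"
        t += half * (1.0 + cfg.heel_strike_jitter * rng.standard_normal())
    return events


def _condition_channel_params(c: LoadCondition, cfg: GeneratorConfig):
    """Per-channel (amplitude scale, offset shift) injected by a condition."""
    amp_scale = np.ones(66)
    off_shift = np.zeros(66)
    if c.carry_mode is CarryMode.BOX:
        amp_scale[_ARM_MASK["L"] | _ARM_MASK["R"]] *= cfg.box_armswing_residual
        off_shift[_ELBOW_FLEX] += cfg.box_arm_posture_deg
        off_shift[_SHOULDER_FLEX] += cfg.box_arm_posture_deg / 2.0
    elif c.carry_mode is CarryMode.DUMBBELLS:
        for side_key, w in (("L", c.left_lb), ("R", c.right_lb)):
            if w > 0:
                amp_scale[_ARM_MASK[side_key]] *= max(
                    0.0, 1.0 - cfg.armswing_suppression_per_lb * w
                )
                amp_scale[_WRIST_MASK[side_key]] *= max(
                    0.0, 1.0 - cfg.wrist_variability_suppression * w
                )
    # positive lateral bending = lean toward the right
    off_shift[_TRUNK_LATERAL] += cfg.trunk_lean_deg_per_lb * (c.right_lb - c.left_lb)
    return amp_scale, off_shift


def generate_trial(
    profile: ParticipantProfile, c: LoadCondition, cfg: GeneratorConfig, seed
) -> tuple[KinematicRecording, EMGRecording]:
    """Generate one trial's kinematic and EMG recordings."""
    rng = np.random.default_rng(seed)
    events = _heel_strikes(profile, cfg, rng)
    t_first, t_last = events[0][0], events[-1][0]
    duration = t_last + cfg.standstill_pad_s

    # --- kinematics ------------------------------------------------------
    n_kin = int(np.ceil(duration * cfg.kinematic_fs))
    t = np.arange(n_kin) / cfg.kinematic_fs
    amp_scale, off_shift = _condition_channel_params(c, cfg)
    amp = _CH_AMP * profile.joint_gain * amp_scale  # (66,)
    offset = _CH_OFF + profile.baseline_offset_deg + off_shift

    walk = ((t >= t_first) & (t < t_last)).astype(float)  # oscillation gate
    phase = 2 * np.pi * (t[:, None] - t_first) / profile.stride_period_s  # (n, 1)
    wave = np.zeros((n_kin, 66))
    for h, h_amp in enumerate(_HARMONIC_AMPS, start=1):
        wave += h_amp * np.cos(h * phase + h * _CH_PHASE[None, :])
    wave /= sum(_HARMONIC_AMPS)
    data = offset[None, :] + walk[:, None] * wave * amp[None, :]
    if cfg.kinematic_noise_deg > 0:
        data = data + cfg.kinematic_noise_deg * rng.standard_normal(data.shape)
    kin = KinematicRecording(data, events, fs=cfg.kinematic_fs)

    # --- EMG --------------------------------------------------------------
    stabilize = cfg.emg_asymmetry_gain_per_lb * c.asymmetry  # bilateral co-contraction
    burst = {
        "L": cfg.emg_base_burst
        + cfg.emg_load_gain_per_lb * c.left_lb
        + cfg.emg_contralateral_gain_per_lb * c.right_lb
        + stabilize,
        "R": cfg.emg_base_burst
        + cfg.emg_load_gain_per_lb * c.right_lb
        + cfg.emg_contralateral_gain_per_lb * c.left_lb
        + stabilize,
    }
    emg = _generate_emg(
        profile, cfg, rng, duration, burst_times=[e[0] for e in events], burst_amp=burst
    )
    return kin, emg


def _bandlimited_carrier(cfg, rng, n) -> np.ndarray:
    sos = _signal.butter(2, (20.0, 450.0), btype="bandpass", fs=cfg.emg_fs, output="sos")
    carrier = _signal.sosfiltfilt(sos, rng.standard_normal((n, 2)), axis=0)
    return carrier / carrier.std(axis=0)


def _generate_emg(profile, cfg, rng, duration, burst_times, burst_amp, role="trial"):
    n = int(np.ceil(duration * cfg.emg_fs))
    t = np.arange(n) / cfg.emg_fs
    quiet = 0.02
    width = 0.18 * profile.stride_period_s / 2.0
    mod = np.full((n, 2), quiet)
    for m_idx, key in enumerate(("L", "R")):
        for tc in burst_times:
            mod[:, m_idx] += burst_amp[key] * np.exp(-0.5 * ((t - tc) / width) ** 2)
    carrier = _bandlimited_carrier(cfg, rng, n)
    data = profile.emg_gain * mod * carrier
    if cfg.emg_noise_level > 0:
        data = data + cfg.emg_noise_level * rng.standard_normal(data.shape)
    return EMGRecording(data, fs=cfg.emg_fs, role=role)


def generate_mvc(profile: ParticipantProfile, cfg: GeneratorConfig, seed) -> EMGRecording:
    """A ~5 s maximal-contraction recording: plateau at the profile's mvc_max.

    The plateau exceeds any carrying trial's burst amplitude by construction,
    so normalized trial envelopes stay in [0, 1] up to noise.
    """
    rng = np.random.default_rng(seed)
    n = int(np.ceil(cfg.mvc_duration_s * cfg.emg_fs))
    t = np.arange(n) / cfg.emg_fs
    quiet = 0.02
    rise, fall = 0.8, cfg.mvc_duration_s - 0.8
    plateau = np.clip((t - rise) / 0.4, 0.0, 1.0) * np.clip((fall - t) / 0.4, 0.0, 1.0)
    mod = quiet + profile.mvc_max * plateau
    carrier = _bandlimited_carrier(cfg, rng, n)
    data = profile.emg_gain * mod[:, None] * carrier
    if cfg.emg_noise_level > 0:
        data = data + cfg.emg_noise_level * rng.standard_normal(data.shape)
    return EMGRecording(data, fs=cfg.emg_fs, role="mvc")


def generate_cohort(n_participants: int, cfg: GeneratorConfig | None = None) -> Cohort:
    """Generate a full cohort: one trial per condition per participant + MVCs.

    Trial presentation order is shuffled per participant under the seed, as
    in the study protocol.  Identical ``(n_participants, cfg)`` (including
    ``cfg.seed``) yield identical cohorts.
    """
    if cfg is None:
        cfg = default_config()
    if n_participants < 2:
        raise ValueError("n_participants must be at least 2")
    conditions = enumerate_conditions()
    root = np.random.SeedSequence(cfg.seed)
    participants, trials, mvcs = [], {}, {}
    for i, child in enumerate(root.spawn(n_participants)):
        pid = f"P{i + 1:02d}"
        streams = child.spawn(3 + len(conditions))
        profile = generate_profile(pid, streams[0])
        order = np.random.default_rng(streams[1]).permutation(len(conditions))
        mvcs[pid] = generate_mvc(profile, cfg, streams[2])
        per_trial = {}
        for j, cond in enumerate(conditions):
            kin, emg = generate_trial(profile, cond, cfg, streams[3 + j])
            per_trial[cond.condition_id] = TrialRecord(pid, cond.condition_id, kin, emg)
        participants.append(profile)
        trials[pid] = [per_trial[conditions[k].condition_id] for k in order]
    return Cohort(config=cfg, participants=participants, trials=trials, mvc=mvcs)
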