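"""Surface-EMG processing chain and the 10 EMG features.

Chain: linear detrend -> 2nd-order Butterworth 20-450 Hz bandpass ->
rectification (absolute value) -> 2nd-order Butterworth 10 Hz lowpass
(the envelope) -> normalization by the maximum of the participant's
processed MVC envelope, so a trial envelope is a fraction of MVC.

All filters are applied forward-backward (zero phase), the standard choice
for offline EMG; this doubles the effective filter order.  Tiny negative
lowpass undershoots are clipped to zero so envelopes are non-negative.

Features: per muscle, the mean and RMS of the normalized envelope per step,
averaged over all left and all right steps (8 features), plus the median
amplitude of all detected peaks of the unsegmented normalized envelope
(minimum amplitude 10% of MVC, minimum duration 0.2 s measured as the width
at half prominence) for each muscle (2 features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EMGRecording
from .segmentation import StepSegment

logger = logging.getLogger(__name__)

__all__ = [
    "EMG_STEP_FEATURE_NAMES",
    "EMG_PEAK_FEATURE_NAMES",
    "EMG_FEATURE_NAMES",
    "EnvelopeSeries",
    "preprocess_emg",
    "mvc_reference",
    "normalize_envelope",
    "trial_emg_step_features",
    "trial_emg_peak_features",
    "trial_emg_features",
]

_MUSCLES = ("ES_L", "ES_R")  # left/right erector spinae, matching channel order

EMG_STEP_FEATURE_NAMES: tuple = tuple(
    f"{m}|{feat}|{side}"
    for m in _MUSCLES
    for feat in ("mean", "rms")
    for side in ("Lsteps", "Rsteps")
)
EMG_PEAK_FEATURE_NAMES: tuple = tuple(f"{m}|peakmedian" for m in _MUSCLES)
#: The 10 EMG feature names (8 step-based + 2 peak-median).
EMG_FEATURE_NAMES: tuple = EMG_STEP_FEATURE_NAMES + EMG_PEAK_FEATURE_NAMES
assert len(EMG_FEATURE_NAMES) == 10

BANDPASS_HZ = (20.0, 450.0)
LOWPASS_HZ = 10.0
PEAK_MIN_AMPLITUDE = 0.10  # fraction of MVC
PEAK_MIN_DURATION_S = 0.2

# Settling span of the slowest stage (10 Hz lowpass), ~3 time constants.
_SETTLE_S = 0.3


@dataclass
class EnvelopeSeries:
    """Per-muscle EMG envelope; unit is a fraction of MVC once normalized."""

    data: np.ndarray  # (n, 2), non-negative
    fs: float
    t0: float = 0.0
    normalized: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[0]) / self.fs


def _sos(fs: float):
    band = signal.butter(2, BANDPASS_HZ, btype="bandpass", fs=fs, output="sos")
    low = signal.butter(2, LOWPASS_HZ, btype="lowpass", fs=fs, output="sos")
    return band, low


def preprocess_emg(raw: EMGRecording) -> tuple[np.ndarray, EnvelopeSeries]:
    """Detrend, bandpass, rectify and extract the (unnormalized) envelope.

    Returns ``(rectified, envelope)``; both have the input's length.
    """
    n = raw.data.shape[0]
    min_len = int(3 * _SETTLE_S * raw.fs)
    if n < min_len:
        raise ValueError(
            f"EMG channel too short to filter reliably: {n} samples < {min_len} "
            f"(3 x {_SETTLE_S} s settling span)"
        )
    band, low = _sos(raw.fs)
    detrended = signal.detrend(raw.data, axis=0, type="linear")
    filtered = signal.sosfiltfilt(band, detrended, axis=0)
    rectified = np.abs(filtered)
    env = signal.sosfiltfilt(low, rectified, axis=0)
    env = np.clip(env, 0.0, None)  # zero-phase lowpass may undershoot slightly
    return rectified, EnvelopeSeries(env, fs=raw.fs, t0=raw.t0, normalized=False)


def mvc_reference(mvc: EMGRecording) -> np.ndarray:
    """Per-muscle normalization reference: max of the processed MVC envelope."""
    if mvc.role != "mvc":
        raise ValueError("mvc_reference requires a recording with role='mvc'")
    _, env = preprocess_emg(mvc)
    ref = env.data.max(axis=0)
    if np.any(ref <= 0):
        dead = [ch for ch, r in zip(mvc.channel_names, ref) if r <= 0]
        raise ValueError(f"non-positive MVC envelope maximum (dead channel?): {dead}")
    return ref


def normalize_envelope(env: EnvelopeSeries, reference: np.ndarray) -> EnvelopeSeries:
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (2,) or np.any(reference <= 0):
        raise ValueError("reference must be 2 positive per-muscle scalars")
    return EnvelopeSeries(env.data / reference, fs=env.fs, t0=env.t0, normalized=True)


def trial_emg_step_features(
    env: EnvelopeSeries, steps: list[StepSegment]
) -> dict:
    """The 8 step-based features: per muscle x {mean, RMS} x {L, R} steps.

    Each feature is computed per step, then averaged across that side's
    steps.  A side with no steps yields zeros with a warning.
    """
    times = env.times
    per_side: dict[str, list[np.ndarray]] = {"L": [], "R": []}
    for seg in steps:
        mask = (times >= seg.start_s) & (times < seg.end_s)
        window = env.data[mask]
        if window.shape[0] == 0:
            logger.warning("step %s contains no EMG samples; skipped", seg)
            continue
        # rows: per-muscle [mean, rms]
        per_side[seg.side].append(
            np.stack([window.mean(axis=0), np.sqrt((window**2).mean(axis=0))])
        )

    out = {}
    for side_key, side_name in (("L", "Lsteps"), ("R", "Rsteps")):
        if per_side[side_key]:
            agg = np.mean(per_side[side_key], axis=0)  # (2 stats, 2 muscles)
        else:
            logger.warning("no %s steps in trial: EMG features for that side set to 0", side_key)
            agg = np.zeros((2, 2))
        for m_idx, muscle in enumerate(_MUSCLES):
            out[f"{muscle}|mean|{side_name}"] = float(agg[0, m_idx])
            out[f"{muscle}|rms|{side_name}"] = float(agg[1, m_idx])
    return {name: out[name] for name in EMG_STEP_FEATURE_NAMES}


def trial_emg_peak_features(env: EnvelopeSeries) -> dict:
    """Median amplitude of qualifying envelope peaks per muscle (2 features).

    A peak qualifies if its amplitude is at least 10% of MVC and its width
    at half prominence spans at least 0.2 s.  No qualifying peaks -> 0.
    """
    if not env.normalized:
        raise ValueError("peak features require an MVC-normalized envelope")
    out = {}
    min_width = PEAK_MIN_DURATION_S * env.fs
    for m_idx, muscle in enumerate(_MUSCLES):
        x = env.data[:, m_idx]
        peaks, _ = signal.find_peaks(
            x, height=PEAK_MIN_AMPLITUDE, width=min_width, rel_height=0.5
        )
        out[f"{muscle}|peakmedian"] = float(np.median(x[peaks])) if peaks.size else 0.0
    return out


def trial_emg_features(
    emg: EMGRecording | None,
    mvc_ref: np.ndarray | None,
    steps: list[StepSegment],
) -> tuple[dict, bool]:
    """All 10 named EMG features for one trial; zeros + flag if EMG was lost."""
    if emg is None:
        return {name: 0.0 for name in EMG_FEATURE_NAMES}, True
    if mvc_ref is None:
        raise ValueError("an MVC reference is required when EMG is present")
    _, env = preprocess_emg(emg)
    norm = normalize_envelope(env, mvc_ref)
    features = trial_emg_step_features(norm, steps)
    features.update(trial_emg_peak_features(norm))
    return {name: features[name] for name in EMG_FEATURE_NAMES}, False
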