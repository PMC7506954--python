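"""The EMG chain: detrend, bandpass, rectify, envelope, MVC normalization,
step features and peak features."""

import numpy as np
import pytest

from carrygait.emg import (
    EMG_FEATURE_NAMES,
    EnvelopeSeries,
    mvc_reference,
    normalize_envelope,
    preprocess_emg,
    trial_emg_features,
    trial_emg_peak_features,
    trial_emg_step_features,
)
from carrygait.io import EMGRecording
from carrygait.segmentation import StepSegment

FS = 2148.0


def _steady(env, fs=FS):
    """Mean of the middle half of a channel (away from filter transients)."""
    n = env.shape[0]
    return env[n // 4 : 3 * n // 4].mean(axis=0)


def test_dc_is_rejected():
    rec = EMGRecording(np.full((int(10 * FS), 2), 5.0))
    _, env = preprocess_emg(rec)
    assert np.all(_steady(env.data) <= 1e-6 * 5.0)


def test_rectified_sinusoid_envelope_is_two_over_pi():
    t = np.arange(int(10 * FS)) / FS
    x = np.sin(2 * np.pi * 100.0 * t)
    rec = EMGRecording(np.column_stack([x, x]))
    _, env = preprocess_emg(rec)
    np.testing.assert_allclose(_steady(env.data), 2 / np.pi, rtol=0.02)


def test_out_of_band_sinusoid_is_attenuated():
    t = np.arange(int(10 * FS)) / FS
    lo = np.sin(2 * np.pi * 5.0 * t)
    hi = np.sin(2 * np.pi * 100.0 * t)
    _, env = preprocess_emg(EMGRecording(np.column_stack([lo, hi])))
    steady = _steady(env.data)
    assert steady[0] <= 0.1 * steady[1]


def test_too_short_recording_raises():
    with pytest.raises(ValueError, match="too short"):
        preprocess_emg(EMGRecording(np.zeros((100, 2))))


def _burst_recording(amp=(0.8, 0.5), role="trial", rng=None):
    rng = rng or np.random.default_rng(0)
    t = np.arange(int(5 * FS)) / FS
    carrier = rng.standard_normal((t.size, 2))
    gate = ((t > 1.0) & (t < 4.0)).astype(float)
    return EMGRecording(carrier * gate[:, None] * np.array(amp), role=role)


def test_mvc_reference_and_role_check():
    mvc = _burst_recording(role="mvc")
    ref = mvc_reference(mvc)
    assert ref.shape == (2,) and np.all(ref > 0)
    with pytest.raises(ValueError, match="role"):
        mvc_reference(_burst_recording(role="trial"))
    with pytest.raises(ValueError, match="dead channel"):
        mvc_reference(EMGRecording(np.zeros((int(5 * FS), 2)), role="mvc"))


def test_normalization_identity_and_scale_invariance(rng):
    rec = _burst_recording(rng=rng)
    _, env = preprocess_emg(rec)
    ref = env.data.max(axis=0)
    norm = normalize_envelope(env, ref)
    assert norm.data.max(axis=0) == pytest.approx([1.0, 1.0])
    # scaling raw EMG by k scales the envelope by k, normalized features unchanged
    k = 3.7
    scaled = EMGRecording(rec.data * k)
    _, env_k = preprocess_emg(scaled)
    np.testing.assert_allclose(env_k.data, env.data * k, rtol=1e-9, atol=1e-12)
    norm_k = normalize_envelope(env_k, env_k.data.max(axis=0))
    np.testing.assert_allclose(norm_k.data, norm.data, rtol=1e-9, atol=1e-12)
    # an envelope equal everywhere to the reference normalizes to exactly 1
    const = EnvelopeSeries(np.full((1000, 2), 0.8), fs=FS)
    np.testing.assert_array_equal(
        normalize_envelope(const, np.array([0.8, 0.8])).data, 1.0
    )


STEPS = [
    StepSegment(0.0, 0.5, "R"),
    StepSegment(0.5, 1.0, "L"),
    StepSegment(1.0, 1.5, "R"),
    StepSegment(1.5, 2.0, "L"),
]


def test_step_features_constant_envelope():
    env = EnvelopeSeries(np.column_stack([np.full(int(2 * FS), 0.3),
                                          np.full(int(2 * FS), 0.6)]), fs=FS,
                         normalized=True)
    feats = trial_emg_step_features(env, STEPS)
    assert list(feats) == list(EMG_FEATURE_NAMES[:8])
    for side in ("Lsteps", "Rsteps"):
        assert feats[f"ES_L|mean|{side}"] == pytest.approx(0.3)
        assert feats[f"ES_L|rms|{side}"] == pytest.approx(0.3)
        assert feats[f"ES_R|mean|{side}"] == pytest.approx(0.6)
        assert feats[f"ES_R|rms|{side}"] == pytest.approx(0.6)


def test_step_features_match_brute_force(rng):
    env = EnvelopeSeries(np.abs(rng.normal(size=(int(2 * FS), 2))), fs=FS,
                         normalized=True)
    feats = trial_emg_step_features(env, STEPS)
    t = env.times
    for m_idx, muscle in enumerate(("ES_L", "ES_R")):
        for side_key, side in (("L", "Lsteps"), ("R", "Rsteps")):
            means, rmss = [], []
            for s in STEPS:
                if s.side != side_key:
                    continue
                w = env.data[(t >= s.start_s) & (t < s.end_s), m_idx]
                means.append(w.mean())
                rmss.append(np.sqrt(np.mean(w**2)))
            np.testing.assert_allclose(
                feats[f"{muscle}|mean|{side}"], np.mean(means), rtol=1e-12
            )
            np.testing.assert_allclose(
                feats[f"{muscle}|rms|{side}"], np.mean(rmss), rtol=1e-12
            )


def _bump_envelope(centers, heights, widths, dur=12.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    x = np.full(t.size, 0.01)
    for c, h, w in zip(centers, heights, widths):
        sigma = w / 2.355  # FWHM -> sigma
        x = x + h * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return t, x


def test_peak_features_examples():
    flat = EnvelopeSeries(np.full((int(3 * FS), 2), 0.05), fs=FS, normalized=True)
    assert trial_emg_peak_features(flat) == {"ES_L|peakmedian": 0.0,
                                             "ES_R|peakmedian": 0.0}
    # one smooth 0.5-high bump, 0.4 s wide at half height -> one peak
    _, x = _bump_envelope([2.0], [0.5], [0.4])
    env = EnvelopeSeries(np.column_stack([x, x]), fs=FS, normalized=True)
    feats = trial_emg_peak_features(env)
    assert feats["ES_L|peakmedian"] == pytest.approx(0.51, abs=0.02)
    # three qualifying bumps -> median of their heights
    _, x3 = _bump_envelope([2.0, 5.0, 8.0], [0.3, 0.5, 0.4], [0.5, 0.5, 0.5])
    env3 = EnvelopeSeries(np.column_stack([x3, x3]), fs=FS, normalized=True)
    assert trial_emg_peak_features(env3)["ES_L|peakmedian"] == pytest.approx(
        0.41, abs=0.02
    )
    with pytest.raises(ValueError, match="normalized"):
        trial_emg_peak_features(EnvelopeSeries(x3[:, None].repeat(2, 1), fs=FS))


def test_peak_detection_matches_constructed_truth(rng):
    """On random well-separated bumps, the detected qualifying set equals the
    constructed one (heights/widths drawn away from the thresholds)."""
    for _ in range(100):
        n = int(rng.integers(2, 6))
        centers = 2.0 + 3.0 * np.arange(n) + rng.uniform(-0.3, 0.3, n)
        qualifying = rng.random(n) < 0.6
        heights = np.where(qualifying, rng.uniform(0.2, 0.9, n), rng.uniform(0.02, 0.07, n))
        widths = np.where(qualifying, rng.uniform(0.3, 0.8, n), rng.uniform(0.3, 0.8, n))
        _, x = _bump_envelope(centers, heights, widths, dur=3.0 * n + 4.0)
        env = EnvelopeSeries(np.column_stack([x, x]), fs=FS, normalized=True)
        got = trial_emg_peak_features(env)["ES_L|peakmedian"]
        expected = np.median(heights[qualifying]) + 0.01 if qualifying.any() else 0.0
        np.testing.assert_allclose(got, expected, atol=0.03)


def test_trial_emg_features_missing_and_complete(rng):
    feats, flag = trial_emg_features(None, None, STEPS)
    assert flag and set(feats.values()) == {0.0}
    rec = _burst_recording(rng=rng)
    mvc = _burst_recording(amp=(2.0, 2.0), role="mvc", rng=rng)
    feats, flag = trial_emg_features(rec, mvc_reference(mvc), STEPS)
    assert not flag
    assert list(feats) == list(EMG_FEATURE_NAMES)
    assert len(feats) == 10
    assert all(v >= 0 for v in feats.values())
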