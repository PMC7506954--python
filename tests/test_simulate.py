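"""The synthetic cohort generator: structure, determinism and the injected
load-condition effects (postural offsets, arm-swing/wrist suppression,
contralateral EMG loading)."""

import dataclasses

import numpy as np
import pytest

from carrygait.emg import mvc_reference, preprocess_emg
from carrygait.io import KINEMATIC_CHANNELS
from carrygait.protocol import condition_by_id, enumerate_conditions
from carrygait.simulate import (
    GeneratorConfig,
    default_config,
    generate_cohort,
    generate_mvc,
    generate_profile,
    generate_trial,
)

CFG = default_config(seed=5)
PROFILE = generate_profile("P01", 42)
FS_EMG = CFG.emg_fs


def _channel(kin, name):
    return kin.data[:, KINEMATIC_CHANNELS.index(name)]


def _walk_mask(kin):
    t = kin.times
    return (t >= kin.heel_strikes[0][0]) & (t < kin.heel_strikes[-1][0])


def test_config_validation_names_the_field():
    with pytest.raises(ValueError, match="emg_noise_level"):
        GeneratorConfig(emg_noise_level=-0.1)
    with pytest.raises(ValueError, match="emg_fs"):
        GeneratorConfig(emg_fs=500.0)


def test_trial_structure():
    kin, emg = generate_trial(PROFILE, condition_by_id("none"), CFG, 7)
    assert kin.data.shape[1] == 66 and not np.isnan(kin.data).any()
    assert emg.data.shape[1] == 2 and not np.isnan(emg.data).any()
    events = kin.heel_strikes
    assert len(events) == PROFILE.n_steps + 1
    times = [t for t, _ in events]
    assert all(b > a for a, b in zip(times, times[1:]))
    sides = [s for _, s in events]
    assert all(a != b for a, b in zip(sides, sides[1:]))
    # standstill padding before the first and after the last heel strike
    assert times[0] == pytest.approx(CFG.standstill_pad_s)
    assert kin.duration_s >= times[-1] + CFG.standstill_pad_s - 1 / kin.fs


def test_seeded_determinism():
    a_kin, a_emg = generate_trial(PROFILE, condition_by_id("db_5_25"), CFG, 7)
    b_kin, b_emg = generate_trial(PROFILE, condition_by_id("db_5_25"), CFG, 7)
    np.testing.assert_array_equal(a_kin.data, b_kin.data)
    np.testing.assert_array_equal(a_emg.data, b_emg.data)
    assert a_kin.heel_strikes == b_kin.heel_strikes


def test_zero_noise_waveform_is_seed_independent():
    quiet = dataclasses.replace(
        CFG, kinematic_noise_deg=0.0, heel_strike_jitter=0.0
    )
    a, _ = generate_trial(PROFILE, condition_by_id("box_15_15"), quiet, 1)
    b, _ = generate_trial(PROFILE, condition_by_id("box_15_15"), quiet, 999)
    np.testing.assert_array_equal(a.data, b.data)


def test_box_raises_elbow_flexion_and_kills_arm_swing():
    kin_box, _ = generate_trial(PROFILE, condition_by_id("box_15_15"), CFG, 7)
    kin_none, _ = generate_trial(PROFILE, condition_by_id("none"), CFG, 8)
    for side in ("left", "right"):
        ch = f"{side} elbow|flexion/extension"
        lift = _channel(kin_box, ch).mean() - _channel(kin_none, ch).mean()
        assert lift >= CFG.box_arm_posture_deg / 2
        swing = f"{side} shoulder|flexion/extension"
        assert (
            _channel(kin_box, swing)[_walk_mask(kin_box)].var()
            < 0.5 * _channel(kin_none, swing)[_walk_mask(kin_none)].var()
        )


def test_dumbbell_suppresses_same_side_wrist_variability():
    kin, _ = generate_trial(PROFILE, condition_by_id("db_25_0"), CFG, 7)
    walk = _walk_mask(kin)
    left = _channel(kin, "left wrist|pronation/supination")[walk].var()
    right = _channel(kin, "right wrist|pronation/supination")[walk].var()
    assert left < right


def test_wrist_suppression_is_monotone_in_weight():
    prev = np.inf
    for cid in ("none", "db_5_0", "db_15_0", "db_25_0"):
        kin, _ = generate_trial(PROFILE, condition_by_id(cid), CFG, 7)
        v = _channel(kin, "left wrist|pronation/supination")[_walk_mask(kin)].var()
        assert v <= prev * 1.05  # weakly decreasing up to noise
        prev = v


def test_contralateral_emg_dominates():
    _, emg = generate_trial(PROFILE, condition_by_id("db_0_25"), CFG, 7)
    _, env = preprocess_emg(emg)
    left, right = env.data.mean(axis=0)
    assert left > right  # dumbbell on the right loads the left erector spinae
    # and the opposite carry mirrors it
    _, emg2 = generate_trial(PROFILE, condition_by_id("db_25_0"), CFG, 7)
    _, env2 = preprocess_emg(emg2)
    left2, right2 = env2.data.mean(axis=0)
    assert right2 > left2


def test_mirror_symmetry_of_channel_statistics():
    quiet = dataclasses.replace(
        CFG, kinematic_noise_deg=0.0, heel_strike_jitter=0.0
    )
    a, _ = generate_trial(PROFILE, condition_by_id("db_5_25"), quiet, 1)
    b, _ = generate_trial(PROFILE, condition_by_id("db_25_5"), quiet, 1)
    walk = _walk_mask(a)
    for ch in ("wrist|pronation/supination", "shoulder|flexion/extension"):
        # left/right channels carry different fixed phases, so variances over
        # a non-integer number of gait cycles match only approximately
        np.testing.assert_allclose(
            _channel(a, f"left {ch}")[walk].var(),
            _channel(b, f"right {ch}")[walk].var(),
            rtol=0.1,
        )
    # trunk lean flips sign when the heavy side flips; the common gait
    # waveform cancels in the difference between the two mirrored trials
    lat_a = _channel(a, "L4-L3|lateral bending").mean()
    lat_b = _channel(b, "L4-L3|lateral bending").mean()
    expected_diff = 2 * CFG.trunk_lean_deg_per_lb * (25 - 5)
    np.testing.assert_allclose(lat_a - lat_b, expected_diff, atol=1e-6)


def test_mvc_dominates_every_trial_envelope():
    mvc = generate_mvc(PROFILE, CFG, 3)
    assert mvc.duration_s == pytest.approx(CFG.mvc_duration_s, abs=0.01)
    ref = mvc_reference(mvc)
    heaviest = condition_by_id("db_25_25")
    _, emg = generate_trial(PROFILE, heaviest, CFG, 7)
    _, env = preprocess_emg(emg)
    assert np.all(env.data.max(axis=0) < ref)


def test_mvc_envelope_matches_configured_plateau():
    quiet = dataclasses.replace(CFG, emg_noise_level=0.0)
    mvc = generate_mvc(PROFILE, quiet, 3)
    _, env = preprocess_emg(mvc)
    # numeric oracle for the plateau level: a unit-std band-limited Gaussian
    # carrier re-filtered by the processing bandpass and rectified has mean
    # |x| slightly below sqrt(2/pi) (band edges are trimmed twice)
    from scipy import signal as sig

    sos = sig.butter(2, (20.0, 450.0), btype="bandpass", fs=FS_EMG, output="sos")
    white = np.random.default_rng(777).standard_normal(int(30 * FS_EMG))
    carrier = sig.sosfiltfilt(sos, white)
    carrier /= carrier.std()
    factor = np.abs(sig.sosfiltfilt(sos, carrier)).mean()
    t = env.times
    plateau = env.data[(t > 1.5) & (t < 3.5)].mean(axis=0)
    expected = factor * PROFILE.emg_gain * PROFILE.mvc_max
    np.testing.assert_allclose(plateau, expected, rtol=0.05)


def test_cohort_shape_and_determinism():
    cohort = generate_cohort(2, default_config(seed=11))
    assert cohort.n_participants == 2
    cond_ids = {c.condition_id for c in enumerate_conditions()}
    for p in cohort.participants:
        trials = cohort.trials[p.participant_id]
        assert len(trials) == 19
        assert {t.condition_id for t in trials} == cond_ids
        assert p.participant_id in cohort.mvc
    again = generate_cohort(2, default_config(seed=11))
    for p in cohort.participants:
        for t1, t2 in zip(cohort.trials[p.participant_id], again.trials[p.participant_id]):
            assert t1.condition_id == t2.condition_id
            np.testing.assert_array_equal(t1.kinematics.data, t2.kinematics.data)
    # different participants see different trial orders (seeded shuffles)
    orders = [
        tuple(t.condition_id for t in cohort.trials[p.participant_id])
        for p in cohort.participants
    ]
    assert len(set(orders)) == len(orders)
    with pytest.raises(ValueError, match="at least 2"):
        generate_cohort(1, default_config())
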