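"""Assembly of the per-trial feature matrix from raw recordings.

One row per trial: participant/condition metadata, the 528 inertial
features, the 10 EMG features and the two missing-sensor flags — 538 named
feature columns in the canonical order expected by selection and
classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emg import EMG_FEATURE_NAMES, mvc_reference, trial_emg_features
from .inertial import INERTIAL_FEATURE_NAMES, trial_inertial_features
from .io import EMGRecording, TrialRecord
from .segmentation import segment_steps
from .simulate import Cohort

__all__ = [
    "ALL_FEATURE_NAMES",
    "METADATA_COLUMNS",
    "extract_trial_features",
    "build_feature_table",
    "feature_set_columns",
]

#: All 538 feature names: inertial first, then EMG.
ALL_FEATURE_NAMES: tuple = INERTIAL_FEATURE_NAMES + EMG_FEATURE_NAMES
METADATA_COLUMNS = ("participant_id", "condition_id", "missing_inertial", "missing_emg")


def extract_trial_features(record: TrialRecord, mvc_ref: np.ndarray | None) -> dict:
    """One trial -> a row dict of metadata plus all 538 features.

    Step windows come from the kinematic heel-strike stream; when the
    kinematic stream was lost there are no step windows, so the step-based
    EMG features fall back to zeros while the peak features (computed on the
    unsegmented envelope) are still available.
    """
    steps = []
    if record.kinematics is not None and len(record.kinematics.heel_strikes) >= 2:
        steps = segment_steps(record.kinematics.heel_strikes)
    inertial, missing_inertial = trial_inertial_features(record.kinematics, steps)
    emg, missing_emg = trial_emg_features(record.emg, mvc_ref, steps)
    row = {
        "participant_id": record.participant_id,
        "condition_id": record.condition_id,
        "missing_inertial": missing_inertial,
        "missing_emg": missing_emg,
    }
    row.update(inertial)
    row.update(emg)
    return row


def build_feature_table(cohort: Cohort) -> pd.DataFrame:
    """Feature rows for every trial of a cohort, MVC-normalized per participant."""
    refs = {pid: mvc_reference(rec) for pid, rec in cohort.mvc.items()}
    rows = [
        extract_trial_features(record, refs.get(record.participant_id))
        for _, record in cohort.iter_trials()
    ]
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(ALL_FEATURE_NAMES))


def feature_set_columns(feature_set: str) -> tuple:
    """Column names for one of the three input feature sets."""
    if feature_set == "inertial":
        return INERTIAL_FEATURE_NAMES
    if feature_set == "emg":
        return EMG_FEATURE_NAMES
    if feature_set == "both":
        return ALL_FEATURE_NAMES
    raise ValueError(f"unknown feature set: {feature_set!r} (inertial|emg|both)")
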