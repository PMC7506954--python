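"""Per-step inertial (joint-angle) features.

For every one of the 66 joint-angle channels, four moments are computed per
step — mean and variance of the raw signal and of its absolute value — then
averaged separately over all left steps and all right steps, giving
66 x 4 x 2 = 528 features per trial (264 per-step values per step).

Variance uses the sample (n-1) denominator; a single-sample step window
returns variance 0 with a logged warning.  A trial whose kinematic stream
was lost yields all-zero features with ``missing_inertial`` set, mirroring
the zero-fill convention for lost sensor systems.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import KINEMATIC_CHANNELS, KinematicRecording
from .segmentation import StepSegment

logger = logging.getLogger(__name__)

__all__ = [
    "MOMENTS",
    "SIDES",
    "INERTIAL_FEATURE_NAMES",
    "step_moments",
    "trial_inertial_features",
]

MOMENTS = ("raw|mean", "raw|var", "abs|mean", "abs|var")
SIDES = ("Lsteps", "Rsteps")

#: Canonical names of the 528 inertial features:
#: ``<joint>|<plane>|<raw|abs>|<mean|var>|<Lsteps|Rsteps>``.
INERTIAL_FEATURE_NAMES: tuple = tuple(
    f"{channel}|{moment}|{side}"
    for channel in KINEMATIC_CHANNELS
    for moment in MOMENTS
    for side in SIDES
)
assert len(INERTIAL_FEATURE_NAMES) == 66 * 4 * 2


def step_moments(window) -> tuple:
    """(mean, var, mean_abs, var_abs) of one scalar step window.

    Variance uses the (n-1) denominator; n = 1 returns variance 0 with a
    warning rather than NaN.
    """
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty step window")
    if x.size == 1:
        logger.warning("single-sample step window: variance set to 0")
        return float(x[0]), 0.0, float(abs(x[0])), 0.0
    a = np.abs(x)
    return (
        float(x.mean()),
        float(x.var(ddof=1)),
        float(a.mean()),
        float(a.var(ddof=1)),
    )


def _window_moments(data: np.ndarray) -> np.ndarray:
    """Stacked (4, n_channels) moments of one step window, all channels at once."""
    n = data.shape[0]
    ddof = 1 if n > 1 else 0
    if n == 1:
        logger.warning("single-sample step window: variance set to 0")
    a = np.abs(data)
    return np.stack(
        [data.mean(axis=0), data.var(axis=0, ddof=ddof), a.mean(axis=0), a.var(axis=0, ddof=ddof)]
    )


def trial_inertial_features(
    kinematics: KinematicRecording | None, steps: list[StepSegment]
) -> tuple[dict, bool]:
    """Compute the 528 named inertial features for one trial.

    Returns ``(features, missing_inertial)``.  ``features`` maps every name
    in :data:`INERTIAL_FEATURE_NAMES` to a float.  If ``kinematics`` is None
    (lost sensor system) all features are 0.0 and the flag is True.  A side
    with zero steps gets zeros for its features with a logged warning.
    """
    if kinematics is None:
        return {name: 0.0 for name in INERTIAL_FEATURE_NAMES}, True

    times = kinematics.times
    # per-side list of (4, 66) per-step moment arrays
    by_side: dict[str, list[np.ndarray]] = {"L": [], "R": []}
    for seg in steps:
        mask = (times >= seg.start_s) & (times < seg.end_s)
        window = kinematics.data[mask]
        if window.shape[0] == 0:
            logger.warning("step %s contains no kinematic samples; skipped", seg)
            continue
        by_side[seg.side].append(_window_moments(window))

    values = np.zeros((66, 4, 2))
    for side_idx, side in enumerate(("L", "R")):
        if not by_side[side]:
            logger.warning("no %s steps in trial: that side's features set to 0", side)
            continue
        mean_over_steps = np.mean(by_side[side], axis=0)  # (4, 66)
        values[:, :, side_idx] = mean_over_steps.T

    features = {}
    i = 0
    for ch in range(66):
        for m in range(4):
            for s in range(2):
                features[INERTIAL_FEATURE_NAMES[i]] = float(values[ch, m, s])
                i += 1
    return features, False
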