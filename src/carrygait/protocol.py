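"""Load-carriage study protocol: the 19 load conditions and five classification problems.

The study protocol has each participant walk one lab crossing per condition:

* one control trial without any load,
* three trials with a 30-lb box held in front of the body (symmetrically
  loaded, left-heavy 25/5, right-heavy 5/25),
* fifteen dumbbell trials: one dumbbell (5/15/25 lb, left or right hand),
  three symmetric pairs, and six asymmetric pairs.

Five supervised classification problems are defined over these conditions:

P1  box vs. no box (all 19 conditions),
P2  box vs. 1 dumbbell vs. 2 dumbbells (no-load trial skipped),
P3  symmetric vs. <20 lb vs. >=20 lb left-right difference (box trials skipped),
P4  symmetric vs. <=10 lb vs. >10 lb left-right difference (box trials skipped),
P5  symmetric vs. heavier left vs. heavier right (box trials skipped).

Class labels are coded 1..K in the listing order above, which is the coding
the regression-rounded classifier consumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "CarryMode",
    "LoadCondition",
    "ProblemDefinition",
    "SKIP",
    "PROBLEMS",
    "enumerate_conditions",
    "condition_by_id",
    "label_condition",
    "class_code",
    "class_counts",
    "conditions_to_json",
    "conditions_from_json",
]

#: Sentinel returned by :func:`label_condition` for conditions excluded
#: from a classification problem.
SKIP = "SKIP"

SCHEMA_VERSION = 1


class CarryMode(str, Enum):
    NONE = "none"
    BOX = "box"
    DUMBBELLS = "dumbbells"


@dataclass(frozen=True)
class LoadCondition:
    """One of the 19 carried-load configurations.

    ``left_lb``/``right_lb`` are the weights in pounds carried on (or, for a
    box, loaded into) the left and right side; 0 means nothing on that side.
    """

    condition_id: str
    carry_mode: CarryMode
    left_lb: int
    right_lb: int

    @property
    def asymmetry(self) -> int:
        """Absolute left-right weight difference in pounds."""
        return abs(self.left_lb - self.right_lb)

    @property
    def total_lb(self) -> int:
        return self.left_lb + self.right_lb

    @property
    def n_dumbbells(self) -> int:
        if self.carry_mode is not CarryMode.DUMBBELLS:
            return 0
        return int(self.left_lb > 0) + int(self.right_lb > 0)


@dataclass(frozen=True)
class ProblemDefinition:
    """One classification problem: ordered class labels over the conditions."""

    problem_id: str
    class_labels: tuple
    description: str

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)


PROBLEMS: dict[str, ProblemDefinition] = {
    "P1": ProblemDefinition(
        "P1",
        ("box", "no box"),
        "box vs. no box (dumbbells or no load); all conditions used",
    ),
    "P2": ProblemDefinition(
        "P2",
        ("box", "1 dumbbell", "2 dumbbells"),
        "box vs. one dumbbell vs. two dumbbells; no-load condition skipped",
    ),
    "P3": ProblemDefinition(
        "P3",
        ("symmetric", "<20 lb difference", ">=20 lb difference"),
        "load asymmetry with a 20 lb threshold; box conditions skipped",
    ),
    "P4": ProblemDefinition(
        "P4",
        ("symmetric", "<=10 lb difference", ">10 lb difference"),
        "load asymmetry with a 10 lb threshold; box conditions skipped",
    ),
    "P5": ProblemDefinition(
        "P5",
        ("symmetric", "heavier left", "heavier right"),
        "side of the heavier load; box conditions skipped",
    ),
}

_DUMBBELL_WEIGHTS = (0, 5, 15, 25)


def enumerate_conditions() -> list[LoadCondition]:
    """Return the 19 load conditions in canonical order.

    Canonical order (fixed for reproducibility; the study randomized trial
    order per participant, which the simulator reproduces under a seed):
    the no-load condition; the three box conditions (symmetric, left-heavy,
    right-heavy); the fifteen dumbbell conditions sorted lexicographically
    by ``(left_lb, right_lb)``.
    """
    conditions = [LoadCondition("none", CarryMode.NONE, 0, 0)]
    for left, right in ((15, 15), (25, 5), (5, 25)):
        conditions.append(
            LoadCondition(f"box_{left}_{right}", CarryMode.BOX, left, right)
        )
    for left in _DUMBBELL_WEIGHTS:
        for right in _DUMBBELL_WEIGHTS:
            if left == 0 and right == 0:
                continue
            conditions.append(
                LoadCondition(f"db_{left}_{right}", CarryMode.DUMBBELLS, left, right)
            )
    assert len(conditions) == 19
    return conditions


_BY_ID = {c.condition_id: c for c in enumerate_conditions()}


def condition_by_id(condition_id: str) -> LoadCondition:
    try:
        return _BY_ID[condition_id]
    except KeyError:
        raise KeyError(f"unknown condition_id: {condition_id!r}") from None


def label_condition(c: LoadCondition, p: ProblemDefinition | str) -> str:
    """Map a condition to its class label under a problem, or to ``SKIP``.

    The mapping is total and deterministic over the 19 x 5 grid.  The no-load
    condition counts as a symmetric load in P3-P5 and as "no box" in P1; box
    conditions are skipped in P3-P5 and the no-load condition in P2.
    """
    if isinstance(p, str):
        p = PROBLEMS[p]
    if c.condition_id not in _BY_ID:
        raise ValueError(f"unknown condition: {c!r}")
    pid = p.problem_id
    box = c.carry_mode is CarryMode.BOX
    if pid == "P1":
        return "box" if box else "no box"
    if pid == "P2":
        if c.carry_mode is CarryMode.NONE:
            return SKIP
        if box:
            return "box"
        return "1 dumbbell" if c.n_dumbbells == 1 else "2 dumbbells"
    if pid not in ("P3", "P4", "P5"):
        raise ValueError(f"unknown problem: {p!r}")
    if box:
        return SKIP
    a = c.asymmetry
    if pid == "P3":
        if a == 0:
            return "symmetric"
        return "<20 lb difference" if a < 20 else ">=20 lb difference"
    if pid == "P4":
        if a == 0:
            return "symmetric"
        return "<=10 lb difference" if a <= 10 else ">10 lb difference"
    # P5
    if a == 0:
        return "symmetric"
    return "heavier left" if c.left_lb > c.right_lb else "heavier right"


def class_code(c: LoadCondition, p: ProblemDefinition | str) -> Optional[int]:
    """Integer class code 1..K for a condition under a problem; None if skipped."""
    if isinstance(p, str):
        p = PROBLEMS[p]
    label = label_condition(c, p)
    if label == SKIP:
        return None
    return p.class_labels.index(label) + 1


def class_counts(p: ProblemDefinition | str) -> dict[str, int]:
    """Number of conditions per class (one trial per condition per participant).

    Note: the protocol enumeration yields 9 two-dumbbell conditions (3
    symmetric + 6 asymmetric pairs), so P2 counts are (3, 6, 9).
    """
    if isinstance(p, str):
        p = PROBLEMS[p]
    counts = {label: 0 for label in p.class_labels}
    for c in enumerate_conditions():
        label = label_condition(c, p)
        if label != SKIP:
            counts[label] += 1
    return counts


def conditions_to_json(conditions: list[LoadCondition] | None = None) -> str:
    """Serialize conditions (default: the canonical 19) to a JSON document."""
    if conditions is None:
        conditions = enumerate_conditions()
    doc = {
        "schema": "carrygait.conditions",
        "version": SCHEMA_VERSION,
        "conditions": [
            {**asdict(c), "carry_mode": c.carry_mode.value} for c in conditions
        ],
    }
    return json.dumps(doc, indent=1)


def conditions_from_json(text: str) -> list[LoadCondition]:
    doc = json.loads(text)
    if doc.get("schema") != "carrygait.conditions":
        raise ValueError("not a carrygait conditions document")
    return [
        LoadCondition(
            d["condition_id"], CarryMode(d["carry_mode"]), d["left_lb"], d["right_lb"]
        )
        for d in doc["conditions"]
    ]
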