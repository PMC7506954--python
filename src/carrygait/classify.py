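"""Classifiers, leave-participant-out cross-validation, and result reports.

Four classifiers operate on integer class codes 1..K:

REG  ordinary least squares on the numeric class code; the continuous
     prediction is rounded half-up to the nearest code and clipped to
     [1, K] (authored here — rank-deficient designs fall back to the
     minimum-norm solution with a warning);
LDA  linear discriminant analysis;
SVM  linear-kernel support vector machine, C = 1, one-vs-one for K > 2;
EDT  ensemble decision tree: bagging of 100 depth-unlimited trees with a
     fixed seed.

Features are z-scored by training-fold statistics before LDA/SVM/REG
(zero-variance columns, e.g. zero-filled missing-sensor features, are left
unscaled).  The experiment object follows the model/results idiom:
``LopoExperiment(...).fit()`` returns a :class:`CVResult` carrying per-fold
accuracies, the pooled confusion matrix, the selection record and a
``summary()`` table.

Feature selection scope: ``selection_mode="pooled"`` (default) selects once
on the full dataset before cross-validation, reproducing the source
protocol's single per-problem feature count; ``"per-fold"`` reselects inside
each training fold and is the leakage-free alternative.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .pipeline import feature_set_columns
from .protocol import PROBLEMS, ProblemDefinition, class_code, condition_by_id
from .selection import SelectionResult, adaptive_select

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIERS",
    "FEATURE_SETS",
    "train_reg",
    "predict_reg",
    "train_classifier",
    "predict",
    "CVResult",
    "LopoExperiment",
    "lopo_cv",
    "report",
]

CLASSIFIERS = ("LDA", "EDT", "SVM", "REG")
FEATURE_SETS = ("inertial", "emg", "both")

#: Table-style reporting convention: classifier shown per feature set.
REPORT_CLASSIFIER = {"inertial": "REG", "emg": "SVM", "both": "REG"}


# ---------------------------------------------------------------------------
# classifiers

@dataclass
class RegModel:
    coef: np.ndarray  # (p + 1,), intercept first
    n_classes: int


def train_reg(X: np.ndarray, y_codes: np.ndarray) -> RegModel:
    """Multiple linear regression of the class code on the features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_codes, dtype=float)
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient regression design; using the minimum-norm solution",
            stacklevel=2,
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return RegModel(coef=coef, n_classes=int(np.max(y_codes)))


def predict_reg(model: RegModel, X: np.ndarray) -> np.ndarray:
    """Round the continuous output half-up to the closest class code."""
    X = np.asarray(X, dtype=float)
    cont = np.column_stack([np.ones(X.shape[0]), X]) @ model.coef
    return np.clip(np.floor(cont + 0.5).astype(int), 1, model.n_classes)


class _ZScorer:
    """Train-statistics z-scoring; zero-variance columns pass through."""

    def fit(self, X: np.ndarray) -> "_ZScorer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.keep_ = sd > 0
        self.scale_ = np.where(self.keep_, sd, 1.0)
        # zero-variance columns (e.g. zero-filled missing sensors) stay put
        self.mean_ = np.where(self.keep_, self.mean_, 0.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


def train_classifier(name: str, X: np.ndarray, y_codes: np.ndarray, seed: int = 0):
    """Train one of LDA/EDT/SVM/REG; returns an opaque model for :func:`predict`."""
    y = np.asarray(y_codes, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    X = np.asarray(X, dtype=float)
    if name == "REG":
        scaler = _ZScorer().fit(X)
        return ("REG", scaler, train_reg(scaler.transform(X), y))
    if name == "LDA":
        scaler = _ZScorer().fit(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign collinearity warnings
            est = LinearDiscriminantAnalysis().fit(scaler.transform(X), y)
        return ("LDA", scaler, est)
    if name == "SVM":
        scaler = _ZScorer().fit(X)
        est = SVC(kernel="linear", C=1.0, decision_function_shape="ovo")
        return ("SVM", scaler, est.fit(scaler.transform(X), y))
    if name == "EDT":
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=100,
            random_state=seed,
        )
        return ("EDT", None, est.fit(X, y))
    raise ValueError(f"unknown classifier: {name!r} (one of {CLASSIFIERS})")


def predict(model, X: np.ndarray) -> np.ndarray:
    name, scaler, est = model
    X = np.asarray(X, dtype=float)
    if scaler is not None:
        X = scaler.transform(X)
    if name == "REG":
        return predict_reg(est, X)
    return est.predict(X).astype(int)


# ---------------------------------------------------------------------------
# leave-participant-out experiment

@dataclass
class CVResult:
    """Results of one problem x feature set x classifier LOPO evaluation."""

    problem_id: str
    feature_set: str
    classifier: str
    fold_accuracies: dict  # participant_id -> accuracy in percent
    confusion: np.ndarray  # (K, K) counts, rows = true class
    selection: object  # SelectionResult (pooled) | dict of them (per-fold) | None
    selection_mode: str
    class_labels: tuple

    @property
    def mean_accuracy(self) -> float:
        """Mean of per-participant fold accuracies, in percent."""
        return float(np.mean(list(self.fold_accuracies.values())))

    @property
    def n_selected(self) -> Optional[int]:
        if isinstance(self.selection, SelectionResult):
            return len(self.selection)
        return None

    def summary(self) -> str:
        lines = [
            f"Problem {self.problem_id} ({' vs. '.join(self.class_labels)})",
            f"  feature set: {self.feature_set}   classifier: {self.classifier}"
            f"   selection: {self.selection_mode}",
        ]
        if self.n_selected is not None:
            lines.append(
                f"  selected features: {self.n_selected} "
                f"(p < {self.selection.threshold_used:g})"
            )
        lines.append(f"  mean LOPO accuracy: {self.mean_accuracy:.1f}%")
        lines.append("  per-participant: " + "  ".join(
            f"{pid}:{acc:.0f}" for pid, acc in sorted(self.fold_accuracies.items())
        ))
        lines.append("  confusion (rows = true):")
        for label, row in zip(self.class_labels, self.confusion):
            lines.append(f"    {label:<22s} " + " ".join(f"{int(v):4d}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        sel = None
        if isinstance(self.selection, SelectionResult):
            sel = json.loads(self.selection.to_json())
        elif isinstance(self.selection, dict):
            sel = {pid: json.loads(s.to_json()) for pid, s in self.selection.items()}
        return {
            "problem_id": self.problem_id,
            "feature_set": self.feature_set,
            "classifier": self.classifier,
            "selection_mode": self.selection_mode,
            "class_labels": list(self.class_labels),
            "fold_accuracies": {k: float(v) for k, v in self.fold_accuracies.items()},
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
            "selection": sel,
        }


class LopoExperiment:
    """One classification experiment on a per-trial feature table.

    Parameters
    ----------
    table : DataFrame
        Feature matrix from :func:`carrygait.pipeline.build_feature_table`
        (``participant_id``/``condition_id`` metadata plus named features).
    problem : str or ProblemDefinition
        Which of the five classification problems to evaluate; trials whose
        condition is skipped under the problem are dropped before folding.
    feature_set : {"inertial", "emg", "both"}
    classifier : {"LDA", "EDT", "SVM", "REG"}
    selection : {"adaptive", "none"}
        Whether to run adaptive SFFS before classification.
    selection_mode : {"pooled", "per-fold"}
        Pooled selects once on all trials (source-faithful); per-fold
        reselects inside each training fold (leakage-free).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        problem,
        feature_set: str = "inertial",
        classifier: str = "REG",
        selection: str = "adaptive",
        selection_mode: str = "pooled",
        seed: int = 0,
    ):
        self.problem = PROBLEMS[problem] if isinstance(problem, str) else problem
        if classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier: {classifier!r}")
        if selection not in ("adaptive", "none"):
            raise ValueError(f"unknown selection: {selection!r}")
        if selection_mode not in ("pooled", "per-fold"):
            raise ValueError(f"unknown selection_mode: {selection_mode!r}")
        self.feature_set = feature_set
        self.classifier = classifier
        self.selection = selection
        self.selection_mode = selection_mode
        self.seed = seed
        self.feature_names = list(feature_set_columns(feature_set))

        codes = np.array(
            [
                class_code(condition_by_id(cid), self.problem) or 0
                for cid in table["condition_id"]
            ]
        )
        keep = codes > 0
        if not keep.any():
            raise ValueError("no trials remain after SKIP filtering")
        self.table = table.loc[keep].reset_index(drop=True)
        self.y = codes[keep]
        self.groups = self.table["participant_id"].to_numpy()
        self.X = self.table[self.feature_names].to_numpy(dtype=float)
        if np.unique(self.groups).size < 2:
            raise ValueError("leave-participant-out CV needs at least 2 participants")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, problem, **kwargs) -> "LopoExperiment":
        return cls(table, problem, **kwargs)

    def _select(self, X: pd.DataFrame, y: np.ndarray) -> SelectionResult:
        return adaptive_select(X, y)

    def fit(self) -> CVResult:
        """Run selection and leave-participant-out CV; return the results."""
        K = self.problem.n_classes
        frame = pd.DataFrame(self.X, columns=self.feature_names)

        pooled_sel = None
        cols = list(range(len(self.feature_names)))
        if self.selection == "adaptive" and self.selection_mode == "pooled":
            pooled_sel = self._select(frame, self.y)
            cols = [self.feature_names.index(n) for n in pooled_sel.selected]

        participants = sorted(set(self.groups))
        fold_acc: dict[str, float] = {}
        fold_sels: dict[str, SelectionResult] = {}
        confusion = np.zeros((K, K), dtype=int)
        for pid in participants:
            test = self.groups == pid
            train = ~test
            assert not np.any(test & train)  # structural no-leakage guarantee
            if test.sum() == 0:
                raise ValueError(f"empty test fold for participant {pid}")
            use = cols
            if self.selection == "adaptive" and self.selection_mode == "per-fold":
                sel = self._select(frame.loc[train], self.y[train])
                fold_sels[pid] = sel
                use = [self.feature_names.index(n) for n in sel.selected]
            if not use:  # selection kept nothing: predict the training majority
                maj = int(np.bincount(self.y[train]).argmax())
                pred = np.full(int(test.sum()), maj)
            else:
                model = train_classifier(
                    self.classifier, self.X[np.ix_(train, use)], self.y[train], self.seed
                )
                pred = predict(model, self.X[np.ix_(test, use)])
            truth = self.y[test]
            fold_acc[pid] = 100.0 * float(np.mean(pred == truth))
            for t, p in zip(truth, pred):
                confusion[t - 1, p - 1] += 1

        selection: object = pooled_sel
        if self.selection == "adaptive" and self.selection_mode == "per-fold":
            selection = fold_sels
        elif self.selection == "none":
            selection = None
        return CVResult(
            problem_id=self.problem.problem_id,
            feature_set=self.feature_set,
            classifier=self.classifier,
            fold_accuracies=fold_acc,
            confusion=confusion,
            selection=selection,
            selection_mode=self.selection_mode if self.selection != "none" else "none",
            class_labels=self.problem.class_labels,
        )


def lopo_cv(
    table: pd.DataFrame,
    problem,
    feature_set: str = "inertial",
    classifier: str = "REG",
    selection_mode: str = "pooled",
    seed: int = 0,
) -> CVResult:
    """Functional wrapper: build a :class:`LopoExperiment` and fit it."""
    return LopoExperiment(
        table,
        problem,
        feature_set=feature_set,
        classifier=classifier,
        selection_mode=selection_mode,
        seed=seed,
    ).fit()


# ---------------------------------------------------------------------------
# reporting

def report(results: list) -> dict:
    """Render accuracy and top-feature tables from a list of CVResults.

    The accuracy grid shows, per problem x feature set, the selected-feature
    count and mean accuracy for the conventional classifier of that feature
    set (REG for inertial and combined, SVM for EMG-only); every supplied
    result is kept in the machine-readable section regardless.
    """
    doc = {
        "schema": "carrygait.report",
        "version": 1,
        "results": [r.to_dict() for r in results],
        "accuracy_table": {},
        "top_features": {},
    }
    lines = ["Accuracy table (n selected, mean LOPO accuracy %)", ""]
    header = f"{'problem':<8s}" + "".join(f"{fs:>18s}" for fs in FEATURE_SETS)
    lines.append(header)
    by_key = {(r.problem_id, r.feature_set, r.classifier): r for r in results}
    problems = sorted({r.problem_id for r in results})
    for pid in problems:
        row = {}
        cells = [f"{pid:<8s}"]
        for fs in FEATURE_SETS:
            r = by_key.get((pid, fs, REPORT_CLASSIFIER[fs]))
            if r is None:
                cells.append(f"{'-':>18s}")
                continue
            n_sel = r.n_selected if r.n_selected is not None else "*"
            row[fs] = {
                "n_selected": r.n_selected,
                "mean_accuracy": r.mean_accuracy,
                "classifier": r.classifier,
            }
            cells.append(f"{f'{n_sel}, {r.mean_accuracy:.1f}%':>18s}")
        doc["accuracy_table"][pid] = row
        lines.append("".join(cells))

    lines += ["", "Top 5 selected features (inclusion order, inertial+EMG set)"]
    for pid in problems:
        r = by_key.get((pid, "both", REPORT_CLASSIFIER["both"])) or next(
            (x for x in results if x.problem_id == pid and x.n_selected), None
        )
        if r is None or not isinstance(r.selection, SelectionResult):
            continue
        top5 = r.selection.selected[:5]
        doc["top_features"][pid] = top5
        lines.append(f"{pid}:")
        lines += [f"  {name}" for name in top5]
    doc["text"] = "\n".join(lines)
    return doc
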