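"""Sequential floating forward selection (SFFS) with a partial-F p-value criterion.

Each candidate feature is scored by the partial F-test for adding it to an
ordinary least-squares regression of the numeric class code on the features
already selected (plus intercept):

    F = (RSS0 - RSS1) / (RSS1 / (n - q - 2)),   F ~ F(1, n - q - 2)

with q the number of already-selected features.  The floating step tests
each selected feature's removal p-value in the current model (the usual
coefficient t-test, equivalently a partial F with one numerator df) and
removes the worst offender while it exceeds the exclusion threshold, never
removing the feature added in the same pass.

The adaptive scheme reruns the whole selection at a stricter threshold
(0.05 -> 0.01 -> 0.001) whenever the selected set exceeds 50 features,
recording the threshold finally used.  Ties are broken by canonical
feature-name order; a candidate collinear with the selected block (rank
check at 1e-10 relative) scores p = 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["SelectionResult", "candidate_pvalue", "sffs", "adaptive_select"]

_COLLINEAR_RTOL = 1e-10
THRESHOLDS = (0.05, 0.01, 0.001)
MAX_SELECTED = 50


@dataclass
class SelectionResult:
    """Outcome of one (possibly adaptive) SFFS run."""

    selected: list  # ordered feature names
    inclusion_p: dict  # feature name -> p-value at its inclusion step
    threshold_used: float
    history: list = field(default_factory=list)  # (action, name, p) tuples

    def __len__(self) -> int:
        return len(self.selected)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "carrygait.selection",
                "version": 1,
                "selected": self.selected,
                "inclusion_p": self.inclusion_p,
                "threshold_used": self.threshold_used,
                "history": [list(h) for h in self.history],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        doc = json.loads(text)
        return cls(
            selected=doc["selected"],
            inclusion_p=doc["inclusion_p"],
            threshold_used=doc["threshold_used"],
            history=[tuple(h) for h in doc["history"]],
        )


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        return X.to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def candidate_pvalue(selected_block, candidate, labels) -> float:
    """Partial-F p-value for adding one candidate column to the selected block.

    ``selected_block`` is an (n, q) array (q may be 0), ``candidate`` an
    (n,) column, ``labels`` the integer class codes treated as a numeric
    response.  Constant or collinear candidates return p = 1; a perfect fit
    (RSS1 = 0) returns p = 0.
    """
    y = np.asarray(labels, dtype=float)
    n = y.shape[0]
    block = np.asarray(selected_block, dtype=float)
    if block.size == 0:
        block = np.empty((n, 0))
    q = block.shape[1]
    if n - q - 2 < 1:
        raise ValueError(f"too few trials (n={n}) for {q} selected features")
    if np.unique(y).size < 2:
        raise ValueError("labels must have at least 2 distinct values")
    x = np.asarray(candidate, dtype=float)

    X0 = np.column_stack([np.ones(n), block])
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ beta0) ** 2))
    # collinearity: candidate's residual against the selected block + intercept
    gamma, *_ = np.linalg.lstsq(X0, x, rcond=None)
    resid_x = x - X0 @ gamma
    xc = x - x.mean()
    if np.sum(resid_x**2) <= _COLLINEAR_RTOL * max(float(np.sum(xc**2)), np.finfo(float).tiny):
        return 1.0
    X1 = np.column_stack([X0, x])
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(np.sum((y - X1 @ beta1) ** 2))
    dfe = n - q - 2
    if rss1 <= max(rss0, 1.0) * 1e-14:
        return 0.0
    f = max(rss0 - rss1, 0.0) / (rss1 / dfe)
    return float(stats.f.sf(f, 1, dfe))


def _add_step_pvalues(Q: np.ndarray, y: np.ndarray, C: np.ndarray, dfe: int) -> np.ndarray:
    """Vectorized partial-F p-values for all candidate columns ``C``.

    ``Q`` is an orthonormal basis of [1, selected block].  Equivalent to
    calling :func:`candidate_pvalue` per column (asserted in tests).
    """
    ry = y - Q @ (Q.T @ y)
    rC = C - Q @ (Q.T @ C)
    rss0 = float(ry @ ry)
    s_xx = np.einsum("ij,ij->j", rC, rC)
    s_xy = rC.T @ ry
    Cc = C - C.mean(axis=0)
    scale = np.maximum(np.einsum("ij,ij->j", Cc, Cc), np.finfo(float).tiny)
    collinear = s_xx <= _COLLINEAR_RTOL * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = rss0 - s_xy**2 / np.where(collinear, 1.0, s_xx)
        rss1 = np.maximum(rss1, 0.0)
        f = (rss0 - rss1) / (rss1 / dfe)
    p = np.where(rss1 <= max(rss0, 1.0) * 1e-14, 0.0, stats.f.sf(f, 1, dfe))
    p = np.where(collinear, 1.0, p)
    return p


def _removal_pvalues(Xsel: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Removal p-value of each selected feature in the full current model."""
    n, q = Xsel.shape
    X = np.column_stack([np.ones(n), Xsel])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dfe = n - q - 1
    rss = float(resid @ resid)
    XtX_inv = np.linalg.pinv(X.T @ X)
    var = np.maximum(np.diag(XtX_inv) * rss / dfe, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(var > 0, beta**2 / var, np.inf)
    p = stats.f.sf(f[1:], 1, dfe)
    if rss <= 1e-14 * max(float(y @ y), 1.0):
        # saturated model: coefficient tests are meaningless; keep everything
        p = np.zeros(q)
    return p


def sffs(X, labels, threshold: float = 0.05, p_out: float | None = None) -> SelectionResult:
    """One SFFS run at fixed inclusion/exclusion thresholds.

    ``X`` is a DataFrame (columns = feature names) or 2-D array; ``labels``
    the integer class codes.  Deterministic: candidate ties are broken by
    canonical (input) column order via a strict minimum.
    """
    M, names = _as_matrix(X)
    y = np.asarray(labels, dtype=float)
    n, n_feat = M.shape
    if y.shape[0] != n:
        raise ValueError("X and labels disagree on the number of trials")
    if p_out is None:
        p_out = threshold

    selected: list[int] = []
    inclusion_p: dict[str, float] = {}
    history: list[tuple] = []
    max_actions = 10 * n_feat + 100

    while len(history) < max_actions:
        q = len(selected)
        dfe = n - q - 2
        if dfe < 1 or q == n_feat:
            break
        block = np.column_stack([np.ones(n)] + [M[:, j] for j in selected])
        Q, _ = np.linalg.qr(block)
        ry = y - Q @ (Q.T @ y)
        if float(ry @ ry) <= 1e-12 * max(float(np.sum((y - y.mean()) ** 2)), 1.0):
            break  # current model already saturated; nothing left to explain
        rest = [j for j in range(n_feat) if j not in selected]
        p_add = _add_step_pvalues(Q, y, M[:, rest], dfe)
        best = int(np.argmin(p_add))  # strict min -> first (canonical) on ties
        if p_add[best] >= threshold:
            break
        j_new = rest[best]
        selected.append(j_new)
        inclusion_p[names[j_new]] = float(p_add[best])
        history.append(("add", names[j_new], float(p_add[best])))

        # floating removal: worst removable feature while above p_out,
        # never the feature just added in this pass
        while len(selected) > 1 and len(history) < max_actions:
            p_rem = _removal_pvalues(M[:, selected], y)
            order = [
                (i, p)
                for i, p in enumerate(p_rem)
                if selected[i] != j_new
            ]
            worst_i, worst_p = max(order, key=lambda t: (t[1], -t[0]))
            if worst_p <= p_out:
                break
            j_rm = selected.pop(worst_i)
            history.append(("remove", names[j_rm], float(worst_p)))
    else:
        logger.warning("SFFS action cap reached; terminating selection")

    return SelectionResult(
        selected=[names[j] for j in selected],
        inclusion_p=inclusion_p,
        threshold_used=threshold,
        history=history,
    )


def adaptive_select(
    X,
    labels,
    thresholds=THRESHOLDS,
    max_features: int = MAX_SELECTED,
) -> SelectionResult:
    """SFFS with the adaptive threshold scheme.

    Run at the first threshold; while the selected set exceeds
    ``max_features``, rerun from scratch at the next stricter threshold.
    The last run's result is returned with ``threshold_used`` set.
    """
    result = None
    for th in thresholds:
        result = sffs(X, labels, threshold=th)
        if len(result) <= max_features:
            break
        logger.info(
            "selection kept %d > %d features at p<%g; rerunning at stricter threshold",
            len(result), max_features, th,
        )
    return result
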