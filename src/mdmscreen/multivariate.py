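"""Fisher discriminant analysis over metabolite subsets.

A linear two-class Fisher discriminant maximizes between-class over
within-class scatter; its weight vector solves

    (S_W + ridge·I) w = μ_ASD − μ_TD

with S_W the pooled within-class scatter matrix. Projections X·w are
oriented so the affected class scores higher, and ranked by AUROC.
Generalization is assessed by leave-one-out cross-validation: each
participant is scored by a discriminant fitted on the remaining n−1, and
the AUROC is computed on the pooled held-out scores (per-fold AUROC is
undefined for single points). The combination search exhaustively
enumerates all k-subsets of a feature pool in lexicographic order and
reports those whose AUROC clears a floor.

A small ridge (default 1e-6 × trace(S_W)/p) is added automatically when
the scatter matrix is ill-conditioned; this is logged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .errors import BudgetExceededError, SingularScatterError
from .univariate import auroc

logger = logging.getLogger(__name__)

_COND_THRESHOLD = 1e10


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _class_split(labels, positive_group: str):
    labels = np.asarray(labels)
    pos = labels == positive_group
    return pos


@dataclass
class FdaModel:
    """Fitted two-class Fisher discriminant."""

    feature_ids: list[str]
    weights: np.ndarray
    ridge: float
    mean_pos: np.ndarray
    mean_neg: np.ndarray

    def project(self, X) -> np.ndarray:
        M, _ = _as_matrix(X)
        return M @ self.weights


def fit_fda(
    X,
    labels,
    positive_group: str = "ASD",
    ridge: float | None = None,
) -> FdaModel:
    """Fit the Fisher discriminant direction.

    ``ridge=None`` (default) adds 1e-6 × trace(S_W)/p only when S_W is
    ill-conditioned; an explicit ``ridge=0`` on a singular scatter raises
    :class:`SingularScatterError` advising a positive ridge.
    """
    M, names = _as_matrix(X)
    if not np.isfinite(M).all():
        raise ValueError("features must be finite (transform/impute upstream)")
    pos = _class_split(labels, positive_group)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >=2 participants per class, got {n_pos} positive / {n_neg} negative"
        )
    mu1 = M[pos].mean(axis=0)
    mu0 = M[~pos].mean(axis=0)
    c1 = M[pos] - mu1
    c0 = M[~pos] - mu0
    sw = c1.T @ c1 + c0.T @ c0
    p = M.shape[1]

    used_ridge = ridge
    if used_ridge is None:
        cond = np.linalg.cond(sw)
        if not np.isfinite(cond) or cond > _COND_THRESHOLD:
            used_ridge = 1e-6 * np.trace(sw) / p
            logger.info(
                "fit_fda: ill-conditioned scatter (cond=%.3g); ridge=%.3g",
                cond, used_ridge,
            )
        else:
            used_ridge = 0.0
    try:
        w = np.linalg.solve(sw + used_ridge * np.eye(p), mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise SingularScatterError(
            "within-class scatter is singular; pass a positive ridge"
        ) from exc
    if not np.isfinite(w).all():
        raise SingularScatterError(
            "within-class scatter is singular; pass a positive ridge"
        )
    # orient so the positive class projects higher
    if (mu1 - mu0) @ w < 0:
        w = -w
    return FdaModel(
        feature_ids=names, weights=w, ridge=float(used_ridge),
        mean_pos=mu1, mean_neg=mu0,
    )


def fda_auroc(X, labels, positive_group: str = "ASD", **fit_kw) -> float:
    """In-sample AUROC of the fitted discriminant projection."""
    model = fit_fda(X, labels, positive_group, **fit_kw)
    scores = model.project(X)
    pos = _class_split(labels, positive_group)
    return auroc(scores[pos], scores[~pos])


def loocv_scores(X, labels, positive_group: str = "ASD", **fit_kw) -> np.ndarray:
    """Held-out projection score for each participant.

    Each fold's orientation is fixed by its own training-class means, so
    pooled scores are comparable across folds.
    """
    M, names = _as_matrix(X)
    labels = np.asarray(labels)
    n = M.shape[0]
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 participants")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any() or len(counts) != 2:
        raise ValueError(
            "each class needs >=2 members so every training fold keeps both classes"
        )
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_fda(M[keep], labels[keep], positive_group, **fit_kw)
        out[i] = M[i] @ model.weights
    return out


def loocv_auroc(X, labels, positive_group: str = "ASD", **fit_kw) -> float:
    """AUROC of the pooled leave-one-out held-out scores."""
    scores = loocv_scores(X, labels, positive_group, **fit_kw)
    pos = _class_split(labels, positive_group)
    return auroc(scores[pos], scores[~pos])


@dataclass
class CombinationResult:
    feature_ids: tuple[str, ...]
    auroc_insample: float
    auroc_loocv: float | None = None


def combination_search(
    X: pd.DataFrame,
    labels,
    k: int,
    feature_pool: list[str] | None = None,
    auroc_floor: float = 0.0,
    loocv: bool = False,
    positive_group: str = "ASD",
    max_combinations: int = 200_000,
    **fit_kw,
) -> list[CombinationResult]:
    """Evaluate every k-subset of the feature pool with an FDA projection.

    Subsets are enumerated lexicographically in pool order; results with
    in-sample AUROC strictly above ``auroc_floor`` are returned sorted by
    AUROC descending, ties broken lexicographically. LOOCV AUROC is
    computed per subset only when ``loocv=True`` (it multiplies cost by n).
    """
    if feature_pool is None:
        feature_pool = list(X.columns)
    if k > len(feature_pool):
        raise ValueError(f"k={k} exceeds pool size {len(feature_pool)}")
    total = comb(len(feature_pool), k)
    if total > max_combinations:
        raise BudgetExceededError(
            f"C({len(feature_pool)}, {k}) = {total} subsets exceeds the "
            f"budget of {max_combinations}"
        )
    labels = np.asarray(labels)
    pos = _class_split(labels, positive_group)
    results = []
    for subset in itertools.combinations(feature_pool, k):
        M = X.loc[:, list(subset)]
        model = fit_fda(M, labels, positive_group, **fit_kw)
        scores = model.project(M)
        a_in = auroc(scores[pos], scores[~pos])
        if a_in > auroc_floor:
            a_cv = (
                loocv_auroc(M, labels, positive_group, **fit_kw) if loocv else None
            )
            results.append(CombinationResult(subset, a_in, a_cv))
    results.sort(key=lambda r: (-r.auroc_insample, r.feature_ids))
    return results


def combination_results_frame(results: list[CombinationResult]) -> pd.DataFrame:
    """Tabular view of search results for CSV export."""
    return pd.DataFrame(
        {
            "features": ["+".join(r.feature_ids) for r in results],
            "auroc_insample": [r.auroc_insample for r in results],
            "auroc_loocv": [r.auroc_loocv for r in results],
        }
    )
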