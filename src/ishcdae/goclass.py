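"""GO-category classification of gene representations.

One L2-regularized logistic regression per category, evaluated with a
balanced 5-fold protocol: positives and negatives are each split into five
near-equal subsets which are paired into folds, so every fold preserves the
(heavily imbalanced) class ratio. Hyperparameter tuning is two-phase: for
each held-out fold, the regularization strength is selected by cross
validation over the four training folds, the model is refit on all four,
and scored on the held-out fold by ROC AUC. The summary metric is the
unweighted mean over categories of the per-category mean fold AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "AnnotationMatrix",
    "FoldAssignment",
    "CategoryResult",
    "EvaluationSummary",
    "DEFAULT_REG_GRID",
    "filter_categories",
    "make_balanced_folds",
    "auc",
    "train_eval_category",
    "evaluate_all",
]

DEFAULT_REG_GRID: tuple[float, ...] = tuple(float(c) for c in np.logspace(-3, 3, 7))


@dataclass
class AnnotationMatrix:
    """Binary gene x category membership with ordered identifiers."""

    gene_ids: list[str]
    category_ids: list[str]
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership)
        if self.membership.shape != (len(self.gene_ids), len(self.category_ids)):
            raise ValueError("membership shape does not match id lists")
        if not np.isin(self.membership, (0, 1)).all():
            raise ValueError("membership must be binary")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        self.membership = self.membership.astype(np.int8)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationMatrix":
        return cls(gene_ids=list(frame.index.astype(str)),
                   category_ids=list(frame.columns.astype(str)),
                   membership=frame.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.membership, index=self.gene_ids,
                            columns=self.category_ids)

    def positive_counts(self) -> np.ndarray:
        return self.membership.sum(axis=0)

    def labels(self, category_id: str) -> np.ndarray:
        j = self.category_ids.index(category_id)
        return self.membership[:, j].astype(int)


@dataclass
class FoldAssignment:
    """k folds, each a (positive indices, negative indices) pair.

    Folds partition the gene set; positive counts across folds differ by at
    most one, likewise negatives.
    """

    folds: list[tuple[np.ndarray, np.ndarray]]

    @property
    def k(self) -> int:
        return len(self.folds)

    def test_indices(self, i: int) -> np.ndarray:
        pos, neg = self.folds[i]
        return np.concatenate([pos, neg])

    def train_indices(self, i: int) -> np.ndarray:
        return np.concatenate([self.test_indices(j) for j in range(self.k) if j != i])


@dataclass
class CategoryResult:
    category_id: str
    fold_aucs: list[float]
    mean_auc: float
    chosen_reg: list[float]


@dataclass
class EvaluationSummary:
    results: list[CategoryResult]
    mean_auc: float
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for f, (a, c) in enumerate(zip(r.fold_aucs, r.chosen_reg)):
                rows.append({"category": r.category_id, "fold": f,
                             "auc": a, "chosen_reg": c})
        return pd.DataFrame(rows)


def filter_categories(annotations: AnnotationMatrix, min_count: int = 15,
                      max_count: int = 500) -> list[str]:
    """Categories whose positive count lies in [min_count, max_count],
    inclusive — small enough to be semantically specific, large enough to
    test on."""
    counts = annotations.positive_counts()
    return [c for c, n in zip(annotations.category_ids, counts)
            if min_count <= n <= max_count]


def make_balanced_folds(labels: np.ndarray, k: int = 5,
                        seed: int = 0) -> FoldAssignment:
    """Split positives and negatives independently into k near-equal
    shuffled subsets and pair them into folds."""
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) < k:
        raise ValueError(f"need at least {k} positives, got {len(pos)}")
    if len(neg) < k:
        raise ValueError(f"need at least {k} negatives, got {len(neg)}")
    pos_parts = np.array_split(rng.permutation(pos), k)
    neg_parts = np.array_split(rng.permutation(neg), k)
    return FoldAssignment(folds=[(p, n) for p, n in zip(pos_parts, neg_parts)])


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC: the probability a positive outranks a negative, ties
    half-credited (Mann-Whitney convention)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _make_model(reg_c: float) -> Pipeline:
    # scaler fit on training folds only -> leakage-safe standardization
    return Pipeline([
        ("scale", StandardScaler()),
        ("logreg", LogisticRegression(C=reg_c, solver="lbfgs", max_iter=2000)),
    ])


def _fit_score(X, y, train_idx, test_idx, reg_c: float) -> float:
    model = _make_model(reg_c)
    model.fit(X[train_idx], y[train_idx])
    scores = model.decision_function(X[test_idx])
    return auc(scores, y[test_idx])


def train_eval_category(X: np.ndarray, y: np.ndarray, folds: FoldAssignment,
                        reg_grid=DEFAULT_REG_GRID,
                        category_id: str = "") -> CategoryResult:
    """Two-phase k-fold evaluation of one category.

    Outer phase: each fold is held out once. Inner phase: on the remaining
    k-1 folds, each serves as inner validation once; the regularization
    strength with the best inner mean AUC (first grid entry on ties) is
    refit on all k-1 folds and scored on the held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    for i, (pos, neg) in enumerate(folds.folds):
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError(
                f"degenerate fold {i} for category {category_id!r}: "
                f"{len(pos)} positives, {len(neg)} negatives"
            )
    fold_aucs, chosen = [], []
    for i in range(folds.k):
        inner = [j for j in range(folds.k) if j != i]
        grid_scores = []
        for c in reg_grid:
            vals = []
            for j in inner:
                tr = np.concatenate([folds.test_indices(m) for m in inner if m != j])
                vals.append(_fit_score(X, y, tr, folds.test_indices(j), c))
            grid_scores.append(np.mean(vals))
        best_c = reg_grid[int(np.argmax(grid_scores))]
        fold_aucs.append(_fit_score(X, y, folds.train_indices(i),
                                    folds.test_indices(i), best_c))
        chosen.append(float(best_c))
    return CategoryResult(category_id=category_id, fold_aucs=fold_aucs,
                          mean_auc=float(np.mean(fold_aucs)), chosen_reg=chosen)


def evaluate_all(X: np.ndarray, annotations: AnnotationMatrix, k: int = 5,
                 min_count: int = 15, max_count: int = 500,
                 reg_grid=DEFAULT_REG_GRID, seed: int = 0) -> EvaluationSummary:
    """Evaluate every category passing the size filter.

    Per-category failures are collected in ``summary.errors`` rather than
    aborting the remaining categories. The summary AUC is the unweighted
    mean of per-category mean AUCs (empty, with a warning, if no category
    survives the filter).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(annotations.gene_ids):
        raise ValueError("representation rows do not align with annotation genes")
    kept = filter_categories(annotations, min_count, max_count)
    results, errors = [], {}
    if not kept:
        import warnings

        warnings.warn("no categories within the size filter; empty summary")
        return EvaluationSummary(results=[], mean_auc=float("nan"), errors={})
    for idx, cat in enumerate(kept):
        y = annotations.labels(cat)
        try:
            folds = make_balanced_folds(y, k=k, seed=seed + idx)
            results.append(train_eval_category(X, y, folds, reg_grid, cat))
        except Exception as exc:  # collected, not fatal to other categories
            errors[cat] = str(exc)
    mean = float(np.mean([r.mean_auc for r in results])) if results else float("nan")
    return EvaluationSummary(results=results, mean_auc=mean, errors=errors)
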