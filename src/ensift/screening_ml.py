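"""Linear soft-margin SVM screening with MCC/AUROC evaluation.

The classifier is the standard maximum-margin formulation

    minimize   ||w||²/2 + C Σ ξ_i
    subject to y_i(⟨w, x_i⟩ − b) ≥ 1 − ξ_i,   ξ_i ≥ 0

with the linear kernel only. Training is delegated to libsvm via
scikit-learn, but every returned model is checked against the dual
feasibility conditions Σ α_i y_i = 0 and 0 ≤ α_i ≤ C, so the emitted
(w, b, α) genuinely solve the dual.

Evaluation follows retrospective-screening practice: C selected on the grid
{0.01, 0.1, 1, 10, 100, 1000, 10000} by pooled Matthews correlation
coefficient over stratified, compound-grouped 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_C_GRID",
    "FeatureMatrix",
    "SvmModel",
    "ConfusionCounts",
    "CvResult",
    "train_linear_svm",
    "compute_mcc",
    "compute_auroc",
    "cross_validate",
]

DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)

_FEASIBILITY_TOL = 1e-6


@dataclass
class FeatureMatrix:
    """Profiles as an ML-ready matrix with ±1 labels and grouping ids.

    ``groups`` holds the parent-compound id of each row so that
    cross-validation never splits protonation-state instances of one parent
    across folds.
    """

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    groups: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not np.isfinite(self.X).all():
            raise ValueError("features contain non-finite values")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("one id per row required")
        if not self.groups:
            self.groups = list(self.ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class SvmModel:
    """Trained linear SVM: decision function f(x) = ⟨w, x⟩ − b."""

    w: np.ndarray
    b: float
    C: float
    support_alphas: np.ndarray  # α_i for every training row (0 off support)
    slack: np.ndarray           # ξ_i at the solution

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w - self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0, 1, -1)

    def dual_objective(self, X: np.ndarray, y: np.ndarray) -> float:
        """Σ α_i − ½ Σ_ij α_i α_j y_i y_j ⟨x_i, x_j⟩ at the trained α."""
        a = self.support_alphas
        v = (a * y) @ np.asarray(X, dtype=float)
        return float(a.sum() - 0.5 * v @ v)


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray,
                         y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == -1) & (y_pred == -1))),
            FP=int(np.sum((y_true == -1) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


@dataclass
class CvResult:
    per_fold_counts: list[ConfusionCounts]
    pooled_mcc: float
    per_C_results: dict[float, float]
    best_C: float
    per_fold_mcc_mean: float
    pooled_auroc: float

    @property
    def pooled_counts(self) -> ConfusionCounts:
        return sum(self.per_fold_counts, ConfusionCounts())


def train_linear_svm(data: FeatureMatrix, C: float,
                     tol: float = 1e-6) -> SvmModel:
    """Solve the soft-margin linear SVM; verify dual feasibility post-hoc."""
    from sklearn.svm import SVC

    if C <= 0:
        raise ValueError("C must be positive")
    classes = set(np.unique(data.y))
    if classes != {-1, 1}:
        raise ValueError("training data must contain both classes")

    clf = SVC(kernel="linear", C=C, tol=tol, shrinking=False)
    clf.fit(data.X, data.y)

    alphas = np.zeros(data.n)
    # dual_coef_ holds y_i * α_i for the support vectors
    alphas[clf.support_] = np.abs(clf.dual_coef_[0])
    w = clf.coef_[0].copy()
    b = -float(clf.intercept_[0])

    balance = float(np.dot(alphas, data.y))
    if abs(balance) > _FEASIBILITY_TOL * max(1.0, alphas.sum()):
        raise RuntimeError(f"dual feasibility violated: Σ α_i y_i = {balance:g}")
    if (alphas < -_FEASIBILITY_TOL).any() or (alphas > C + _FEASIBILITY_TOL).any():
        raise RuntimeError("dual box constraints violated")

    margins = data.y * (data.X @ w - b)
    slack = np.maximum(0.0, 1.0 - margins)
    return SvmModel(w=w, b=b, C=C, support_alphas=alphas, slack=slack)


def compute_mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient,
    (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    0 when any denominator factor vanishes."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def compute_auroc(scores_pos: Sequence[float],
                  scores_neg: Sequence[float]) -> float:
    """AUROC via the Mann–Whitney pair count: the fraction of
    (positive, negative) pairs ranked correctly, ties counting one half."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return float(wins / (pos.size * neg.size))


def _make_folds(data: FeatureMatrix, k_folds: int, seed: int):
    from sklearn.model_selection import StratifiedGroupKFold

    for cls in (-1, 1):
        n_groups = len({g for g, y in zip(data.groups, data.y) if y == cls})
        if n_groups < k_folds:
            raise ValueError(
                f"class {cls:+d} has {n_groups} compound groups; "
                f"{k_folds}-fold stratification impossible"
            )
    splitter = StratifiedGroupKFold(n_splits=k_folds, shuffle=True,
                                    random_state=seed)
    return list(splitter.split(data.X, data.y, groups=data.groups))


def cross_validate(data: FeatureMatrix,
                   C_grid: Sequence[float] = DEFAULT_C_GRID,
                   k_folds: int = 10,
                   seed: int = 0) -> CvResult:
    """Stratified, compound-grouped k-fold CV over the C grid.

    For each C the held-out confusion counts are pooled over folds and MCC
    computed on the pooled table; ``best_C`` maximizes pooled MCC with ties
    going to the smaller C. The per-fold MCC mean and a pooled AUROC of the
    decision values are reported for the winning C as well.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    folds = _make_folds(data, k_folds, seed)

    per_C_results: dict[float, float] = {}
    per_C_details: dict[float, tuple[list[ConfusionCounts], np.ndarray]] = {}
    for C in C_grid:
        fold_counts: list[ConfusionCounts] = []
        scores = np.zeros(data.n)
        for train_idx, test_idx in folds:
            model = train_linear_svm(
                FeatureMatrix(data.X[train_idx], data.y[train_idx],
                              [data.ids[i] for i in train_idx],
                              [data.groups[i] for i in train_idx]),
                C,
            )
            scores[test_idx] = model.decision_function(data.X[test_idx])
            fold_counts.append(
                ConfusionCounts.from_predictions(
                    data.y[test_idx], model.predict(data.X[test_idx])
                )
            )
        per_C_results[C] = compute_mcc(sum(fold_counts, ConfusionCounts()))
        per_C_details[C] = (fold_counts, scores)

    best_C = min(per_C_results, key=lambda c: (-per_C_results[c], c))
    fold_counts, scores = per_C_details[best_C]
    per_fold_mcc = [compute_mcc(c) for c in fold_counts]
    return CvResult(
        per_fold_counts=fold_counts,
        pooled_mcc=per_C_results[best_C],
        per_C_results=per_C_results,
        best_C=best_C,
        per_fold_mcc_mean=float(np.mean(per_fold_mcc)),
        pooled_auroc=compute_auroc(scores[data.y == 1], scores[data.y == -1]),
    )
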