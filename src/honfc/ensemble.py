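"""Per-level linear SVMs with weighted decision-score fusion.

One linear soft-margin SVM is trained per network level on that level's
LASSO-selected features.  At prediction time the real-valued decision
scores of the level classifiers are combined linearly with fusion weights
that sum to one, and the fused score is thresholded at zero (an exact
zero breaks towards the positive class).

Hyper-parameters — the selection penalty ``lambda``, the SVM cost ``C``
(the soft-margin trade-off, searched over ``2^-5 .. 2^5``) and the fusion
weights (built from the grid 0.1 .. 0.9) — are tuned by an inner
stratified cross-validation on the training data only, maximising inner
accuracy, with deterministic tie-breaks: smallest lambda, then smallest
cost, then the weight vector closest to uniform.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import (
    ColumnScaler,
    LevelFeatureSet,
    SelectionResult,
    apply_selection,
    lasso_select,
)

logger = logging.getLogger("honfc.ensemble")

__all__ = [
    "Grids",
    "LinearSVM",
    "ConstantClassifier",
    "LevelModel",
    "TrainedEnsemble",
    "train_level_svm",
    "fuse_scores",
    "fusion_weight_grid",
    "ensemble_fit",
]


@dataclass(frozen=True)
class Grids:
    """Hyper-parameter search grids (defaults as printed in the study
    protocol)."""

    lambdas: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    costs: tuple[float, ...] = tuple(float(2.0 ** p) for p in range(-5, 6))
    alphas: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

    def __post_init__(self):
        if not (self.lambdas and self.costs and self.alphas):
            raise ValueError("grids must be non-empty")


@dataclass
class LinearSVM:
    """A fitted linear SVM exposing a signed decision score."""

    coef: np.ndarray
    intercept: float
    support: np.ndarray = field(default=None, repr=False)
    dual_coef: np.ndarray = field(default=None, repr=False)

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.coef + self.intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        s = self.decision_scores(x)
        return np.where(s >= 0.0, 1, -1)


@dataclass
class ConstantClassifier:
    """Fallback when a level selects zero features: majority-class label,
    decision score 0 (it neither helps nor harms the fusion)."""

    label: int

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        return np.zeros(np.asarray(x).shape[0])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(x).shape[0], self.label)


def train_level_svm(x: np.ndarray, y: np.ndarray, cost: float):
    """Train a linear soft-margin SVM (or the constant fallback when the
    feature matrix has zero columns).

    Raises
    ------
    ValueError
        If the training labels contain a single class.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("SVM training requires both classes present")
    if x.shape[1] == 0:
        counts = {c: int((y == c).sum()) for c in (1, -1)}
        majority = 1 if counts[1] >= counts[-1] else -1
        logger.warning(
            "zero selected features: falling back to majority-class "
            "constant classifier (label %+d)", majority
        )
        return ConstantClassifier(label=majority)
    clf = SVC(kernel="linear", C=cost, tol=1e-10)
    clf.fit(x, y)
    # with labels {-1, +1}, classes_ = [-1, 1] and a positive decision
    # value votes for +1
    return LinearSVM(
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        support=clf.support_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
    )


def fuse_scores(
    scores: Sequence[float] | np.ndarray,
    fusion_weights: Sequence[float] | np.ndarray,
) -> tuple[float, int]:
    """Linear decision fusion: returns (fused score, label).

    The label is +1 when the fused score is positive, -1 when negative,
    and +1 on an exact tie (documented tie-break).
    """
    scores = np.asarray(scores, dtype=np.float64)
    weights = np.asarray(fusion_weights, dtype=np.float64)
    if scores.shape != weights.shape:
        raise ValueError("scores and fusion weights must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite decision scores")
    if abs(weights.sum() - 1.0) > 1e-12 or np.any(weights < 0):
        raise ValueError("fusion weights must be non-negative and sum to 1")
    fused = float(scores @ weights)
    return fused, (1 if fused >= 0.0 else -1)


def fusion_weight_grid(n_levels: int, alphas: Sequence[float]) -> list[tuple[float, ...]]:
    """Candidate fusion-weight vectors over ``n_levels`` classifiers.

    One level: the single vector (1,).  Two levels: (a, 1-a) for each grid
    value a.  Three or more: every tuple from the grid, normalised to sum
    to one, with duplicates removed (insertion order preserved).
    """
    if n_levels == 1:
        return [(1.0,)]
    if n_levels == 2:
        return [(float(a), round(1.0 - a, 12)) for a in alphas]
    seen: dict[tuple[float, ...], None] = {}
    for combo in itertools.product(alphas, repeat=n_levels):
        total = sum(combo)
        vec = tuple(round(c / total, 12) for c in combo)
        seen.setdefault(vec, None)
    return list(seen)


@dataclass
class LevelModel:
    """Everything needed to score one level: scaler, selection, classifier."""

    level: int | None
    scaler: ColumnScaler
    selection: SelectionResult
    classifier: LinearSVM | ConstantClassifier
    cost: float

    def decision_scores(self, x_raw: np.ndarray) -> np.ndarray:
        x = self.scaler.transform(np.asarray(x_raw, dtype=np.float64))
        x = apply_selection(x, self.selection)
        return self.classifier.decision_scores(x)


@dataclass
class TrainedEnsemble:
    """Per-level models plus fusion weights and the tuning trace."""

    levels: list[int]
    level_models: list[LevelModel]
    fusion_weights: np.ndarray
    tuned_lambda: dict[int, float]
    tuned_cost: dict[int, float]
    metadata: dict

    def __post_init__(self):
        self.fusion_weights = np.asarray(self.fusion_weights, dtype=np.float64)
        if abs(self.fusion_weights.sum() - 1.0) > 1e-12:
            raise ValueError("fusion weights must sum to 1")
        if len(self.level_models) != len(self.levels):
            raise ValueError("one classifier per level is required")

    def decision_scores(self, xs: Mapping[int, np.ndarray]) -> np.ndarray:
        """Per-level decision scores, shape (n_samples, n_levels)."""
        cols = [m.decision_scores(xs[lev])
                for lev, m in zip(self.levels, self.level_models)]
        return np.column_stack(cols)

    def predict(self, xs: Mapping[int, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Fused scores and labels for new subjects; ``xs`` maps level to
        the raw (unstandardised) feature matrix of that level."""
        scores = self.decision_scores(xs)
        fused = scores @ self.fusion_weights
        labels = np.where(fused >= 0.0, 1, -1)
        return fused, labels

    def to_dict(self) -> dict:
        """Portable plain-JSON representation (bit-for-bit reproducible
        predictions via :meth:`from_dict`)."""
        def arr(a):
            return np.asarray(a).tolist()

        return {
            "levels": list(self.levels),
            "fusion_weights": arr(self.fusion_weights),
            "tuned_lambda": {str(k): v for k, v in self.tuned_lambda.items()},
            "tuned_cost": {str(k): v for k, v in self.tuned_cost.items()},
            "metadata": self.metadata,
            "level_models": [
                {
                    "level": m.level,
                    "cost": m.cost,
                    "scaler_mean": arr(m.scaler.mean),
                    "scaler_std": arr(m.scaler.std),
                    "lam": m.selection.lam,
                    "weights": arr(m.selection.weights),
                    "constant_label": (
                        m.classifier.label
                        if isinstance(m.classifier, ConstantClassifier) else None
                    ),
                    "coef": (
                        arr(m.classifier.coef)
                        if isinstance(m.classifier, LinearSVM) else None
                    ),
                    "intercept": (
                        m.classifier.intercept
                        if isinstance(m.classifier, LinearSVM) else None
                    ),
                }
                for m in self.level_models
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TrainedEnsemble":
        from .features import SELECTION_THRESHOLD

        models = []
        for d in payload["level_models"]:
            w = np.asarray(d["weights"], dtype=np.float64)
            sel = SelectionResult(
                level=d["level"], weights=w,
                selected_mask=np.abs(w) > SELECTION_THRESHOLD, lam=d["lam"],
            )
            if d["constant_label"] is not None:
                clf = ConstantClassifier(label=int(d["constant_label"]))
            else:
                clf = LinearSVM(
                    coef=np.asarray(d["coef"], dtype=np.float64),
                    intercept=float(d["intercept"]),
                )
            models.append(LevelModel(
                level=d["level"],
                scaler=ColumnScaler(
                    mean=np.asarray(d["scaler_mean"]),
                    std=np.asarray(d["scaler_std"]),
                ),
                selection=sel, classifier=clf, cost=d["cost"],
            ))
        return cls(
            levels=list(payload["levels"]),
            level_models=models,
            fusion_weights=np.asarray(payload["fusion_weights"]),
            tuned_lambda={int(k): v for k, v in payload["tuned_lambda"].items()},
            tuned_cost={int(k): v for k, v in payload["tuned_cost"].items()},
            metadata=payload["metadata"],
        )


def _fit_level(x: np.ndarray, y: np.ndarray, lam: float, cost: float,
               level: int | None) -> LevelModel:
    scaler = ColumnScaler.fit(x)
    xz = scaler.transform(x)
    sel = lasso_select(xz, y, lam, level=level)
    x_sel = apply_selection(xz, sel)
    clf = train_level_svm(x_sel, y, cost)
    return LevelModel(level=level, scaler=scaler, selection=sel,
                      classifier=clf, cost=cost)


def _stratified_folds(y: np.ndarray, n_splits: int, seed: int):
    """Stratified fold index pairs whose training sides contain both
    classes; redraws with shifted seeds, erroring after 10 attempts."""
    y = np.asarray(y)
    min_class = min(int((y == c).sum()) for c in np.unique(y))
    if min_class < 2:
        raise ValueError("need at least 2 subjects per class")
    n_splits = min(n_splits, min_class)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=(seed + attempt) % (2 ** 31 - 1))
        folds = list(skf.split(np.zeros_like(y), y))
        if all(np.unique(y[tr]).size == 2 for tr, _ in folds):
            return folds
        logger.warning("degenerate fold draw (attempt %d); redrawing", attempt)
    raise RuntimeError("could not draw non-degenerate stratified folds "
                       "after 10 attempts")


def ensemble_fit(
    feature_sets: Mapping[int, LevelFeatureSet],
    grids: Grids = Grids(),
    inner_folds: int = 10,
    seed: int = 0,
) -> TrainedEnsemble:
    """Tune (lambda, cost, fusion weights) by inner stratified CV on the
    training cohort only, then refit every stage on all training data at
    the winning grid point.

    Inside each inner fold the column standardisation, LASSO selection
    and SVMs are all re-fit on the inner training split alone, so no
    validation subject leaks into any fitted statistic.  The grid point
    with the highest mean inner-fold accuracy wins; exact ties fall to
    the smallest lambda, then the smallest cost, then the fusion weight
    vector closest (L2) to uniform.
    """
    levels = sorted(feature_sets)
    base = feature_sets[levels[0]]
    y = base.labels
    ids = base.subject_ids
    for lev in levels:
        fs = feature_sets[lev]
        if fs.subject_ids != ids or not np.array_equal(fs.labels, y):
            raise ValueError("levels disagree on subjects/labels")
    n_levels = len(levels)
    weight_grid = fusion_weight_grid(n_levels, grids.alphas)

    singleton = (len(grids.lambdas) == 1 and len(grids.costs) == 1
                 and len(weight_grid) == 1)
    if singleton:
        best_lam, best_cost = grids.lambdas[0], grids.costs[0]
        best_w = np.asarray(weight_grid[0])
        best_acc = float("nan")
    else:
        folds = _stratified_folds(y, inner_folds, seed)
        # val_scores[(fold, lam, cost)] -> (scores n_val x L, y_val)
        fold_scores: dict[tuple[int, float, float], tuple[np.ndarray, np.ndarray]] = {}
        for f_idx, (tr, va) in enumerate(folds):
            y_tr, y_va = y[tr], y[va]
            for lam in grids.lambdas:
                prepped = []
                for lev in levels:
                    x_tr = feature_sets[lev].features[tr]
                    x_va = feature_sets[lev].features[va]
                    scaler = ColumnScaler.fit(x_tr)
                    xz_tr = scaler.transform(x_tr)
                    sel = lasso_select(xz_tr, y_tr, lam, level=lev)
                    prepped.append((
                        apply_selection(xz_tr, sel),
                        apply_selection(scaler.transform(x_va), sel),
                    ))
                for cost in grids.costs:
                    cols = []
                    for (xs_tr, xs_va) in prepped:
                        clf = train_level_svm(xs_tr, y_tr, cost)
                        cols.append(clf.decision_scores(xs_va))
                    fold_scores[(f_idx, lam, cost)] = (
                        np.column_stack(cols), y_va
                    )

        uniform = np.full(n_levels, 1.0 / n_levels)
        candidates = []
        for lam in grids.lambdas:
            for cost in grids.costs:
                per_fold = [fold_scores[(f, lam, cost)]
                            for f in range(len(folds))]
                for w_idx, w in enumerate(weight_grid):
                    wv = np.asarray(w)
                    accs = []
                    for scores, y_va in per_fold:
                        pred = np.where(scores @ wv >= 0.0, 1, -1)
                        accs.append(float(np.mean(pred == y_va)))
                    acc = float(np.mean(accs))
                    dist = float(np.linalg.norm(wv - uniform))
                    candidates.append((acc, lam, cost, dist, w_idx, wv))
        # highest accuracy; ties -> smallest lambda, cost, most uniform w
        candidates.sort(key=lambda c: (-round(c[0], 12), c[1], c[2],
                                       c[3], c[4]))
        best_acc, best_lam, best_cost, _, _, best_w = candidates[0]

    models = [
        _fit_level(feature_sets[lev].features, y, best_lam, best_cost, lev)
        for lev in levels
    ]
    return TrainedEnsemble(
        levels=levels,
        level_models=models,
        fusion_weights=np.asarray(best_w),
        tuned_lambda={lev: best_lam for lev in levels},
        tuned_cost={lev: best_cost for lev in levels},
        metadata={
            "seed": seed,
            "inner_folds": inner_folds,
            "inner_cv_accuracy": best_acc,
            "grids": {
                "lambdas": list(grids.lambdas),
                "costs": list(grids.costs),
                "alphas": list(grids.alphas),
            },
            "training_ids": list(ids),
        },
    )
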