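"""Edge-feature extraction and L1-regularised (LASSO) feature selection.

Each symmetric ``R x R`` network is reduced to its ``d = R(R-1)/2``
strictly-lower-triangle entries, in column-major order over the lower
triangle: ``(1,0), (2,0), ..., (R-1,0), (2,1), (3,1), ...`` where each
pair is ``(row_roi, col_roi)`` with ``row_roi > col_roi``.  Stacking the
vectors of a cohort gives a per-level ``N x d`` feature table.

Feature selection solves, per level, the L1-penalised least-squares
problem

    min_w  1/2 * || k - X w ||^2  +  lambda * || w ||_1

where ``k`` is the vector of class labels coded +1 / -1.  The penalty
weight ``lambda`` is expressed on this un-normalised scale (no ``1/N``
factor in the loss); the backing solver uses a ``1/(2N)`` convention, so
``lambda`` is rescaled internally by ``1/N``.  Features with a weight of
magnitude above 1e-8 count as selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LassoLars

logger = logging.getLogger("honfc.features")

__all__ = [
    "Edge",
    "LevelFeatureSet",
    "SelectionResult",
    "ColumnScaler",
    "vectorize_lower_triangle",
    "build_level_feature_sets",
    "lasso_select",
    "apply_selection",
    "concat_feature_sets",
]

#: |weight| above this counts as a selected feature
SELECTION_THRESHOLD = 1e-8

_SYM_TOL = 1e-12

# an edge is (row_roi, col_roi) with row > col; in concatenated feature
# tables it is (level, row_roi, col_roi)
Edge = tuple


def lower_triangle_edges(r: int) -> list[tuple[int, int]]:
    """Edge bookkeeping for :func:`vectorize_lower_triangle`: the
    ``R(R-1)/2`` pairs in column-major order over the lower triangle."""
    cols, rows = np.triu_indices(r, k=1)  # upper row-major == lower col-major
    return list(zip(rows.tolist(), cols.tolist()))


def vectorize_lower_triangle(net) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Vectorize a symmetric network into its ``d = R(R-1)/2``
    strictly-lower-triangle entries plus the matching edge index.

    Accepts an :class:`~honfc.networks.FCNetwork` or a bare symmetric
    matrix; asymmetry beyond 1e-12 is an error.
    """
    matrix = np.asarray(getattr(net, "matrix", net), dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(matrix - matrix.T)) > _SYM_TOL:
        raise ValueError("matrix is not symmetric to within 1e-12")
    r = matrix.shape[0]
    cols, rows = np.triu_indices(r, k=1)
    return matrix[rows, cols].copy(), list(zip(rows.tolist(), cols.tolist()))


def unvectorize(vector: np.ndarray, r: int) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from a lower-triangle
    vector (inverse of :func:`vectorize_lower_triangle`)."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.size != r * (r - 1) // 2:
        raise ValueError("vector length does not match R(R-1)/2")
    out = np.eye(r)
    cols, rows = np.triu_indices(r, k=1)
    out[rows, cols] = vector
    out[cols, rows] = vector
    return out


@dataclass
class LevelFeatureSet:
    """Cohort feature table for one network level.

    ``features`` is ``N x d`` (subjects by edges), ``edge_index`` the
    length-``d`` list of (row_roi, col_roi) pairs — or
    (level, row_roi, col_roi) triples in concatenated tables — and
    ``labels`` the +1/-1 class vector.
    """

    level: int | None
    features: np.ndarray
    edge_index: list[Edge]
    subject_ids: list[str]
    labels: np.ndarray
    roi_labels: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        n, d = self.features.shape
        if len(self.edge_index) != d:
            raise ValueError("edge_index length must match feature count")
        if len(self.subject_ids) != n or self.labels.shape != (n,):
            raise ValueError("subject_ids/labels must match subject count")
        if not set(np.unique(self.labels)) <= {1, -1}:
            raise ValueError("labels must be coded +1 / -1")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "LevelFeatureSet":
        """Row-subset (e.g. a CV split), keeping edge bookkeeping."""
        idx = np.asarray(idx)
        return LevelFeatureSet(
            level=self.level,
            features=self.features[idx],
            edge_index=self.edge_index,
            subject_ids=[self.subject_ids[i] for i in idx],
            labels=self.labels[idx],
            roi_labels=self.roi_labels,
        )


def build_level_feature_sets(
    networks_per_subject: list[list],
    labels: np.ndarray | list[int],
    subject_ids: list[str] | None = None,
    roi_labels: list[str] | None = None,
) -> dict[int, LevelFeatureSet]:
    """Vectorize each subject's network hierarchy into per-level cohort
    tables keyed by level."""
    labels = np.asarray(labels)
    if subject_ids is None:
        subject_ids = [nets[0].subject_id for nets in networks_per_subject]
    n_levels = len(networks_per_subject[0])
    out: dict[int, LevelFeatureSet] = {}
    for lev in range(n_levels):
        vecs, edge_index = [], None
        for nets in networks_per_subject:
            v, edge_index = vectorize_lower_triangle(nets[lev])
            vecs.append(v)
        out[lev] = LevelFeatureSet(
            level=lev,
            features=np.vstack(vecs),
            edge_index=edge_index,
            subject_ids=list(subject_ids),
            labels=labels,
            roi_labels=roi_labels,
        )
    return out


def concat_feature_sets(
    sets: dict[int, LevelFeatureSet], levels: list[int]
) -> LevelFeatureSet:
    """Column-wise concatenation of two or more levels into a single
    table; edge bookkeeping gains a level tag: (level, row, col)."""
    if len(levels) < 2:
        raise ValueError("feature concatenation needs at least 2 levels")
    base = sets[levels[0]]
    mats, edges = [], []
    for lev in levels:
        fs = sets[lev]
        if fs.subject_ids != base.subject_ids:
            raise ValueError("levels hold different subject orderings")
        mats.append(fs.features)
        edges.extend((lev, *e) for e in fs.edge_index)
    return LevelFeatureSet(
        level=None,
        features=np.hstack(mats),
        edge_index=edges,
        subject_ids=base.subject_ids,
        labels=base.labels,
        roi_labels=base.roi_labels,
    )


@dataclass
class ColumnScaler:
    """Column z-scoring with statistics frozen on a training split."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "ColumnScaler":
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std = np.where(std == 0.0, 1.0, std)  # constant columns -> centred 0
        return cls(mean=mean, std=std)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


@dataclass
class SelectionResult:
    """LASSO weights and the derived selected-feature mask for one level."""

    level: int | None
    weights: np.ndarray
    selected_mask: np.ndarray
    lam: float

    @property
    def n_selected(self) -> int:
        return int(self.selected_mask.sum())


def lasso_select(
    X: np.ndarray,
    k: np.ndarray,
    lam: float,
    level: int | None = None,
) -> SelectionResult:
    """Solve ``min_w 1/2 ||k - Xw||^2 + lam ||w||_1`` and mark the
    nonzero coordinates.

    ``X`` should be column-standardised on the training split.  The LARS
    homotopy solver is used, which satisfies the KKT stationarity
    conditions of the objective to solver precision.  An empty selection
    is a valid result.
    """
    X = np.asarray(X, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(k))):
        raise ValueError("non-finite values in LASSO inputs")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    n = X.shape[0]
    # solver minimises 1/(2N) ||k - Xw||^2 + alpha ||w||_1
    model = LassoLars(alpha=lam / n, fit_intercept=False, max_iter=5000)
    model.fit(X, k)
    w = np.asarray(model.coef_, dtype=np.float64)
    mask = np.abs(w) > SELECTION_THRESHOLD
    return SelectionResult(level=level, weights=w, selected_mask=mask, lam=lam)


def apply_selection(
    X: np.ndarray,
    result: SelectionResult,
    edge_index: list[Edge] | None = None,
):
    """Keep the selected columns of ``X``; optionally return the matching
    edge bookkeeping.  An all-false mask yields a zero-column matrix."""
    X = np.asarray(X)
    if X.shape[1] != result.selected_mask.size:
        raise ValueError(
            f"feature count {X.shape[1]} does not match selection "
            f"dimension {result.selected_mask.size}"
        )
    reduced = X[:, result.selected_mask]
    if edge_index is None:
        return reduced
    if len(edge_index) != result.selected_mask.size:
        raise ValueError("edge_index length does not match selection")
    kept = [e for e, keep in zip(edge_index, result.selected_mask) if keep]
    return reduced, kept


def selection_to_rows(
    result: SelectionResult,
    edge_index: list[Edge],
    roi_labels: list[str] | None = None,
) -> list[dict]:
    """Flatten a selection result to CSV-ready rows (edge, optional ROI
    names, weight, selected flag)."""
    rows = []
    for e, w, sel in zip(edge_index, result.weights, result.selected_mask):
        lev, (a, b) = (e[0], e[1:]) if len(e) == 3 else (result.level, e)
        row = {"level": lev, "roi_a": a, "roi_b": b,
               "weight": float(w), "selected": bool(sel)}
        if roi_labels is not None:
            row["roi_a_name"] = roi_labels[a]
            row["roi_b_name"] = roi_labels[b]
        rows.append(row)
    return rows
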