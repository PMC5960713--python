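"""Repeated stratified cross-validation, metrics, model comparison and
selection-frequency analysis.

The outer protocol is a stratified 10-fold cross-validation repeated 20
times with fresh partitions (repetition ``r`` draws its partition with
seed ``base_seed + r``).  Within each outer fold, the whole pipeline —
standardisation, LASSO selection, SVM training and hyper-parameter
tuning — sees the nine training subsets only; the held-out subset is
scored once.  Six measures summarise the confusion counts: accuracy
(ACC), sensitivity (TPR), specificity (TNR), precision (PPV), negative
predictive value (NPV) and F1.  A 0/0 ratio is recorded as undefined and
excluded (with a logged count) from averages rather than imputed.

Two configurations run on identical partitions are compared with a
two-tailed paired t-test over their matched per-fold accuracies (all
repetitions pooled).  The discriminative-edge analysis counts, per level,
how often each edge received a nonzero LASSO weight across all outer
fold fits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import Grids, TrainedEnsemble, ensemble_fit, _stratified_folds
from .features import Edge, LevelFeatureSet, concat_feature_sets

logger = logging.getLogger("honfc.evaluate")

__all__ = [
    "METRIC_NAMES",
    "compute_metrics",
    "EvalConfig",
    "FoldRecord",
    "EvaluationReport",
    "run_repeated_cv",
    "concat_pipeline",
    "ComparisonResult",
    "compare_models",
    "feature_frequency",
]

METRIC_NAMES = ("ACC", "TPR", "TNR", "PPV", "NPV", "F1")


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float | None]:
    """The six confusion-count measures; a 0/0 ratio maps to ``None``."""
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0:
            raise ValueError(f"negative confusion count {name}={v}")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num, den):
        return num / den if den > 0 else None

    acc = (tp + tn) / total
    tpr = ratio(tp, tp + fn)
    tnr = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    if tpr is None or ppv is None or (ppv + tpr) == 0:
        f1 = None
    else:
        f1 = 2.0 * ppv * tpr / (ppv + tpr)
    out = {"ACC": acc, "TPR": tpr, "TNR": tnr, "PPV": ppv, "NPV": npv, "F1": f1}
    undef = [k for k, v in out.items() if v is None]
    if undef:
        logger.info("undefined metric(s) %s for counts TP=%d TN=%d FP=%d FN=%d",
                    undef, tp, tn, fp, fn)
    return out


@dataclass(frozen=True)
class EvalConfig:
    """One feature-type configuration of the repeated-CV protocol.

    ``levels`` is the subset of network levels used; ``mode`` is
    ``"ensemble"`` (one SVM per level, fused scores) or ``"concat"``
    (features concatenated, single LASSO + SVM).
    """

    levels: tuple[int, ...]
    mode: str = "ensemble"
    folds: int = 10
    repetitions: int = 20
    base_seed: int = 0
    inner_folds: int = 10
    grids: Grids = field(default_factory=Grids)

    def __post_init__(self):
        if self.mode not in ("ensemble", "concat"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "concat" and len(self.levels) < 2:
            raise ValueError("concatenation needs at least 2 levels")
        if not self.levels:
            raise ValueError("at least one level is required")

    def name(self) -> str:
        sep = "+" if self.mode == "ensemble" else "&"
        return sep.join(f"L{v}" for v in self.levels) + f":{self.mode}"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["levels"] = list(self.levels)
        d["grids"] = {"lambdas": list(self.grids.lambdas),
                      "costs": list(self.grids.costs),
                      "alphas": list(self.grids.alphas)}
        return d


@dataclass
class FoldRecord:
    repetition: int
    fold: int
    test_ids: list[str]
    tp: int
    tn: int
    fp: int
    fn: int
    metrics: dict[str, float | None]
    selected_edges: dict[int, list[Edge]]
    tuned_lambda: float
    tuned_cost: float
    fusion_weights: list[float]


@dataclass
class EvaluationReport:
    """Per-fold records plus aggregates for one configuration."""

    config: dict
    per_fold: list[FoldRecord]
    aggregate: dict[str, float]
    undefined_counts: dict[str, int]
    partition_fingerprint: str
    subject_ids: list[str]

    def fold_accuracies(self) -> np.ndarray:
        return np.array([rec.metrics["ACC"] for rec in self.per_fold])

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for rec in d["per_fold"]:
            rec["selected_edges"] = {
                str(k): [list(e) for e in v]
                for k, v in rec["selected_edges"].items()
            }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        folds = [
            FoldRecord(**{
                **rec,
                "selected_edges": {
                    int(k): [tuple(e) for e in v]
                    for k, v in rec["selected_edges"].items()
                },
            })
            for rec in d["per_fold"]
        ]
        return cls(config=d["config"], per_fold=folds,
                   aggregate=d["aggregate"],
                   undefined_counts=d["undefined_counts"],
                   partition_fingerprint=d["partition_fingerprint"],
                   subject_ids=d["subject_ids"])

    def metrics_frame(self) -> pd.DataFrame:
        """One row per repetition x fold with counts and metrics."""
        rows = []
        for rec in self.per_fold:
            row = {"configuration": self.config.get("name", ""),
                   "repetition": rec.repetition, "fold": rec.fold,
                   "TP": rec.tp, "TN": rec.tn, "FP": rec.fp, "FN": rec.fn}
            row.update({k: (np.nan if v is None else v)
                        for k, v in rec.metrics.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _partition_fingerprint(partitions: list[list[list[str]]]) -> str:
    payload = json.dumps(partitions, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    return tp, tn, fp, fn


def run_repeated_cv(
    feature_sets: Mapping[int, LevelFeatureSet],
    config: EvalConfig,
) -> EvaluationReport:
    """Repeated stratified k-fold evaluation of one configuration.

    The report is a pure function of ``feature_sets`` and ``config``:
    running twice with the same base seed gives identical output.
    """
    sets = {lev: feature_sets[lev] for lev in config.levels}
    base = sets[config.levels[0]]
    y, ids = base.labels, base.subject_ids
    n = len(ids)
    min_class = min(int((y == c).sum()) for c in np.unique(y))
    if min_class < config.folds:
        raise ValueError(
            f"cohort too small for stratified {config.folds}-fold CV: "
            f"minority class has {min_class} subjects "
            f"(needs >= {config.folds})"
        )
    if config.mode == "concat":
        concat = concat_feature_sets(sets, list(config.levels))
        fit_sets: Mapping = {0: concat}

    records: list[FoldRecord] = []
    partitions: list[list[list[str]]] = []
    for rep in range(config.repetitions):
        rep_seed = config.base_seed + rep
        folds = _stratified_folds(y, config.folds, rep_seed)
        partitions.append([sorted(ids[i] for i in te) for _, te in folds])
        for f_idx, (tr, te) in enumerate(folds):
            inner_seed = (rep_seed * 1009 + f_idx) % (2 ** 31 - 1)
            if config.mode == "ensemble":
                train = {lev: sets[lev].subset(tr) for lev in config.levels}
                test_x = {lev: sets[lev].features[te] for lev in config.levels}
            else:
                train = {0: fit_sets[0].subset(tr)}
                test_x = {0: fit_sets[0].features[te]}
            model = ensemble_fit(train, grids=config.grids,
                                 inner_folds=config.inner_folds,
                                 seed=inner_seed)
            # leakage audit: the fitted model must never have seen a
            # held-out subject
            train_seen = set(model.metadata["training_ids"])
            held_out = [ids[i] for i in te]
            assert not train_seen.intersection(held_out), \
                "held-out subject leaked into training"
            _, pred = model.predict(test_x)
            tp, tn, fp, fn = _confusion(y[te], pred)
            selected: dict[int, list[Edge]] = {}
            for lev_key, lm in zip(model.levels, model.level_models):
                src = train[lev_key]
                edges = [e for e, keep in
                         zip(src.edge_index, lm.selection.selected_mask)
                         if keep]
                if config.mode == "concat":
                    by_level: dict[int, list[Edge]] = {}
                    for lev_tag, a, b in edges:
                        by_level.setdefault(lev_tag, []).append((a, b))
                    for k, v in by_level.items():
                        selected.setdefault(k, []).extend(v)
                else:
                    selected[lev_key] = edges
            records.append(FoldRecord(
                repetition=rep, fold=f_idx, test_ids=held_out,
                tp=tp, tn=tn, fp=fp, fn=fn,
                metrics=compute_metrics(tp, tn, fp, fn),
                selected_edges=selected,
                tuned_lambda=model.tuned_lambda[model.levels[0]],
                tuned_cost=model.tuned_cost[model.levels[0]],
                fusion_weights=np.asarray(model.fusion_weights).tolist(),
            ))
        # per repetition the test folds must partition the cohort
        covered = [sid for _, te in folds for sid in (ids[i] for i in te)]
        assert sorted(covered) == sorted(ids), "folds do not partition cohort"

    aggregate: dict[str, float] = {}
    undefined: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = [rec.metrics[name] for rec in records]
        defined = [v for v in vals if v is not None]
        undefined[name] = len(vals) - len(defined)
        aggregate[name] = float(np.mean(defined)) if defined else float("nan")
    n_undef = sum(undefined.values())
    if n_undef:
        logger.info("excluded %d undefined metric value(s) from averages",
                    n_undef)

    cfg = config.to_dict()
    cfg["name"] = config.name()
    return EvaluationReport(
        config=cfg,
        per_fold=records,
        aggregate=aggregate,
        undefined_counts=undefined,
        partition_fingerprint=_partition_fingerprint(partitions),
        subject_ids=list(ids),
    )


def concat_pipeline(
    feature_sets: Mapping[int, LevelFeatureSet],
    levels: list[int],
    config: EvalConfig | None = None,
    **kw,
) -> EvaluationReport:
    """Feature-concatenation baseline: the named levels are joined
    column-wise, a single LASSO and a single linear SVM are fit, under
    the same repeated-CV protocol."""
    if config is None:
        config = EvalConfig(levels=tuple(levels), mode="concat", **kw)
    else:
        config = replace(config, levels=tuple(levels), mode="concat")
    return run_repeated_cv(feature_sets, config)


@dataclass
class ComparisonResult:
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool  # all paired differences identical (zero variance)


def compare_models(report_a: EvaluationReport,
                   report_b: EvaluationReport) -> ComparisonResult:
    """Two-tailed paired t-test over matched per-fold accuracies.

    Both reports must come from runs over identical partitions (same
    subjects, same base seed), so that fold accuracies pair one-to-one.
    Zero-variance differences are flagged degenerate with p = 1.
    """
    if report_a.partition_fingerprint != report_b.partition_fingerprint:
        raise ValueError("reports were produced on different partitions; "
                         "paired comparison is invalid")
    a = report_a.fold_accuracies()
    b = report_b.fold_accuracies()
    if a.shape != b.shape:
        raise ValueError("reports hold different numbers of folds")
    diff = a - b
    if np.allclose(diff.std(ddof=0), 0.0):
        return ComparisonResult(t_statistic=0.0, p_value=1.0,
                                n_pairs=a.size, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return ComparisonResult(t_statistic=float(t), p_value=float(p),
                            n_pairs=a.size, degenerate=False)


def feature_frequency(
    report: EvaluationReport,
    top_n: int = 10,
    roi_labels: list[str] | None = None,
) -> dict[int, pd.DataFrame]:
    """Per level, the edges ranked by how often they were selected over
    all folds x repetitions (ties broken lexicographically by edge
    index).  Returns the top ``top_n`` rows per level."""
    counters: dict[int, Counter] = {}
    for rec in report.per_fold:
        for lev, edges in rec.selected_edges.items():
            counters.setdefault(lev, Counter()).update(edges)
    out: dict[int, pd.DataFrame] = {}
    for lev in sorted(counters):
        items = sorted(counters[lev].items(), key=lambda kv: (-kv[1], kv[0]))
        rows = []
        for (a, b), count in items[:top_n]:
            row = {"level": lev, "roi_a": a, "roi_b": b, "frequency": count}
            if roi_labels is not None:
                row["roi_a_name"] = roi_labels[a]
                row["roi_b_name"] = roi_labels[b]
            rows.append(row)
        out[lev] = pd.DataFrame(rows)
    return out
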