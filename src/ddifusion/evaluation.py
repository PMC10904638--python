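"""Cross-validation protocol, negative sampling, metrics and ablations.

The evaluation unit is the labeled drug *pair* (the setting is
transductive: every drug is in the graph at training time, only pair labels
are held out).  Binary runs balance the known interactions with an equal
number of uniformly sampled unconnected pairs; each CV fold rebuilds the
topology view from training pairs only before training a fresh model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .featurization import FeatureMatrix
from .graph_views import InteractionDataset
from .pair_classifier import (
    ABLATION_VARIANTS,
    DualViewModel,
    FoldSpec,
    TrainConfig,
    train,
)

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "make_folds",
    "sample_negatives",
    "compute_metrics",
    "mean_report",
    "cross_validate",
    "run_ablation",
]


@dataclass
class SplitPlan:
    """k disjoint test folds that partition the sample index set."""

    folds: list[np.ndarray]
    seed: int
    stratified: bool = False

    def __post_init__(self) -> None:
        self.folds = [np.asarray(f, dtype=np.int64) for f in self.folds]
        all_idx = np.concatenate(self.folds) if self.folds else np.array([], dtype=np.int64)
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("folds overlap")

    @property
    def k(self) -> int:
        return len(self.folds)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, test_indices) for one fold."""
        test = self.folds[fold]
        train_idx = np.concatenate([f for i, f in enumerate(self.folds) if i != fold])
        return np.sort(train_idx), np.sort(test)


@dataclass
class MetricsReport:
    """Metric values for one prediction set (or, with ``folds`` filled, the
    per-fold reports plus their mean in ``overall``)."""

    task: str
    overall: dict[str, float | None]
    per_class: dict[int, dict[str, float | None]] = field(default_factory=dict)
    folds: list["MetricsReport"] | None = None
    n_samples: int = 0


def make_folds(
    n_samples: int,
    k: int,
    seed: int,
    labels: Sequence[int] | None = None,
) -> SplitPlan:
    """Random (optionally label-stratified) partition into ``k`` near-equal
    folds (sizes differ by at most 1).

    Stratification deals each label's shuffled samples cyclically across
    folds with a running pointer, so it degrades gracefully for labels rarer
    than ``k``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_samples:
        raise ValueError(f"cannot make {k} folds from {n_samples} samples")
    rng = np.random.default_rng(seed)
    buckets: list[list[int]] = [[] for _ in range(k)]
    if labels is None:
        order = rng.permutation(n_samples)
        for ptr, idx in enumerate(order):
            buckets[ptr % k].append(int(idx))
        stratified = False
    else:
        labels = np.asarray(labels)
        if labels.shape != (n_samples,):
            raise ValueError("labels must align with samples")
        ptr = int(rng.integers(k))
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            for idx in rng.permutation(members):
                buckets[ptr % k].append(int(idx))
                ptr += 1
        stratified = True
    folds = [np.sort(np.asarray(b, dtype=np.int64)) for b in buckets]
    return SplitPlan(folds=folds, seed=seed, stratified=stratified)


def sample_negatives(
    positives: Iterable[tuple[int, int]] | np.ndarray,
    n_drugs: int,
    ratio: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Uniformly sample unordered non-self drug pairs absent from
    ``positives`` (ratio x the positive count, no duplicates,
    seed-reproducible)."""
    pos = np.asarray(list(map(tuple, positives)) if not isinstance(positives, np.ndarray) else positives)
    pos = np.sort(pos.reshape(-1, 2), axis=1)
    pos_codes = set((pos[:, 0] * n_drugs + pos[:, 1]).tolist())
    n_pos = len(pos_codes)
    needed = int(round(ratio * len(pos)))
    total_candidates = n_drugs * (n_drugs - 1) // 2 - n_pos
    if needed > total_candidates:
        raise ValueError(
            f"cannot sample {needed} negatives: only {total_candidates} unconnected pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen: set[int] = set()
    if needed > 0.3 * total_candidates:
        ii, jj = np.triu_indices(n_drugs, k=1)
        codes = ii * n_drugs + jj
        candidates = np.array([c for c in codes.tolist() if c not in pos_codes], dtype=np.int64)
        picked = rng.choice(candidates, size=needed, replace=False)
        chosen = set(picked.tolist())
    else:
        while len(chosen) < needed:
            batch = max(256, 2 * (needed - len(chosen)))
            i = rng.integers(0, n_drugs, size=batch)
            j = rng.integers(0, n_drugs, size=batch)
            lo, hi = np.minimum(i, j), np.maximum(i, j)
            for code in (lo * n_drugs + hi)[lo != hi].tolist():
                if code not in pos_codes and code not in chosen:
                    chosen.add(code)
                    if len(chosen) == needed:
                        break
    out = np.array(sorted(chosen), dtype=np.int64)
    return np.column_stack([out // n_drugs, out % n_drugs])


def _binary_metrics(y: np.ndarray, scores: np.ndarray) -> dict[str, float | None]:
    pred = (scores >= 0.5).astype(int)
    out: dict[str, float | None] = {"ACC": float((pred == y).mean())}
    if len(np.unique(y)) < 2:
        out["AUC"] = None
        out["AUCPR"] = None
    else:
        out["AUC"] = float(roc_auc_score(y, scores))
        out["AUCPR"] = float(average_precision_score(y, scores))
    return out


def _multiclass_metrics(
    y: np.ndarray, scores: np.ndarray
) -> tuple[dict[str, float | None], dict[int, dict[str, float | None]]]:
    n_types = scores.shape[1]
    pred = scores.argmax(axis=1)
    present = np.unique(y)
    p_mac, r_mac, f_mac, _ = precision_recall_fscore_support(
        y, pred, labels=present, average="macro", zero_division=0
    )
    p_mic, r_mic, f_mic, _ = precision_recall_fscore_support(
        y, pred, average="micro", zero_division=0
    )
    onehot = np.eye(n_types)[y]
    overall: dict[str, float | None] = {
        "ACC": float((pred == y).mean()),
        "AUC_micro": float(roc_auc_score(onehot.ravel(), scores.ravel()))
        if len(present) > 1
        else None,
        "AUCPR_micro": float(average_precision_score(onehot.ravel(), scores.ravel())),
        "F1_macro": float(f_mac),
        "Pre_macro": float(p_mac),
        "Recall_macro": float(r_mac),
        "F1_micro": float(f_mic),
        "Pre_micro": float(p_mic),
        "Recall_micro": float(r_mic),
    }
    per_class: dict[int, dict[str, float | None]] = {}
    for c in present.tolist():
        y_c = (y == c).astype(int)
        pred_c = (pred == c).astype(int)
        p_c, r_c, f_c, _ = precision_recall_fscore_support(
            y_c, pred_c, average="binary", zero_division=0
        )
        per_class[int(c)] = {
            "support": int(y_c.sum()),
            "AUPR": float(average_precision_score(y_c, scores[:, c])),
            "F1": float(f_c),
        }
    return overall, per_class


def compute_metrics(y_true: np.ndarray, scores: np.ndarray, task: str) -> MetricsReport:
    """Score predictions: binary -> ACC (threshold 0.5) / AUC / AUCPR;
    multiclass -> ACC, macro P/R/F1 over present labels, micro AUC/AUCPR on
    flattened one-vs-rest scores, plus per-class AUPR and F1.

    Metrics undefined for the given label set (e.g. AUC with one class) are
    reported as ``None``, never silently as a number.
    """
    y = np.asarray(y_true, dtype=np.int64).ravel()
    scores = np.asarray(scores, dtype=np.float64)
    if task == "binary":
        scores = scores.ravel()
        if y.shape != scores.shape:
            raise ValueError("labels and scores must align")
        return MetricsReport(task=task, overall=_binary_metrics(y, scores), n_samples=len(y))
    if task == "multiclass":
        if scores.ndim != 2 or scores.shape[0] != len(y):
            raise ValueError("multiclass scores must be [m, R] aligned with labels")
        if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("multiclass score rows must be normalized")
        overall, per_class = _multiclass_metrics(y, scores)
        return MetricsReport(task=task, overall=overall, per_class=per_class, n_samples=len(y))
    raise ValueError(f"unknown task {task!r}")


def mean_report(fold_reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of fold metrics (``None`` entries skipped per metric)."""
    if not fold_reports:
        raise ValueError("no fold reports to average")
    task = fold_reports[0].task
    keys = fold_reports[0].overall.keys()
    overall: dict[str, float | None] = {}
    for key in keys:
        vals = [r.overall[key] for r in fold_reports if r.overall.get(key) is not None]
        overall[key] = float(np.mean(vals)) if vals else None
    per_class: dict[int, dict[str, float | None]] = {}
    all_classes = sorted({c for r in fold_reports for c in r.per_class})
    for c in all_classes:
        entries = [r.per_class[c] for r in fold_reports if c in r.per_class]
        per_class[c] = {
            "support": int(sum(e["support"] for e in entries)),
            "AUPR": float(np.mean([e["AUPR"] for e in entries])),
            "F1": float(np.mean([e["F1"] for e in entries])),
        }
    return MetricsReport(
        task=task,
        overall=overall,
        per_class=per_class,
        folds=list(fold_reports),
        n_samples=int(sum(r.n_samples for r in fold_reports)),
    )


def _assemble_samples(
    dataset: InteractionDataset, cfg: TrainConfig, negative_ratio: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs and labels that constitute the CV sample set for a task."""
    if cfg.task == "binary":
        negatives = sample_negatives(
            dataset.pairs, dataset.n_drugs, ratio=negative_ratio, seed=cfg.seed
        )
        pairs = np.vstack([dataset.pairs, negatives])
        labels = np.concatenate(
            [np.ones(len(dataset.pairs), dtype=np.int64), np.zeros(len(negatives), dtype=np.int64)]
        )
        return pairs, labels
    if dataset.labels is None:
        raise ValueError("multiclass evaluation needs labeled interactions")
    return dataset.pairs.copy(), dataset.labels.copy()


def cross_validate(
    dataset: InteractionDataset,
    features: FeatureMatrix,
    cfg: TrainConfig,
    n_folds: int = 5,
    negative_ratio: float = 1.0,
    return_models: bool = False,
):
    """k-fold CV of the full pipeline; the returned report carries per-fold
    metrics in ``.folds`` and their mean in ``.overall``.

    Negatives (binary task) are sampled once up front and folded together
    with the positives, so folds stay disjoint in pairs; each fold's
    topology graph is built from training pairs only.
    """
    pairs, labels = _assemble_samples(dataset, cfg, negative_ratio)
    plan = make_folds(len(pairs), n_folds, seed=cfg.seed, labels=labels)
    fold_reports: list[MetricsReport] = []
    models: list[DualViewModel] = []
    for f in range(plan.k):
        train_idx, test_idx = plan.split(f)
        fold = FoldSpec(
            train_pairs=pairs[train_idx],
            train_labels=labels[train_idx],
            test_pairs=pairs[test_idx],
            test_labels=labels[test_idx],
        )
        try:
            model, _history = train(dataset, features, cfg, fold)
        except Exception as err:
            raise RuntimeError(f"training failed in fold {f}: {err}") from err
        scores = model.predict(fold.test_pairs)
        fold_reports.append(compute_metrics(fold.test_labels, scores, cfg.task))
        if return_models:
            models.append(model)
    report = mean_report(fold_reports)
    return (report, models) if return_models else report


def run_ablation(
    variant: str,
    dataset: InteractionDataset,
    features: FeatureMatrix,
    cfg: TrainConfig,
    n_folds: int = 5,
    negative_ratio: float = 1.0,
) -> MetricsReport:
    """Cross-validate an ablated model under the otherwise identical
    protocol.

    ``without_multiscale`` classifies on the last GCN layer only;
    ``without_topology_view`` / ``without_feature_view`` keep the single
    remaining view; ``scale_only_n`` uses layer n's attention-free output.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}")
    return cross_validate(
        dataset, features, replace(cfg, variant=variant), n_folds=n_folds,
        negative_ratio=negative_ratio,
    )
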