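"""Training protocol, splits, metrics, repetition/CV drivers and sweeps.

Defaults follow the study protocol: Adam (lr 0.0025, weight decay 1e-5),
cross-entropy loss, 150 epochs, dropout 0.5, stratified 70/10/20
train/validation/test splits, checkpointing the epoch with the best
validation accuracy.  Gradient steps are full-batch at desk scale: cohorts of
a few hundred subjects fit in one batch, which removes an undocumented degree
of freedom from the protocol.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import gcn
from .fcn import (DEFAULT_THRESHOLDS, PATTERNS, PatternGraph, SrConfig,
                  build_pattern_graphs, canonicalize, granger_fcn,
                  pearson_fcn, sparse_representation_fcn, symmetrize_gcm)
from .gcn import MfcpModel, backward, forward, init_model, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "EvalMetrics",
    "RunSummary",
    "stratified_split",
    "stratified_folds",
    "prepare_arrays",
    "cohort_graphs",
    "train_model",
    "evaluate",
    "repeated_runs",
    "cross_validate",
    "ablation_study",
    "sweep_lambda",
    "sweep_threshold",
    "export_embeddings",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class TrainConfig:
    """Optimization and protocol settings."""

    learning_rate: float = 0.0025
    weight_decay: float = 1e-5
    epochs: int = 150
    dropout: float = 0.5
    batch_size: int | None = None  # None = full batch
    seed: int = 0
    train_fraction: float = 0.70
    val_fraction: float = 0.10
    test_fraction: float = 0.20
    k_folds: int = 5

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class EvalMetrics:
    """Confusion counts and derived classification metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    auc: float | None = None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.tn + self.fp + self.fn, 1)

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc}


@dataclass
class RunSummary:
    """Per-run metrics plus mean ± sample standard deviation aggregates."""

    runs: list[EvalMetrics]
    histories: list[pd.DataFrame] = field(default_factory=list)
    best_epochs: list[int] = field(default_factory=list)
    std_convention: str = "sample standard deviation (ddof=1)"

    def metric_values(self, name: str) -> np.ndarray:
        vals = [getattr(m, name) for m in self.runs]
        return np.array([v for v in vals if v is not None], dtype=float)

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for name in METRIC_NAMES:
            vals = self.metric_values(name)
            rows.append({
                "metric": name,
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "std": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Splits

def _apportion(m: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment; ties favour earlier subsets."""
    exact = [f * m for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    rem = m - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def stratified_split(labels: np.ndarray, fractions: tuple[float, float, float],
                     seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/val/test index sets, deterministic given seed.

    Within each class, subjects are shuffled and apportioned to the three
    subsets by largest remainder, so class proportions in each subset are
    within one subject of exact stratification.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(
                f"class {cls} has only {idx.size} members; need >= 3 to stratify")
        rng.shuffle(idx)
        counts = _apportion(idx.size, fractions)
        start = 0
        for part, c in zip(parts, counts):
            part.append(idx[start:start + c])
            start += c
    return tuple(np.sort(np.concatenate(p)) for p in parts)  # type: ignore[return-value]


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Stratified k-fold partition of subject indices."""
    labels = np.asarray(labels)
    smallest = min(np.sum(labels == cls) for cls in np.unique(labels))
    if k > smallest:
        raise ValueError(f"k={k} exceeds smallest class size {smallest}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].append(chunk)
    return [np.sort(np.concatenate(f)) for f in folds]


# ---------------------------------------------------------------------------
# Data marshalling

def cohort_graphs(cohort, patterns: tuple[str, ...] = PATTERNS,
                  sr_config: SrConfig | None = None, lag_order: int = 1,
                  thresholds: dict[str, float] | None = None,
                  ) -> list[dict[str, PatternGraph]]:
    """Per-subject pattern graphs for a whole cohort."""
    out = []
    for subj in cohort.subjects:
        graphs = build_pattern_graphs(subj, patterns=patterns,
                                      sr_config=sr_config, lag_order=lag_order,
                                      thresholds=thresholds)
        out.append({g.pattern: g for g in graphs})
    return out


def prepare_arrays(graphs: list[dict[str, PatternGraph]],
                   patterns: tuple[str, ...],
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Stack per-subject propagation operators and features into batch arrays."""
    batch = {}
    for pat in patterns:
        P = np.stack([gcn.propagation_operator(g[pat].adjacency) for g in graphs])
        X = np.stack([g[pat].node_features for g in graphs])
        batch[pat] = (P, X)
    return batch


def _subset(batch: dict[str, tuple[np.ndarray, np.ndarray]],
            idx: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {p: (P[idx], X[idx]) for p, (P, X) in batch.items()}


# ---------------------------------------------------------------------------
# Optimization

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.wd * p  # coupled L2, as in the reference optimizer
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flat_grads(model: MfcpModel, grads: dict) -> list[np.ndarray]:
    out = []
    for p in model.patterns:
        out.extend(grads["conv"][p])
    for W, b in grads["head"]:
        out.extend([W, b])
    return out


def _cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    probs = softmax(logits)
    m = len(labels)
    loss = float(-np.log(np.clip(probs[np.arange(m), labels], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(m), labels] -= 1.0
    return loss, dlogits / m


def train_model(graphs: list[dict[str, PatternGraph]], labels: np.ndarray,
                patterns: tuple[str, ...], config: TrainConfig,
                split: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                ) -> tuple[MfcpModel, RunSummary]:
    """Train one classifier and return the checkpointed model plus summary.

    After every epoch the model is evaluated on the validation set; the
    parameters with the highest validation accuracy are checkpointed (ties
    broken by lower validation loss, then by earlier epoch).  Fully
    reproducible given ``config.seed``: the seed drives the split, the weight
    initialization and the dropout masks through spawned substreams.
    """
    labels = np.asarray(labels, dtype=int)
    patterns = tuple(p for p in PATTERNS if p in patterns)
    root = np.random.SeedSequence(config.seed)
    ss_split, ss_init, ss_drop = root.spawn(3)
    if split is None:
        split = stratified_split(
            labels, (config.train_fraction, config.val_fraction,
                     config.test_fraction),
            seed=int(ss_split.generate_state(1)[0] % (2**31)))
    tr_idx, val_idx, te_idx = split
    if len(val_idx) == 0:
        raise ValueError("validation set is empty; cannot checkpoint")

    batch = prepare_arrays(graphs, patterns)
    feature_dim = batch[patterns[0]][1].shape[-1]
    model = init_model(patterns, feature_dim, seed=ss_init,
                       dropout_rate=config.dropout)
    drop_rng = np.random.Generator(np.random.PCG64(ss_drop))

    tr_batch, val_batch = _subset(batch, tr_idx), _subset(batch, val_idx)
    y_tr, y_val = labels[tr_idx], labels[val_idx]
    opt = _Adam(model.parameters(), config.learning_rate, config.weight_decay)

    best = None  # (acc, -loss, -epoch) maximized
    best_model = model.copy()
    best_epoch = 0
    history = []
    for epoch in range(1, config.epochs + 1):
        cache = forward(model, tr_batch, training=True, rng=drop_rng)
        loss, dlogits = _cross_entropy(cache.logits, y_tr)
        grads, _ = backward(model, cache, dlogits)
        opt.step(_flat_grads(model, grads))

        val_cache = forward(model, val_batch, training=False)
        val_loss, _ = _cross_entropy(val_cache.logits, y_val)
        val_acc = float((val_cache.logits.argmax(axis=1) == y_val).mean())
        history.append({"epoch": epoch, "train_loss": loss,
                        "val_loss": val_loss, "val_accuracy": val_acc})
        key = (val_acc, -val_loss, -epoch)
        if best is None or key > best:
            best = key
            best_model = model.copy()
            best_epoch = epoch
        logger.debug("epoch %d train_loss %.4f val_acc %.3f", epoch, loss, val_acc)

    te_metrics = evaluate(best_model, [graphs[i] for i in te_idx], labels[te_idx])
    summary = RunSummary(runs=[te_metrics],
                         histories=[pd.DataFrame(history)],
                         best_epochs=[best_epoch])
    summary.split = split  # type: ignore[attr-defined]
    return best_model, summary


# ---------------------------------------------------------------------------
# Evaluation

def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Rank-based AUC: probability a random case outranks a random control,
    ties credited 1/2.  Undefined (None) when only one class is present."""
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # mid-ranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def evaluate(model: MfcpModel, graphs: list[dict[str, PatternGraph]],
             labels: np.ndarray) -> EvalMetrics:
    """Hard predictions by arg-max score; positive class = case (label 1)."""
    labels = np.asarray(labels, dtype=int)
    batch = prepare_arrays(graphs, model.patterns)
    cache = forward(model, batch, training=False)
    preds = cache.logits.argmax(axis=1)
    scores = softmax(cache.logits)[:, 1]
    tp = int(np.sum((preds == 1) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn,
                       auc=auc_mann_whitney(scores, labels))


# ---------------------------------------------------------------------------
# Drivers

def _derive_seeds(base_seed: int, n: int) -> list[int]:
    states = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in states]


def repeated_runs(graphs: list[dict[str, PatternGraph]], labels: np.ndarray,
                  patterns: tuple[str, ...], config: TrainConfig,
                  n_repetitions: int = 30, base_seed: int | None = None,
                  ) -> RunSummary:
    """Repeat the split/train/test protocol with independent seeds.

    Each repetition draws a fresh stratified split and a fresh initialization
    (both resampled).  Aggregates report mean ± sample std (ddof=1).
    """
    if n_repetitions < 2:
        raise ValueError("n_repetitions must be >= 2")
    base = config.seed if base_seed is None else base_seed
    runs, hists, bests = [], [], []
    for seed in _derive_seeds(base, n_repetitions):
        _, summ = train_model(graphs, labels, patterns,
                              replace(config, seed=seed))
        runs.extend(summ.runs)
        hists.extend(summ.histories)
        bests.extend(summ.best_epochs)
    return RunSummary(runs=runs, histories=hists, best_epochs=bests)


def cross_validate(graphs: list[dict[str, PatternGraph]], labels: np.ndarray,
                   patterns: tuple[str, ...], config: TrainConfig,
                   k: int | None = None) -> RunSummary:
    """Stratified k-fold cross-validation.

    Within each fold 1/8 of the training portion is held out as a validation
    set for checkpoint selection, mirroring the 70/10 train/validation ratio
    of the hold-out protocol.
    """
    labels = np.asarray(labels, dtype=int)
    k = k or config.k_folds
    folds = stratified_folds(labels, k, config.seed)
    runs, hists, bests = [], [], []
    for f, test_idx in enumerate(folds):
        train_pool = np.sort(np.concatenate([folds[g] for g in range(k) if g != f]))
        val_seed = int(np.random.SeedSequence([config.seed, f]).generate_state(1)[0]
                       % (2**31))
        tr_rel, val_rel, _ = stratified_split(
            labels[train_pool], (0.875, 0.125, 0.0), seed=val_seed)
        split = (train_pool[tr_rel], train_pool[val_rel], test_idx)
        _, summ = train_model(graphs, labels, patterns,
                              replace(config, seed=config.seed + f), split=split)
        runs.extend(summ.runs)
        hists.extend(summ.histories)
        bests.extend(summ.best_epochs)
    return RunSummary(runs=runs, histories=hists, best_epochs=bests)


def pattern_subsets() -> list[tuple[str, ...]]:
    """The 7 non-empty subsets of {PC, SR, GCM} in canonical order."""
    subsets = []
    for r in (1, 2, 3):
        subsets.extend(itertools.combinations(PATTERNS, r))
    return subsets


def ablation_study(graphs: list[dict[str, PatternGraph]], labels: np.ndarray,
                   config: TrainConfig, n_repetitions: int = 1,
                   ) -> pd.DataFrame:
    """Train and evaluate all 7 pattern subsets under identical protocols.

    Every subset reuses the same seeds (hence the same data partitions); head
    widths adapt automatically to the branch count.  Returns one row per
    subset with mean ± sample-std metrics.
    """
    seeds = _derive_seeds(config.seed, n_repetitions)
    rows = []
    for subset in pattern_subsets():
        runs = []
        for seed in seeds:
            _, summ = train_model(graphs, labels, subset,
                                  replace(config, seed=seed))
            runs.extend(summ.runs)
        summary = RunSummary(runs=runs)
        row = {"patterns": "+".join(subset), "n_patterns": len(subset),
               "n_runs": len(runs)}
        for _, rec in summary.aggregate().iterrows():
            row[f"{rec['metric']}_mean"] = rec["mean"]
            row[f"{rec['metric']}_std"] = rec["std"]
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_lambda(cohort, grid: list[float], config: TrainConfig,
                 patterns: tuple[str, ...] = PATTERNS, lag_order: int = 1,
                 thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Sensitivity of classification to the SR penalty λ.

    Re-estimates the SR networks at every grid point (other patterns are
    estimated once) and retrains under the fixed seed.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    static = [p for p in patterns if p != "SR"]
    base = cohort_graphs(cohort, tuple(static), lag_order=lag_order,
                         thresholds=thresholds) if static else \
        [{} for _ in cohort.subjects]
    rows = []
    for lam in grid:
        graphs = [dict(g) for g in base]
        if "SR" in patterns:
            for g, subj in zip(graphs, cohort.subjects):
                raw = sparse_representation_fcn(subj, SrConfig(lam=lam))
                canon = canonicalize(raw, thresholds["SR"])
                g["SR"] = PatternGraph(node_features=canon.weights.copy(),
                                       adjacency=canon, pattern="SR")
        _, summ = train_model(graphs, cohort.labels, patterns, config)
        m = summ.runs[0]
        rows.append({"lambda": lam, **m.as_dict()})
    return pd.DataFrame(rows)


def sweep_threshold(cohort, pattern: str, grid: list[float],
                    config: TrainConfig, patterns: tuple[str, ...] = PATTERNS,
                    sr_config: SrConfig | None = None, lag_order: int = 1,
                    thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Sensitivity of classification to one pattern's edge threshold.

    A grid point that empties every subject's graph for the swept pattern is
    recorded as a flagged degenerate row (the model still trains on the
    edgeless graphs) instead of failing.  Because canonicalization rescales
    weights to unit maximum before thresholding, the maximum edge survives any
    threshold below 1; grid points >= 1 therefore denote the fully edge-free
    regime and are handled here rather than rejected.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if pattern not in patterns:
        raise ValueError(f"swept pattern {pattern} not in {patterns}")
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    sr_config = sr_config or SrConfig()
    static = tuple(p for p in patterns if p != pattern)
    base = cohort_graphs(cohort, static, sr_config=sr_config,
                         lag_order=lag_order, thresholds=thresholds) if static \
        else [{} for _ in cohort.subjects]
    # raw estimates for the swept pattern are reused across grid points
    raws = []
    for subj in cohort.subjects:
        if pattern == "PC":
            raws.append(pearson_fcn(subj))
        elif pattern == "SR":
            raws.append(sparse_representation_fcn(subj, sr_config))
        else:
            raws.append(symmetrize_gcm(granger_fcn(subj, lag_order)))
    rows = []
    import warnings as _warnings
    for theta in grid:
        graphs = [dict(g) for g in base]
        empty = 0
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for g, raw in zip(graphs, raws):
                if theta >= 1.0:
                    canon = canonicalize(raw, 0.0)
                    canon.weights[:] = 0.0
                    canon.threshold_applied = theta
                else:
                    canon = canonicalize(raw, theta)
                if canon.weights.max() == 0:
                    empty += 1
                g[pattern] = PatternGraph(node_features=canon.weights.copy(),
                                          adjacency=canon, pattern=pattern)
        degenerate = empty == len(graphs)
        _, summ = train_model(graphs, cohort.labels, patterns, config)
        m = summ.runs[0]
        rows.append({"pattern": pattern, "threshold": theta,
                     "n_empty_graphs": empty, "degenerate": degenerate,
                     **m.as_dict()})
    return pd.DataFrame(rows)


def export_embeddings(model: MfcpModel, graphs: list[dict[str, PatternGraph]],
                      subject_ids: list[str], labels: np.ndarray,
                      ) -> pd.DataFrame:
    """Fused graph-representation vectors (64·branches) per subject, eval mode."""
    batch = prepare_arrays(graphs, model.patterns)
    cache = forward(model, batch, training=False)
    fused = cache.fused
    cols = {f"e{j:03d}": fused[:, j] for j in range(fused.shape[1])}
    return pd.DataFrame({"subject_id": subject_ids,
                         "label": np.asarray(labels, dtype=int), **cols})
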