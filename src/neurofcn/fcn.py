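"""Functional connectivity network (FCN) estimation under three patterns.

Given one subject's ROI time-series matrix (t time points × n ROIs) this
module estimates three complementary weighted networks over the ROIs:

* **PC** — full Pearson correlation between regional series (synchronous
  co-fluctuation).
* **SR** — sparse representation: each ROI's series is reconstructed from all
  other ROIs' series under an L1 penalty, so edges capture conditional
  (partial-correlation-like) dependence.
* **GCM** — pairwise Granger causality mapping: the log ratio of residual sums
  of squares between an autoregression of the target on its own lags
  (restricted) and one augmented with the candidate driver's lags
  (unrestricted), symmetrized by the magnitude of the bidirectional sum.

All raw estimates pass through a common canonicalization — symmetrize, take
magnitudes, zero the diagonal, rescale to unit maximum, threshold — yielding
non-negative symmetric weighted adjacencies suitable for spectral graph
convolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

PATTERNS = ("PC", "SR", "GCM")
#: per-pattern default canonicalization thresholds (sensitivity-analysis optima)
DEFAULT_THRESHOLDS = {"PC": 0.1, "SR": 0.2, "GCM": 0.2}

__all__ = [
    "PATTERNS",
    "DEFAULT_THRESHOLDS",
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "DirectedCausality",
    "SrConfig",
    "PatternGraph",
    "pearson_fcn",
    "sparse_representation_fcn",
    "granger_fcn",
    "symmetrize_gcm",
    "canonicalize",
    "build_pattern_graphs",
]


@dataclass
class RoiTimeSeries:
    """One subject's regional BOLD-like signals (t time points × n ROIs)."""

    values: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D t×n matrix")
        t, n = self.values.shape
        if t < 3 or n < 2:
            raise ValueError(f"need t >= 3 and n >= 2, got t={t}, n={n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite entries")
        if len(self.roi_labels) != n:
            raise ValueError(f"{len(self.roi_labels)} ROI labels for {n} columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """An n×n weighted adjacency tagged with its estimation pattern.

    ``canonical`` marks matrices that satisfy the adjacency contract used by
    the graph network: symmetric, entrywise non-negative, zero diagonal.
    """

    weights: np.ndarray
    pattern: str
    roi_labels: list[str]
    canonical: bool = False
    threshold_applied: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("connectivity weights contain non-finite entries")
        if self.canonical:
            if not np.allclose(self.weights, self.weights.T):
                raise ValueError("canonical matrix must be symmetric")
            if np.any(self.weights < 0) or np.any(np.diag(self.weights) != 0):
                raise ValueError("canonical matrix must be non-negative with zero diagonal")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass
class DirectedCausality:
    """Directed Granger strengths; entry (i, j) is G_{i->j}."""

    strengths: np.ndarray
    lag_order: int
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        if not np.all(np.isfinite(self.strengths)):
            raise ValueError("causality strengths contain non-finite entries")
        if np.any(np.diag(self.strengths) != 0):
            raise ValueError("diagonal must be zero")


@dataclass
class SrConfig:
    """Sparse-representation solver settings.

    ``lam`` is the L1 penalty weight on the objective
    ``||x_i - X_{-i} w||^2 + lam * ||w||_1`` (default 1, the
    sensitivity-analysis optimum).
    """

    lam: float = 1.0
    max_iterations: int = 500
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class PatternGraph:
    """Node-feature matrix plus canonical adjacency for one pattern.

    Under the connectivity-profile convention the node features are the rows
    of the canonical adjacency, so the feature width equals n.
    """

    node_features: np.ndarray
    adjacency: ConnectivityMatrix
    pattern: str

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        if not self.adjacency.canonical:
            raise ValueError("PatternGraph requires a canonical adjacency")
        if self.node_features.shape[0] != self.adjacency.n_rois:
            raise ValueError("feature rows must align with adjacency rows")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


# ---------------------------------------------------------------------------
# Pearson correlation pattern

def pearson_fcn(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Full-correlation network: w_ij is the centered cosine of series i, j.

    A zero-variance ROI cannot be correlated; its off-diagonal weights are set
    to 0 and a warning names the ROI.
    """
    x = ts.values
    centered = x - x.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    flat = norms == 0
    if np.any(flat):
        names = [ts.roi_labels[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"zero-variance ROI(s) {names}: correlations set to 0")
        logger.warning("zero-variance ROI(s) %s in subject %s", names, ts.subject_id)
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe
    w = unit.T @ unit
    w[flat, :] = 0.0
    w[:, flat] = 0.0
    np.fill_diagonal(w, 1.0)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(weights=w, pattern="PC", roi_labels=ts.roi_labels)


# ---------------------------------------------------------------------------
# Sparse representation pattern

def _lasso_cd(G: np.ndarray, c: np.ndarray, lam: float, max_iter: int,
              tol: float) -> tuple[np.ndarray, bool, list[float], float]:
    """Cyclic coordinate descent for min_w w'Gw - 2c'w + lam*||w||_1 (+ const).

    G = X'X, c = X'y.  Soft-thresholds each coordinate at lam/2 (the objective
    carries no 1/2 factor).  Returns (w, converged, per-sweep objectives offset
    by the constant y'y, final max coefficient change).
    """
    p = G.shape[0]
    w = np.zeros(p)
    diag = np.diag(G).copy()
    degenerate = diag <= 0
    diag[degenerate] = 1.0
    grad = -2.0 * c  # gradient of smooth part at w = 0 (without +2Gw term folded in)
    Gw = np.zeros(p)
    objs: list[float] = []
    converged = False
    delta = np.inf
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if degenerate[j]:
                continue
            # partial residual correlation: c_j - sum_{k != j} G_jk w_k
            rho = c[j] - (Gw[j] - G[j, j] * w[j])
            new = np.sign(rho) * max(abs(rho) - lam / 2.0, 0.0) / diag[j]
            if new != w[j]:
                Gw += G[:, j] * (new - w[j])
                delta = max(delta, abs(new - w[j]))
                w[j] = new
        objs.append(float(w @ Gw - 2.0 * c @ w + lam * np.sum(np.abs(w))))
        if delta < tol:
            converged = True
            break
    return w, converged, objs, delta


def sr_objective(x_target: np.ndarray, design: np.ndarray, w: np.ndarray,
                 lam: float) -> float:
    """Reconstruction objective ||x_target - design @ w||^2 + lam*||w||_1."""
    resid = x_target - design @ w
    return float(resid @ resid + lam * np.sum(np.abs(w)))


def sparse_representation_fcn(ts: RoiTimeSeries,
                              config: SrConfig | None = None,
                              ) -> ConnectivityMatrix:
    """Sparse-representation network via per-ROI L1-penalized regression.

    Row i of the returned (asymmetric) matrix minimizes
    ``||x_i - sum_{j != i} W_ij x_j||^2 + lam * sum_{j != i} |W_ij|``
    by cyclic coordinate descent; the per-sweep objective is non-increasing.
    Non-convergence is reported through the ``converged`` flag and a warning,
    never an exception.
    """
    config = config or SrConfig()
    x = ts.values
    n = ts.n_rois
    G_full = x.T @ x
    W = np.zeros((n, n))
    all_converged = True
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        G = G_full[np.ix_(others, others)]
        c = G_full[others, i]
        w, conv, objs, delta = _lasso_cd(G, c, config.lam,
                                         config.max_iterations,
                                         config.tolerance)
        if len(objs) > 1:
            # CD guarantees monotone descent; guard against numerical slip
            drift = max(b - a for a, b in zip(objs, objs[1:]))
            if drift > 1e-8 * max(1.0, abs(objs[0])):
                logger.warning("SR objective increased by %g for ROI %d", drift, i)
        if not conv:
            all_converged = False
            warnings.warn(
                f"SR solver did not converge for ROI {ts.roi_labels[i]} "
                f"(last max coefficient change {delta:.2e})")
        W[i, others] = w
    return ConnectivityMatrix(weights=W, pattern="SR", roi_labels=ts.roi_labels,
                              converged=all_converged)


# ---------------------------------------------------------------------------
# Granger causality mapping

_GCM_CAP = 30.0  # cap for ln(RSS ratio) when the unrestricted fit is exact


def _lagged(y: np.ndarray, lag: int) -> np.ndarray:
    """Columns y_{t-1} ... y_{t-lag} aligned to the common effective sample."""
    t = len(y)
    return np.column_stack([y[lag - k - 1:t - k - 1] for k in range(lag)])


def _ols_rss(Z: np.ndarray, y: np.ndarray) -> float:
    """RSS of least squares y ~ Z, ridge-stabilized against collinearity.

    Normal equations get a jitter of 1e-8 × mean(diag(Z'Z)) on the diagonal,
    which leaves well-conditioned problems untouched to ~1e-7 relative error.
    """
    G = Z.T @ Z
    jitter = 1e-8 * max(np.mean(np.diag(G)), 1e-12)
    beta = np.linalg.solve(G + jitter * np.eye(G.shape[0]), Z.T @ y)
    resid = y - Z @ beta
    return float(resid @ resid)


def granger_fcn(ts: RoiTimeSeries, lag_order: int = 1) -> DirectedCausality:
    """Pairwise Granger causality G_{x->y} = ln(RSS_restricted / RSS_unrestricted).

    For each ordered ROI pair the restricted model regresses y_t on an
    intercept and its own ``lag_order`` lags; the unrestricted model adds the
    same lags of x.  Both are fitted over the common effective sample of
    t − lag_order points, so the RSS ratio is >= 1 up to solver tolerance and
    the strength is non-negative.  Degenerate cases: a zero-variance target
    yields 0 with a warning; an exactly-fitting unrestricted model is capped.
    """
    if lag_order < 1:
        raise ValueError("lag_order must be >= 1")
    t, n = ts.values.shape
    if t <= 2 * lag_order + 2:
        raise ValueError(f"need t > 2*lag_order + 2 = {2 * lag_order + 2}, got t={t}")
    x = ts.values
    G = np.zeros((n, n))
    ones = np.ones(t - lag_order)
    lagged = [_lagged(x[:, j], lag_order) for j in range(n)]
    targets = [x[:, j][lag_order:] for j in range(n)]
    variances = x.var(axis=0)
    rss_restricted = np.empty(n)
    for j in range(n):
        if variances[j] == 0:
            rss_restricted[j] = np.nan
            continue
        rss_restricted[j] = _ols_rss(np.column_stack([ones, lagged[j]]), targets[j])
    for j in range(n):  # target
        if variances[j] == 0:
            warnings.warn(f"constant target ROI {ts.roi_labels[j]}: Granger strengths set to 0")
            continue
        for i in range(n):  # source
            if i == j:
                continue
            Z = np.column_stack([ones, lagged[j], lagged[i]])
            rss_u = _ols_rss(Z, targets[j])
            if rss_u <= 0 or rss_restricted[j] / max(rss_u, 1e-300) > np.exp(_GCM_CAP):
                warnings.warn(
                    f"exact unrestricted fit for {ts.roi_labels[i]}->"
                    f"{ts.roi_labels[j]}; strength capped at {_GCM_CAP}")
                G[i, j] = _GCM_CAP
            else:
                G[i, j] = max(np.log(rss_restricted[j] / rss_u), 0.0)
    return DirectedCausality(strengths=G, lag_order=lag_order,
                             roi_labels=list(ts.roi_labels))


def symmetrize_gcm(dc: DirectedCausality) -> ConnectivityMatrix:
    """Undirected aggregate A_ij = |G_{i->j} + G_{j->i}|, zero diagonal."""
    G = dc.strengths
    A = np.abs(G + G.T)
    np.fill_diagonal(A, 0.0)
    labels = dc.roi_labels or [f"ROI{i:03d}" for i in range(A.shape[0])]
    return ConnectivityMatrix(weights=A, pattern="GCM", roi_labels=labels)


# ---------------------------------------------------------------------------
# Canonicalization

def canonicalize(cm: ConnectivityMatrix, threshold: float = 0.0) -> ConnectivityMatrix:
    """Normalize a raw estimate into a non-negative symmetric adjacency.

    Steps, in order: symmetrize by (W + W')/2, take absolute values, zero the
    diagonal, rescale so the maximum entry is 1 (when positive), then zero all
    entries strictly below ``threshold`` keeping surviving weights.  Idempotent
    at a fixed threshold.  A matrix emptied by the threshold is returned with a
    warning rather than rejected.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    w = np.asarray(cm.weights, dtype=float)
    w = (w + w.T) / 2.0
    w = np.abs(w)
    np.fill_diagonal(w, 0.0)
    mx = w.max()
    if mx > 0:
        w = w / mx
    if threshold > 0:
        w[w < threshold] = 0.0
    if w.max() == 0:
        warnings.warn(
            f"{cm.pattern} adjacency is empty after thresholding at {threshold}")
    return ConnectivityMatrix(weights=w, pattern=cm.pattern,
                              roi_labels=cm.roi_labels, canonical=True,
                              threshold_applied=threshold,
                              converged=cm.converged)


# ---------------------------------------------------------------------------
# Assembly

def _estimate_raw(ts: RoiTimeSeries, pattern: str, sr_config: SrConfig,
                  lag_order: int) -> ConnectivityMatrix:
    if pattern == "PC":
        return pearson_fcn(ts)
    if pattern == "SR":
        return sparse_representation_fcn(ts, sr_config)
    if pattern == "GCM":
        return symmetrize_gcm(granger_fcn(ts, lag_order))
    raise ValueError(f"unknown pattern {pattern!r}")


def build_pattern_graphs(
    ts: RoiTimeSeries,
    patterns: tuple[str, ...] = PATTERNS,
    sr_config: SrConfig | None = None,
    lag_order: int = 1,
    thresholds: dict[str, float] | None = None,
) -> list[PatternGraph]:
    """Estimate, canonicalize and package the requested pattern graphs.

    Node features are the rows of the canonical adjacency (each node's
    connectivity profile).  Graphs are returned in the fixed order PC, SR,
    GCM regardless of the order patterns were requested in.
    """
    if not patterns:
        raise ValueError("at least one pattern must be requested")
    unknown = set(patterns) - set(PATTERNS)
    if unknown:
        raise ValueError(f"unknown pattern(s) {sorted(unknown)}")
    sr_config = sr_config or SrConfig()
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    graphs = []
    for pattern in PATTERNS:
        if pattern not in patterns:
            continue
        raw = _estimate_raw(ts, pattern, sr_config, lag_order)
        canon = canonicalize(raw, thresholds[pattern])
        graphs.append(PatternGraph(node_features=canon.weights.copy(),
                                   adjacency=canon, pattern=pattern))
    return graphs
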