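"""Node-level Grad-CAM attribution over the final graph-convolution layer.

For a trained model and one subject, let H (n ROIs × 32 channels) be a
branch's final post-ReLU node feature map, taken just before readout pooling.
With y_c the pre-softmax logit of the target class, channel weights are the
node-averaged gradients

    alpha_k = (1/n) * sum_i  d y_c / d H_{i,k},

and the importance of ROI i is the rectified channel-weighted sum

    S_i = ReLU( sum_k alpha_k * H_{i,k} ),

normalized within the subject by its maximum so scores lie in [0, 1].  A
subject whose scores are rectified entirely to zero is returned unnormalized
with a degenerate flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcn import PatternGraph
from .gcn import MfcpModel, backward, forward
from .training import prepare_arrays

__all__ = [
    "NodeImportance",
    "gradcam_node_importance",
    "top_k_rois",
    "importance_report",
]

CLASS_NAMES = {0: "control", 1: "case"}


@dataclass
class NodeImportance:
    """Per-ROI Grad-CAM scores for one subject, pattern and target class."""

    scores: np.ndarray
    pattern: str
    target_class: int
    subject_id: str
    roi_labels: list[str]
    normalized: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0):
            raise ValueError("Grad-CAM scores must be non-negative")


def gradcam_node_importance(model: MfcpModel,
                            subject_graphs: dict[str, PatternGraph],
                            target_class: int = 1,
                            subject_id: str = "",
                            ) -> dict[str, NodeImportance]:
    """Per-branch ROI importance maps for one subject (eval mode).

    Gradients of the target-class logit with respect to each branch's final
    conv-layer features come from the network's own backward pass, so the
    attribution is exact and deterministic.
    """
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 (control) or 1 (case)")
    batch = prepare_arrays([subject_graphs], model.patterns)
    cache = forward(model, batch, training=False)
    dlogits = np.zeros_like(cache.logits)
    dlogits[0, target_class] = 1.0
    _, dH2 = backward(model, cache, dlogits)
    out = {}
    for pat in model.patterns:
        H = cache.branch[pat]["H2"][0]          # (n, 32)
        grad = dH2[pat][0]                      # d y_c / d H
        alpha = grad.mean(axis=0)               # node-averaged channel weights
        s = np.maximum(H @ alpha, 0.0)
        mx = s.max()
        if mx > 0:
            out[pat] = NodeImportance(scores=s / mx, pattern=pat,
                                      target_class=target_class,
                                      subject_id=subject_id,
                                      roi_labels=subject_graphs[pat].adjacency.roi_labels)
        else:
            out[pat] = NodeImportance(scores=s, pattern=pat,
                                      target_class=target_class,
                                      subject_id=subject_id,
                                      roi_labels=subject_graphs[pat].adjacency.roi_labels,
                                      normalized=False, degenerate=True)
    return out


def top_k_rois(importances: list[NodeImportance], k: int = 5) -> pd.DataFrame:
    """Rank ROIs by mean normalized score across subjects (one pattern).

    Ties are broken by ROI index (lower index first).  Returns the k
    highest-mean ROIs with labels, mean scores and 1-based ranks.
    """
    if not importances:
        raise ValueError("need at least one importance map")
    labels = importances[0].roi_labels
    for imp in importances:
        if imp.roi_labels != labels:
            raise ValueError("inconsistent ROI labels across subjects")
    mean = np.mean([imp.scores for imp in importances], axis=0)
    order = sorted(range(len(mean)), key=lambda i: (-mean[i], i))[:k]
    return pd.DataFrame({
        "roi_label": [labels[i] for i in order],
        "roi_index": order,
        "mean_score": [float(mean[i]) for i in order],
        "rank": np.arange(1, len(order) + 1),
    })


def importance_report(per_pattern: dict[str, list[NodeImportance]],
                      k: int = 5) -> dict:
    """Top-k ROI tables per pattern plus pairwise top-k set overlaps.

    The overlap statistic (|top-k(p) ∩ top-k(q)|) quantifies how much the
    discriminative regions differ between connection patterns.
    """
    tables = {pat: top_k_rois(imps, k=k) for pat, imps in per_pattern.items()}
    pats = sorted(tables)
    overlaps = []
    for i, p in enumerate(pats):
        for q in pats[i + 1:]:
            shared = set(tables[p]["roi_label"]) & set(tables[q]["roi_label"])
            overlaps.append({"pattern_a": p, "pattern_b": q,
                             "overlap": len(shared),
                             "shared_rois": sorted(shared)})
    return {"top_k": tables, "k": k, "pairwise_overlap": pd.DataFrame(overlaps)}
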