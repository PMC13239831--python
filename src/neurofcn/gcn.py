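"""Multi-branch first-order spectral graph convolutional classifier.

One branch per connection pattern.  Each branch propagates node features with
the renormalized operator P = D̂^{-1/2}(A + I)D̂^{-1/2} through two 32-unit
graph convolution layers (bias-free, ReLU), then pools node embeddings with a
mean‖max readout into a 64-vector.  Branch embeddings are concatenated in the
fixed order PC, SR, GCM and classified by a three-layer fully connected head
(64·branches → 32 → 16 → 2, ReLU, dropout 0.5 after the first two layers
during training).

Implemented directly on numpy arrays with hand-derived backward passes: the
model is tiny, the arithmetic is exact and dependency-free, and having the
explicit chain rule makes the gradient-based node attribution in
:mod:`neurofcn.interpret` a byproduct of the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcn import ConnectivityMatrix, PatternGraph

CONV_WIDTH = 32
READOUT_WIDTH = 2 * CONV_WIDTH  # mean ‖ max
HEAD_HIDDEN = (32, 16)
N_CLASSES = 2

__all__ = [
    "CONV_WIDTH",
    "READOUT_WIDTH",
    "MfcpModel",
    "ForwardCache",
    "propagation_operator",
    "normalized_laplacian",
    "branch_forward",
    "readout",
    "forward",
    "backward",
    "init_model",
    "softmax",
]


def propagation_operator(adjacency: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Renormalized propagation operator D̂^{-1/2}(A + I)D̂^{-1/2}.

    Self-loops guarantee strictly positive degrees, so the operator is always
    defined; it is symmetric with eigenvalues in [-1, 1].
    """
    A = adjacency.weights if isinstance(adjacency, ConnectivityMatrix) else np.asarray(adjacency, float)
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def normalized_laplacian(adjacency: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian I - D^{-1/2} A D^{-1/2}.

    Exposed as a derived quantity; propagation itself uses the self-loop
    renormalized operator.  Zero-degree nodes contribute identity rows.
    """
    A = adjacency.weights if isinstance(adjacency, ConnectivityMatrix) else np.asarray(adjacency, float)
    deg = A.sum(axis=1)
    inv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return np.eye(A.shape[0]) - A * inv[:, None] * inv[None, :]


@dataclass
class MfcpModel:
    """Weights of the multi-branch GCN plus fused classifier head.

    ``conv_weights[pattern] = [W0 (f×32), W1 (32×32)]`` per branch (bias-free);
    ``head`` holds three (W, b) affine layers with widths
    64·branches → 32 → 16 → 2.
    """

    patterns: tuple[str, ...]
    conv_weights: dict[str, list[np.ndarray]]
    head: list[tuple[np.ndarray, np.ndarray]]
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= len(self.patterns) <= 3:
            raise ValueError("model supports 1-3 branches")
        expect = READOUT_WIDTH * len(self.patterns)
        if self.head[0][0].shape[0] != expect:
            raise ValueError(
                f"head input width {self.head[0][0].shape[0]} != 64 x branches = {expect}")

    @property
    def fused_dim(self) -> int:
        return READOUT_WIDTH * len(self.patterns)

    def parameters(self) -> list[np.ndarray]:
        params = []
        for p in self.patterns:
            params.extend(self.conv_weights[p])
        for W, b in self.head:
            params.extend([W, b])
        return params

    def copy(self) -> "MfcpModel":
        return MfcpModel(
            patterns=self.patterns,
            conv_weights={p: [w.copy() for w in ws]
                          for p, ws in self.conv_weights.items()},
            head=[(W.copy(), b.copy()) for W, b in self.head],
            dropout_rate=self.dropout_rate,
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(patterns: tuple[str, ...], feature_dim: int,
               seed: int | np.random.SeedSequence = 0,
               dropout_rate: float = 0.5) -> MfcpModel:
    """Glorot-uniform initialization from a single seeded generator."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    conv = {p: [_glorot(rng, feature_dim, CONV_WIDTH),
                _glorot(rng, CONV_WIDTH, CONV_WIDTH)] for p in patterns}
    widths = [READOUT_WIDTH * len(patterns), *HEAD_HIDDEN, N_CLASSES]
    head = [(_glorot(rng, widths[i], widths[i + 1]), np.zeros(widths[i + 1]))
            for i in range(3)]
    return MfcpModel(patterns=tuple(patterns), conv_weights=conv, head=head,
                     dropout_rate=dropout_rate)


# ---------------------------------------------------------------------------
# Forward pass (batched over subjects: leading axis m)

@dataclass
class ForwardCache:
    """Intermediate activations needed by the backward pass."""

    inputs: dict[str, tuple[np.ndarray, np.ndarray]]  # pattern -> (P, X)
    branch: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    fused: np.ndarray | None = None
    head_pre: list[np.ndarray] = field(default_factory=list)
    head_act: list[np.ndarray] = field(default_factory=list)
    drop_masks: list[np.ndarray | None] = field(default_factory=list)
    logits: np.ndarray | None = None


def branch_forward(P: np.ndarray, X: np.ndarray, W0: np.ndarray,
                   W1: np.ndarray) -> np.ndarray:
    """Two-layer graph convolution ReLU(P ReLU(P X W0) W1); accepts a batch."""
    if X.shape[-1] != W0.shape[0]:
        raise ValueError(
            f"feature width {X.shape[-1]} does not match W0 rows {W0.shape[0]}")
    H1 = np.maximum(P @ X @ W0, 0.0)
    return np.maximum(P @ H1 @ W1, 0.0)


def readout(node_embeddings: np.ndarray) -> np.ndarray:
    """Mean‖max pooling of node embeddings into a 2d-vector (d=32 → 64)."""
    H = np.asarray(node_embeddings, dtype=float)
    if H.shape[-2] < 1:
        raise ValueError("readout requires at least one node")
    return np.concatenate([H.mean(axis=-2), H.max(axis=-2)], axis=-1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(model: MfcpModel, batch: dict[str, tuple[np.ndarray, np.ndarray]],
            training: bool = False,
            rng: np.random.Generator | None = None) -> ForwardCache:
    """Full multi-branch forward pass.

    ``batch[pattern] = (P, X)`` with P of shape (m, n, n) and X of shape
    (m, n, f).  Dropout (inverted scaling) is applied after the first two head
    layers only when ``training`` is true; eval mode is fully deterministic.
    """
    missing = set(model.patterns) - set(batch)
    if missing:
        raise ValueError(f"batch missing pattern(s) {sorted(missing)}")
    cache = ForwardCache(inputs=batch)
    embeddings = []
    for pat in model.patterns:
        P, X = batch[pat]
        W0, W1 = model.conv_weights[pat]
        S0 = P @ X @ W0
        H1 = np.maximum(S0, 0.0)
        PH1 = P @ H1
        S1 = PH1 @ W1
        H2 = np.maximum(S1, 0.0)
        r = readout(H2)
        cache.branch[pat] = {"S0": S0, "H1": H1, "PH1": PH1, "S1": S1,
                             "H2": H2,
                             "argmax": H2.argmax(axis=-2)}
        embeddings.append(r)
    z = np.concatenate(embeddings, axis=-1)
    cache.fused = z
    h = z
    for layer, (W, b) in enumerate(model.head):
        pre = h @ W + b
        cache.head_pre.append(pre)
        if layer < 2:
            h = np.maximum(pre, 0.0)
            if training and model.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training-mode dropout requires an rng")
                keep = 1.0 - model.dropout_rate
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                cache.drop_masks.append(mask)
            else:
                cache.drop_masks.append(None)
        else:
            h = pre
        cache.head_act.append(h)
    cache.logits = h
    return cache


# ---------------------------------------------------------------------------
# Backward pass

def backward(model: MfcpModel, cache: ForwardCache, dlogits: np.ndarray,
             ) -> tuple[dict, dict[str, np.ndarray]]:
    """Backpropagate ``dlogits`` (m×2) through head, readout and branches.

    Returns ``(grads, dH2)`` where ``grads`` mirrors the model structure
    (summed over the batch) and ``dH2[pattern]`` is the gradient with respect
    to each branch's final post-ReLU node feature map — the quantity the
    Grad-CAM attribution consumes.
    """
    head_grads: list[tuple[np.ndarray, np.ndarray]] = [None] * 3  # type: ignore
    dh = dlogits
    for layer in (2, 1, 0):
        W, b = model.head[layer]
        inp = cache.fused if layer == 0 else cache.head_act[layer - 1]
        dW = inp.reshape(-1, inp.shape[-1]).T @ dh.reshape(-1, dh.shape[-1])
        db = dh.reshape(-1, dh.shape[-1]).sum(axis=0)
        head_grads[layer] = (dW, db)
        dinp = dh @ W.T
        if layer > 0:
            mask = cache.drop_masks[layer - 1]
            if mask is not None:
                dinp = dinp * mask
            dinp = dinp * (cache.head_pre[layer - 1] > 0)
        dh = dinp
    dz = dh  # gradient wrt fused embedding (m, 64*branches)

    conv_grads: dict[str, list[np.ndarray]] = {}
    dH2_out: dict[str, np.ndarray] = {}
    for k, pat in enumerate(model.patterns):
        dr = dz[..., k * READOUT_WIDTH:(k + 1) * READOUT_WIDTH]
        br = cache.branch[pat]
        H2 = br["H2"]
        m, n, d = H2.shape
        dmean = dr[..., :CONV_WIDTH]
        dmax = dr[..., CONV_WIDTH:]
        dH2 = np.repeat(dmean[:, None, :], n, axis=1) / n
        # max routes gradient to the first argmax node per channel
        idx = br["argmax"]  # (m, d)
        rows = np.arange(m)[:, None]
        cols = np.arange(d)[None, :]
        scatter = np.zeros_like(dH2)
        scatter[rows, idx, cols] = dmax
        dH2 = dH2 + scatter
        dH2_out[pat] = dH2

        P, X = cache.inputs[pat]
        W0, W1 = model.conv_weights[pat]
        dS1 = dH2 * (br["S1"] > 0)
        dW1 = np.einsum("mnd,mne->de", br["PH1"], dS1)
        dH1 = (P.transpose(0, 2, 1) @ dS1) @ W1.T
        dS0 = dH1 * (br["S0"] > 0)
        PX = P @ X
        dW0 = np.einsum("mnf,mnd->fd", PX, dS0)
        conv_grads[pat] = [dW0, dW1]
    grads = {"conv": conv_grads, "head": head_grads}
    return grads, dH2_out
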