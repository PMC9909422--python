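"""Losses and the semi-supervised training loop.

The objective is L = L_lab + lam * L_unlab: mean-over-views cross-entropy on
the labeled samples plus a consistency penalty, the squared L2 distance of
every view's prediction from the sharpened mean prediction (treated as a
constant target, i.e. detached).  Optimisation is full-batch Adam with
hand-written backpropagation through the MLP, the propagation operator, the
DropNode masks and the masked gene layer; the analytic gradients are checked
against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import HiRANDParams, _activation, _softmax, init_params
from .io_graphs import LabelSet

__all__ = [
    "HiRANDConfig",
    "LossBreakdown",
    "TrainHistory",
    "sharpen",
    "supervised_loss",
    "consistency_loss",
    "total_loss",
    "loss_and_gradients",
    "train_model",
]

_EPS = 1e-12


@dataclass
class HiRANDConfig:
    """Hyperparameters of the network and its training loop."""

    S: int = 4
    delta: float = 0.5
    K: int = 1
    T: float = 0.5
    lam: float = 1.0
    hidden: tuple = (128,)
    activation: str = "tanh"
    lr: float = 1e-3
    epochs: int = 200
    weight_decay: float = 5e-4
    seed: int = 0
    scale_dropnode: bool = False
    normalization: str = "sym"
    variant: str = "average"
    consistency_all: bool = True  # printed-index sum over all n; False -> unlabeled only
    lam_warmup: int = 0  # epochs of linear ramp of lam from 0 (0 = no warm-up)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if not 0.0 < self.T <= 1.0:
            raise ValueError("T must lie in (0, 1]")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class LossBreakdown:
    lab: float
    unlab: float
    lam: float

    @property
    def total(self) -> float:
        return self.lab + self.lam * self.unlab


TrainHistory = list  # list[LossBreakdown], one per epoch


def sharpen(Zbar: np.ndarray, T: float) -> np.ndarray:
    """Temperature sharpening: raise each row to the power 1/T and renormalise.

    T = 1 is the identity; T -> 0 approaches the one-hot argmax.  Output rows
    sum to 1 and never have higher entropy than the input rows.
    """
    if not 0.0 < T <= 1.0:
        raise ValueError("T must lie in (0, 1]")
    Z = np.asarray(Zbar, dtype=float)
    if np.any(Z.sum(axis=1) <= 0):
        raise ValueError("sharpen needs rows with positive mass")
    p = np.clip(Z, _EPS, None) ** (1.0 / T)
    return p / p.sum(axis=1, keepdims=True)


def _labeled_info(Y) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a LabelSet / int-vector-with-minus-ones into (labeled_idx, labels)."""
    if isinstance(Y, LabelSet):
        y = Y.labels
    else:
        y = np.asarray(Y, dtype=int)
    idx = np.flatnonzero(y >= 0)
    if idx.size == 0:
        raise ValueError("no labeled samples")
    return idx, y[idx]


def supervised_loss(per_view, Y) -> float:
    """Mean over views of the summed cross-entropy over labeled samples."""
    idx, lab = _labeled_info(Y)
    S = len(per_view)
    loss = 0.0
    for Z in per_view:
        p = np.clip(Z[idx, lab], _EPS, 1.0)
        loss += -np.log(p).sum()
    return loss / S


def consistency_loss(per_view, sharpened: np.ndarray, include_idx=None) -> float:
    """Mean over views of the summed squared L2 distance to the sharpened centre."""
    S = len(per_view)
    loss = 0.0
    for Z in per_view:
        if Z.shape != sharpened.shape:
            raise ValueError("view and sharpened-target shapes differ")
        d = sharpened - Z
        if include_idx is not None:
            d = d[include_idx]
        loss += (d * d).sum()
    return loss / S


def total_loss(lab: float, unlab: float, lam: float) -> LossBreakdown:
    if lab < 0 or unlab < 0:
        raise ValueError("loss components must be nonnegative")
    return LossBreakdown(float(lab), float(unlab), float(lam))


# ---------------------------------------------------------------------------
# backprop engine


def loss_and_gradients(X: np.ndarray, A_gene: np.ndarray, Abar: np.ndarray,
                       y: np.ndarray, params: HiRANDParams, cfg: HiRANDConfig,
                       masks: np.ndarray, target: np.ndarray | None = None):
    """One full forward/backward pass with the given per-view DropNode masks.

    ``masks`` is S x n in {0,1}.  ``target``, if given, is used as the
    (constant) sharpened consistency target; otherwise it is computed from
    this pass's mean prediction and detached.

    Returns (LossBreakdown, grads: HiRANDParams, per_view list).
    """
    act, act_grad = _activation(cfg.activation)
    n, g = X.shape
    S = masks.shape[0]
    lab_idx, lab = _labeled_info(y)
    if cfg.consistency_all:
        cons_idx = None
    else:
        cons_idx = np.flatnonzero(np.asarray(y) < 0)

    scale = 1.0 / (1.0 - cfg.delta) if (cfg.scale_dropnode and cfg.delta < 1.0) else 1.0

    # forward, caching per-view activations
    G0 = X @ (A_gene * params.W0)
    H1 = act(G0)
    caches = []
    per_view = []
    L = len(params.mlp_weights)
    for s in range(S):
        m = masks[s] * scale
        V = m[:, None] * H1
        P = Abar @ V
        acts = [P]
        zs = []
        a = P
        for l, (W, b) in enumerate(zip(params.mlp_weights, params.mlp_biases)):
            z = a @ W + b
            zs.append(z)
            a = act(z) if l < L - 1 else z
            acts.append(a)
        Z = _softmax(a)
        per_view.append(Z)
        caches.append((m, acts, zs))

    center = np.mean(per_view, axis=0)
    sharp = sharpen(center, cfg.T) if target is None else target

    loss_lab = supervised_loss(per_view, y)
    loss_unlab = consistency_loss(per_view, sharp, include_idx=cons_idx)
    breakdown = total_loss(loss_lab, loss_unlab, cfg.lam)

    # backward
    gW = [np.zeros_like(W) for W in params.mlp_weights]
    gb = [np.zeros_like(b) for b in params.mlp_biases]
    dH1 = np.zeros_like(H1)
    Y_onehot = np.zeros((lab_idx.size, center.shape[1]))
    Y_onehot[np.arange(lab_idx.size), lab] = 1.0

    for s in range(S):
        Z = per_view[s]
        m, acts, zs = caches[s]
        # cross-entropy through softmax on labeled rows
        dlogits = np.zeros_like(Z)
        dlogits[lab_idx] = (Z[lab_idx] - Y_onehot) / S
        # consistency (sharpened target constant) through the softmax Jacobian
        dZ = np.zeros_like(Z)
        rows = slice(None) if cons_idx is None else cons_idx
        dZ[rows] = (2.0 * cfg.lam / S) * (Z[rows] - sharp[rows])
        dlogits += Z * (dZ - (dZ * Z).sum(axis=1, keepdims=True))

        da = dlogits
        for l in range(L - 1, -1, -1):
            if l < L - 1:
                da = da * act_grad(zs[l], acts[l + 1])
            gW[l] += acts[l].T @ da
            gb[l] += da.sum(axis=0)
            da = da @ params.mlp_weights[l].T
        dV = Abar.T @ da
        dH1 += m[:, None] * dV

    dG0 = dH1 * act_grad(G0, H1)
    gW0 = A_gene * (X.T @ dG0)
    return breakdown, HiRANDParams(gW0, gW, gb), per_view


class _Adam:
    def __init__(self, shapes, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, tensors, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (x, gx) in enumerate(zip(tensors, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * gx
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * gx * gx
            x -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def _flatten(params: HiRANDParams):
    return [params.W0, *params.mlp_weights, *params.mlp_biases]


def train_model(X, A_gene: np.ndarray, Abar: np.ndarray, y,
                cfg: HiRANDConfig) -> tuple[HiRANDParams, TrainHistory]:
    """Full-batch semi-supervised training; deterministic given cfg.seed.

    ``y`` holds 0/1 labels with -1 for unlabeled samples; ``Abar`` is the
    precomputed mixed-order propagation matrix of the sample graph.  Fresh
    DropNode masks are drawn every epoch for each of the S views.
    """
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    lab_idx, lab = _labeled_info(y)
    if np.unique(lab).size < 2:
        raise ValueError("labeled samples must cover both classes")
    rng = np.random.default_rng(cfg.seed)
    params = init_params(g, cfg.hidden, cfg.n_classes, rng)
    tensors = _flatten(params)
    opt = _Adam([t.shape for t in tensors], cfg.lr)
    n_weights = 1 + len(params.mlp_weights)  # W0 + MLP weights get weight decay

    history: TrainHistory = []
    for epoch in range(cfg.epochs):
        if cfg.lam_warmup > 0:
            from dataclasses import replace
            lam_t = cfg.lam * min(1.0, epoch / cfg.lam_warmup)
            cfg_t = replace(cfg, lam=lam_t, lam_warmup=0)
        else:
            cfg_t = cfg
        masks = (rng.random((cfg.S, n)) >= cfg.delta).astype(float)
        breakdown, grads, _ = loss_and_gradients(X, A_gene, Abar, y, params, cfg_t, masks)
        if not np.isfinite(breakdown.total):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: lab={breakdown.lab}, "
                f"unlab={breakdown.unlab}")
        gtensors = _flatten(grads)
        for i in range(n_weights):  # L2 weight decay on weights, not biases
            gtensors[i] = gtensors[i] + cfg.weight_decay * tensors[i]
        opt.step(tensors, gtensors)
        history.append(breakdown)
    return params, history
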