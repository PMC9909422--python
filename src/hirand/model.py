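"""The HiRAND network: gene-masked graph convolution, DropNode random
propagation over the sample graph, MLP head, and gene importance scores.

Two graphs are convolved in order.  The gene layer H1 = act(X (A_g * W0))
aggregates expression along the gene interaction graph through an
elementwise-masked trainable weight matrix, which doubles as a feature
selector: the importance of gene j is the normalised mass of |W0| on its
incident edges.  The sample layer zeroes whole sample rows with Bernoulli
masks (DropNode) and diffuses the survivors over the kNN sample-similarity
graph with a mixed-order propagation matrix, producing S stochastic views of
the data whose predictions are tied together by a consistency loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io_graphs import GeneGraph, SampleGraph, ExpressionMatrix, build_sample_graph, mixed_order_matrix

__all__ = [
    "HiRANDParams",
    "PredictionSet",
    "ImportanceScores",
    "gene_selection_forward",
    "importance_scores",
    "drop_node",
    "random_propagation",
    "mlp_forward",
    "init_params",
    "forward_train",
    "forward_inference",
    "HiRANDClassifier",
]

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
}


def _activation(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}, got {name!r}")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _as_adjacency(G) -> np.ndarray:
    if isinstance(G, GeneGraph):
        return G.adjacency
    return np.asarray(G, dtype=float)


@dataclass
class HiRANDParams:
    """All trainable tensors: the gene-layer weight and the MLP affine stack."""

    W0: np.ndarray
    mlp_weights: list
    mlp_biases: list

    def copy(self) -> "HiRANDParams":
        return HiRANDParams(self.W0.copy(),
                            [w.copy() for w in self.mlp_weights],
                            [b.copy() for b in self.mlp_biases])


@dataclass
class PredictionSet:
    """Per-view prediction matrices with their centre and sharpened centre."""

    per_view: list
    center: np.ndarray
    sharpened: np.ndarray


@dataclass
class ImportanceScores:
    """Nonnegative per-gene scores summing to 1, aligned to ``gene_ids``."""

    scores: np.ndarray
    gene_ids: list | None = None

    def top(self, n: int) -> list:
        order = np.argsort(-self.scores, kind="stable")[:n]
        if self.gene_ids is None:
            return order.tolist()
        return [self.gene_ids[i] for i in order]


def init_params(g: int, hidden, C: int, rng: np.random.Generator) -> HiRANDParams:
    """Symmetric-uniform fan-in initialisation of W0 and the MLP stack."""
    W0 = rng.uniform(-1.0, 1.0, size=(g, g)) / np.sqrt(g)
    widths = [g, *hidden, C]
    weights, biases = [], []
    for fin, fout in zip(widths[:-1], widths[1:]):
        lim = 1.0 / np.sqrt(fin)
        weights.append(rng.uniform(-lim, lim, size=(fin, fout)))
        biases.append(np.zeros(fout))
    return HiRANDParams(W0, weights, biases)


def gene_selection_forward(X, G, W0: np.ndarray, activation: str = "tanh") -> np.ndarray:
    """Gene-graph convolution H1 = act(X (A_g * W0)); output is n x g."""
    Xv = _as_matrix(X)
    A = _as_adjacency(G)
    if A.shape != W0.shape or Xv.shape[1] != A.shape[0]:
        raise ValueError(
            f"shape mismatch: X {Xv.shape}, adjacency {A.shape}, W0 {W0.shape}")
    act, _ = _activation(activation)
    return act(Xv @ (A * W0))


def importance_scores(W0: np.ndarray, G) -> ImportanceScores:
    """Gene importance I_j = sum_i A_ij |W0_ij| / sum_ij A_ij |W0_ij|.

    A gene with no |W| mass on its incident edges scores exactly 0; the
    vector sums to 1.
    """
    A = _as_adjacency(G)
    if A.shape != W0.shape:
        raise ValueError("adjacency and W0 shapes differ")
    mass = A * np.abs(W0)
    total = mass.sum()
    if total == 0:
        raise ValueError("all masked weights are zero; importance undefined")
    scores = mass.sum(axis=0) / total
    gene_ids = G.gene_ids if isinstance(G, GeneGraph) else None
    return ImportanceScores(scores, gene_ids)


def drop_node(H: np.ndarray, delta: float, rng, scale: bool = False) -> np.ndarray:
    """Zero whole sample rows with independent Bernoulli(1-delta) keep masks.

    No rescaling by default (inference uses the full features); ``scale=True``
    divides kept rows by 1-delta so the expectation matches the clean input.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("drop rate delta must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mask = (rng.random(H.shape[0]) >= delta).astype(float)
    if scale and delta < 1.0:
        mask = mask / (1.0 - delta)
    return mask[:, None] * H


def random_propagation(H_masked: np.ndarray, SG, K: int, normalization: str = "sym") -> np.ndarray:
    """Diffuse masked features over the sample graph: Abar @ H, weight-free.

    ``SG`` may be a SampleGraph or a precomputed propagation matrix.
    """
    if isinstance(SG, SampleGraph):
        if SG.n_samples != H_masked.shape[0]:
            raise ValueError("sample graph size does not match feature matrix")
        Abar = mixed_order_matrix(SG, K, normalization=normalization)
    else:
        Abar = np.asarray(SG, dtype=float)
        if Abar.shape[0] != H_masked.shape[0]:
            raise ValueError("propagation matrix size does not match feature matrix")
    return Abar @ H_masked


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def mlp_forward(H2: np.ndarray, params: HiRANDParams, activation: str = "tanh") -> np.ndarray:
    """MLP with activated hidden layers and a row-softmax output."""
    act, _ = _activation(activation)
    a = H2
    L = len(params.mlp_weights)
    for l, (W, b) in enumerate(zip(params.mlp_weights, params.mlp_biases)):
        z = a @ W + b
        a = act(z) if l < L - 1 else z
    return _softmax(a)


def forward_train(X, G, SG, params: HiRANDParams, config) -> PredictionSet:
    """S stochastic augmented views -> S prediction matrices + centre + sharpened centre."""
    from .train import sharpen  # local import to avoid a module cycle

    rng = np.random.default_rng(config.seed)
    H1 = gene_selection_forward(X, G, params.W0, config.activation)
    Abar = SG if isinstance(SG, np.ndarray) else mixed_order_matrix(
        SG, config.K, normalization=config.normalization, variant=config.variant)
    per_view = []
    for _ in range(config.S):
        H1d = drop_node(H1, config.delta, rng, scale=config.scale_dropnode)
        H2 = Abar @ H1d
        per_view.append(mlp_forward(H2, params, config.activation))
    center = np.mean(per_view, axis=0)
    return PredictionSet(per_view, center, sharpen(center, config.T))


def forward_inference(X, G, SG, params: HiRANDParams, config) -> np.ndarray:
    """Deterministic pass: gene layer -> propagation of undropped features -> MLP."""
    H1 = gene_selection_forward(X, G, params.W0, config.activation)
    Abar = SG if isinstance(SG, np.ndarray) else mixed_order_matrix(
        SG, config.K, normalization=config.normalization, variant=config.variant)
    return mlp_forward(Abar @ H1, params, config.activation)


# ---------------------------------------------------------------------------
# sklearn estimator


class HiRANDClassifier(BaseEstimator, ClassifierMixin):
    """Semi-supervised graph-random-network classifier.

    Fit on an n x g matrix with labels in {0, 1} and ``-1`` for unlabeled
    samples (the convention of sklearn's label-propagation estimators).  The
    gene interaction graph, if any, is passed as ``gene_adjacency``; without
    one the gene layer degenerates to a per-gene trainable scaling (identity
    adjacency).  The sample similarity graph is built internally from the
    training matrix.

    Training minimises cross-entropy on the labeled subset plus ``lam`` times
    a consistency penalty pulling every stochastic view towards the sharpened
    mean prediction.  ``augmentation=False`` removes the augmentation layer
    entirely (single deterministic view, no DropNode, no propagation).

    Prediction is transductive for the samples seen at fit time; new samples
    are scored by rebuilding the similarity graph over the union of fitted
    and new rows and running the deterministic forward pass.

    Parameters
    ----------
    S : number of stochastic augmentations per step (default 4).
    delta : DropNode drop rate in [0, 1] (default 0.5).
    K : propagation order; the mixed-order matrix averages adjacency powers
        0..K (default 1).
    T : sharpening temperature in (0, 1]; smaller pushes the consistency
        target towards one-hot (default 0.5).
    lam : weight of the consistency loss (default 1.0).
    hidden : MLP hidden widths (default (128,)).
    k_neighbors, mu : sample-graph kNN size and kernel scale (10, 0.5).

    Attributes
    ----------
    params_ : fitted :class:`HiRANDParams`.
    importance_ : :class:`ImportanceScores` from the trained gene layer.
    feature_importances_ : its raw score vector (sums to 1).
    history_ : per-epoch loss breakdown list.
    transduction_proba_ : class probabilities for the fitted samples.
    """

    def __init__(self, gene_adjacency=None, S: int = 4, delta: float = 0.5,
                 K: int = 1, T: float = 0.5, lam: float = 1.0,
                 hidden=(128,), activation: str = "tanh", lr: float = 1e-3,
                 epochs: int = 200, weight_decay: float = 5e-4,
                 k_neighbors: int = 10, mu: float = 0.5,
                 augmentation: bool = True, scale_dropnode: bool = False,
                 normalization: str = "sym", consistency_all: bool = True,
                 lam_warmup: int = 0, random_state: int = 0):
        self.gene_adjacency = gene_adjacency
        self.S = S
        self.delta = delta
        self.K = K
        self.T = T
        self.lam = lam
        self.hidden = hidden
        self.activation = activation
        self.lr = lr
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.k_neighbors = k_neighbors
        self.mu = mu
        self.augmentation = augmentation
        self.scale_dropnode = scale_dropnode
        self.normalization = normalization
        self.consistency_all = consistency_all
        self.lam_warmup = lam_warmup
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _config(self):
        from .train import HiRANDConfig

        if self.augmentation:
            S, delta, K = self.S, self.delta, self.K
        else:  # ablation: augmentation layer removed
            S, delta, K = 1, 0.0, 0
        return HiRANDConfig(S=S, delta=delta, K=K, T=self.T, lam=self.lam,
                            hidden=tuple(self.hidden), activation=self.activation,
                            lr=self.lr, epochs=self.epochs,
                            weight_decay=self.weight_decay,
                            seed=self.random_state,
                            scale_dropnode=self.scale_dropnode,
                            normalization=self.normalization,
                            consistency_all=self.consistency_all,
                            lam_warmup=self.lam_warmup)

    def _gene_adjacency(self, g: int) -> np.ndarray:
        A = self.gene_adjacency
        if A is None:
            return np.eye(g)
        A = _as_adjacency(A)
        if A.shape != (g, g):
            raise ValueError(f"gene_adjacency is {A.shape}, expected ({g}, {g})")
        return A

    def _graph(self, values: np.ndarray):
        k = min(self.k_neighbors, values.shape[0] - 1)
        return build_sample_graph(values, k=k, mu=self.mu)

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        from .train import train_model

        Xv = check_array(_as_matrix(X))
        y = np.asarray(y)
        if y.shape[0] != Xv.shape[0]:
            raise ValueError("X and y length mismatch")
        y = y.astype(int)
        labeled = y[y >= 0]
        if labeled.size == 0:
            raise ValueError("need at least one labeled sample (y >= 0)")
        if not np.isin(labeled, (0, 1)).all():
            raise ValueError("labels must be 0/1 with -1 for unlabeled")
        if np.unique(labeled).size < 2:
            raise ValueError("labeled subset must contain both classes")

        cfg = self._config()
        A_gene = self._gene_adjacency(Xv.shape[1])
        SG = self._graph(Xv)
        Abar = mixed_order_matrix(SG, cfg.K, normalization=cfg.normalization)
        params, history = train_model(Xv, A_gene, Abar, y, cfg)

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = Xv.shape[1]
        self.X_fit_ = Xv
        self.gene_adjacency_ = A_gene
        self.sample_graph_ = SG
        self.params_ = params
        self.history_ = history
        self.config_ = cfg
        self.importance_ = importance_scores(params.W0, A_gene)
        if isinstance(self.gene_adjacency, GeneGraph):
            self.importance_.gene_ids = self.gene_adjacency.gene_ids
        self.feature_importances_ = self.importance_.scores
        self.transduction_proba_ = forward_inference(Xv, A_gene, Abar, params, cfg)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        Xv = check_array(_as_matrix(X))
        if Xv.shape == self.X_fit_.shape and np.array_equal(Xv, self.X_fit_):
            return self.transduction_proba_
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        combined = np.vstack([self.X_fit_, Xv])
        SG = self._graph(combined)
        Abar = mixed_order_matrix(SG, self.config_.K,
                                  normalization=self.config_.normalization)
        Z = forward_inference(combined, self.gene_adjacency_, Abar,
                              self.params_, self.config_)
        return Z[self.X_fit_.shape[0]:]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def score(self, X, y, sample_weight=None) -> float:
        from sklearn.metrics import accuracy_score
        return accuracy_score(y, self.predict(X), sample_weight=sample_weight)

    # -- checkpointing ----------------------------------------------------

    def save(self, path) -> None:
        """Write fitted tensors to a single .npz archive with a JSON config sidecar."""
        import json
        from pathlib import Path

        check_is_fitted(self, "params_")
        path = Path(path)
        arrays = {"W0": self.params_.W0, "X_fit": self.X_fit_,
                  "gene_adjacency": self.gene_adjacency_}
        for i, (W, b) in enumerate(zip(self.params_.mlp_weights,
                                       self.params_.mlp_biases)):
            arrays[f"mlp_W{i}"] = W
            arrays[f"mlp_b{i}"] = b
        np.savez(path, **arrays)
        params = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in self.get_params().items() if k != "gene_adjacency"}
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(params, fh, indent=2)

    @classmethod
    def load(cls, path) -> "HiRANDClassifier":
        """Restore a fitted classifier from :meth:`save` output."""
        import json
        from pathlib import Path

        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            params = json.load(fh)
        params["hidden"] = tuple(params["hidden"])
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        clf = cls(gene_adjacency=data["gene_adjacency"], **params)
        n_layers = sum(1 for k in data.files if k.startswith("mlp_W"))
        restored = HiRANDParams(data["W0"],
                                [data[f"mlp_W{i}"] for i in range(n_layers)],
                                [data[f"mlp_b{i}"] for i in range(n_layers)])
        Xv = data["X_fit"]
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = Xv.shape[1]
        clf.X_fit_ = Xv
        clf.gene_adjacency_ = data["gene_adjacency"]
        clf.params_ = restored
        clf.history_ = []
        clf.config_ = clf._config()
        clf.sample_graph_ = clf._graph(Xv)
        Abar = mixed_order_matrix(clf.sample_graph_, clf.config_.K,
                                  normalization=clf.config_.normalization)
        clf.importance_ = importance_scores(restored.W0, clf.gene_adjacency_)
        clf.feature_importances_ = clf.importance_.scores
        clf.transduction_proba_ = forward_inference(Xv, clf.gene_adjacency_,
                                                    Abar, restored, clf.config_)
        return clf
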