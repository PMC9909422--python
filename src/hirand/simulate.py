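"""Synthetic benchmark data with graph-structured covariance and a planted sparse signal.

The generator builds a scale-free (preferential-attachment) feature graph,
turns shortest-path distances D into a covariance Sigma_ij = base^D_ij, draws
multivariate Gaussian expression profiles, and derives a binary outcome from
a sparse linear predictor pushed through a fixed nonlinear link and
thresholded at its median.  Everything is a pure function of the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.stats import norm

from .io_graphs import ExpressionMatrix, GeneGraph

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "generate_feature_graph",
    "graph_distances",
    "distance_to_covariance",
    "sample_expression",
    "generate_outcome",
    "simulate_dataset",
    "write_dataset",
]

# offsets fanning one master seed out to the independent random stages
_SEED_GRAPH, _SEED_X, _SEED_OUTCOME = 11, 23, 37
_SEED_MOD = 2**31 - 1


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults are the benchmark conditions: 500 samples, 1000 features on a
    scale-free graph, covariance decaying 0.7 per hop, 20 true predictors
    with coefficient magnitudes in (1, 1.5), half the signs flipped.
    """

    g: int = 1000
    n: int = 500
    cov_base: float = 0.7
    n_true: int = 20
    beta_range: tuple[float, float] = (1.0, 1.5)
    neg_prob: float = 0.5
    ba_m: int = 1
    seed: int = 0
    phi: object = field(default=None, repr=False)  # CDF hook; None -> standard normal

    def __post_init__(self) -> None:
        if not 0 < self.cov_base < 1:
            raise ValueError("cov_base must lie in (0, 1)")
        if self.n_true > self.g:
            raise ValueError("n_true cannot exceed g")
        lo, hi = self.beta_range
        if lo <= 0 or hi <= lo:
            raise ValueError("beta_range must be a positive increasing interval")


@dataclass
class SimulatedDataset:
    X: ExpressionMatrix
    y: np.ndarray
    true_idx: np.ndarray
    beta: np.ndarray
    beta0: float
    feature_graph: GeneGraph
    spec: SimulationSpec


def generate_feature_graph(g: int, seed: int, m: int = 1) -> GeneGraph:
    """Scale-free feature graph via Barabasi-Albert preferential attachment.

    Returns a connected graph on ``g`` nodes with self-loops added to the
    adjacency (the convention used by the gene-selection layer).
    """
    if g < 3:
        raise ValueError("need at least 3 nodes")
    G = nx.barabasi_albert_graph(g, m, seed=int(seed) % _SEED_MOD)
    A = nx.to_numpy_array(G, nodelist=range(g))
    A = ((A + A.T) > 0).astype(float)
    np.fill_diagonal(A, 1.0)
    gene_ids = [f"gene_{i:04d}" for i in range(g)]
    return GeneGraph(A, gene_ids)


def graph_distances(G: GeneGraph) -> np.ndarray:
    """All-pairs shortest-path hop counts; errors if the graph is disconnected."""
    A = G.adjacency.copy()
    np.fill_diagonal(A, 0.0)
    D = shortest_path(sparse.csr_matrix(A), method="D", unweighted=True, directed=False)
    if not np.all(np.isfinite(D)):
        raise ValueError("feature graph is disconnected; distances undefined")
    return D.astype(int)


def distance_to_covariance(D: np.ndarray, base: float = 0.7) -> np.ndarray:
    """Sigma_ij = base ** D_ij: covariance decays geometrically with graph distance."""
    if not 0 < base < 1:
        raise ValueError("base must lie in (0, 1)")
    D = np.asarray(D)
    return np.power(float(base), D.astype(float))


def _jittered_cholesky(Sigma: np.ndarray) -> np.ndarray:
    """Cholesky factor of Sigma, adding the smallest diagonal jitter that makes it PD."""
    for eps in (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4):
        try:
            return np.linalg.cholesky(Sigma + eps * np.eye(Sigma.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance not positive definite even after 1e-4 jitter")


def sample_expression(Sigma: np.ndarray, n: int, seed: int,
                      gene_ids: list[str] | None = None) -> ExpressionMatrix:
    """Draw n i.i.d. samples from N(0, Sigma)."""
    g = Sigma.shape[0]
    L = _jittered_cholesky(np.asarray(Sigma, dtype=float))
    rng = np.random.default_rng(int(seed) % _SEED_MOD)
    X = rng.standard_normal((n, g)) @ L.T
    if gene_ids is None:
        gene_ids = [f"gene_{i:04d}" for i in range(g)]
    sample_ids = [f"sample_{i:04d}" for i in range(n)]
    return ExpressionMatrix(X, sample_ids, gene_ids)


def _inverse_link(x: np.ndarray, phi=None) -> np.ndarray:
    """Nonlinear link score (0.7*phi(tanh x) + 0.3*phi(x^2)) * (1 + e^x)^2.

    phi defaults to the standard normal CDF.  The exponent is clipped at
    +/-350 only to keep (1+e^x)^2 inside float64 range; the clip sits deep in
    the monotone tail.
    """
    cdf = norm.cdf if phi is None else phi
    xc = np.clip(x, -350.0, 350.0)
    return (0.7 * cdf(np.tanh(x)) + 0.3 * cdf(x ** 2)) * (1.0 + np.exp(xc)) ** 2


def generate_outcome(X: ExpressionMatrix | np.ndarray, spec: SimulationSpec,
                     rng: np.random.Generator | None = None):
    """Plant a sparse signal and threshold the link score at its median.

    Picks ``n_true`` feature positions uniformly, draws |beta_j| and the
    intercept from ``beta_range``, flips each coefficient's sign with
    probability ``neg_prob``, computes s_i = eta^{-1}(x_i' beta + beta0) and
    sets y_i = 1 iff s_i exceeds the median score.

    Returns (y, true_idx, beta, beta0).
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    n, g = values.shape
    if g < spec.n_true:
        raise ValueError("fewer columns than true predictors")
    if rng is None:
        rng = np.random.default_rng((spec.seed + _SEED_OUTCOME) % _SEED_MOD)
    true_idx = np.sort(rng.choice(g, size=spec.n_true, replace=False))
    lo, hi = spec.beta_range
    beta_mag = rng.uniform(lo, hi, size=spec.n_true)
    signs = np.where(rng.random(spec.n_true) < spec.neg_prob, -1.0, 1.0)
    beta = beta_mag * signs
    beta0 = float(rng.uniform(lo, hi))
    lin = values[:, true_idx] @ beta + beta0
    s = _inverse_link(lin, spec.phi)
    if np.allclose(s, s[0]):
        raise ValueError("degenerate outcome scores: all equal")
    m = float(np.median(s))
    y = (s > m).astype(int)
    return y, true_idx, beta, beta0


def simulate_dataset(spec: SimulationSpec | None = None, **kwargs) -> SimulatedDataset:
    """Run the full pipeline: graph -> distances -> covariance -> X -> outcome."""
    if spec is None:
        spec = SimulationSpec(**kwargs)
    G = generate_feature_graph(spec.g, spec.seed + _SEED_GRAPH, m=spec.ba_m)
    D = graph_distances(G)
    Sigma = distance_to_covariance(D, spec.cov_base)
    X = sample_expression(Sigma, spec.n, spec.seed + _SEED_X, gene_ids=G.gene_ids)
    y, true_idx, beta, beta0 = generate_outcome(X, spec)
    return SimulatedDataset(X, y, true_idx, beta, beta0, G, spec)


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write expression CSV, label CSV, edge-list TSV and a JSON truth file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.csv",
        "labels": out / "labels.csv",
        "edges": out / "gene_graph.tsv",
        "truth": out / "truth.json",
    }
    ds.X.to_frame().to_csv(paths["expression"])
    with open(paths["labels"], "w") as fh:
        for sid, lab in zip(ds.X.sample_ids, ds.y):
            fh.write(f"{sid},{int(lab)}\n")
    A = ds.feature_graph.adjacency
    ids = ds.feature_graph.gene_ids
    with open(paths["edges"], "w") as fh:
        ii, jj = np.nonzero(np.triu(A, k=1))
        for i, j in zip(ii, jj):
            fh.write(f"{ids[i]}\t{ids[j]}\n")
    with open(paths["truth"], "w") as fh:
        json.dump({
            "true_idx": ds.true_idx.tolist(),
            "true_genes": [ids[i] for i in ds.true_idx],
            "beta": ds.beta.tolist(),
            "beta0": ds.beta0,
            "spec": {k: v for k, v in vars(ds.spec).items() if k != "phi"},
        }, fh, indent=2)
    return paths
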