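"""Expression / graph IO and sample-similarity graph construction.

The sample graph is the backbone of the random-propagation augmentation:
samples are connected to their k most similar neighbours under a scaled
exponential kernel on cosine distance, and features are smoothed with the
average of adjacency powers 0..K (mixed-order propagation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.metrics.pairwise import cosine_distances

logger = logging.getLogger("hirand")

__all__ = [
    "ExpressionMatrix",
    "GeneGraph",
    "SampleGraph",
    "LabelSet",
    "load_expression",
    "load_gene_graph",
    "load_labels",
    "build_sample_graph",
    "mixed_order_matrix",
    "save_results",
]


@dataclass
class ExpressionMatrix:
    """An n-samples x g-genes numeric matrix with identifier indexes."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.values.shape
        if n < 2 or g < 1:
            raise ValueError(f"need n >= 2 samples and g >= 1 genes, got {n} x {g}")
        if len(self.sample_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths do not match matrix shape")
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite entry at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class GeneGraph:
    """Binary symmetric gene-gene adjacency (with self-loops) over a fixed gene order."""

    adjacency: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if A.shape[0] != len(self.gene_ids):
            raise ValueError("adjacency size does not match gene_ids")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = A

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class SampleGraph:
    """Sparse weighted kNN sample-similarity graph.

    ``similarity`` holds the scaled-exponential-kernel weights on the kept
    edges plus the unit self-similarity diagonal.
    """

    similarity: sparse.csr_matrix
    k: int
    mu: float

    @property
    def n_samples(self) -> int:
        return self.similarity.shape[0]

    def propagation(self, K: int, normalization: str = "sym", variant: str = "average") -> np.ndarray:
        """Mixed-order propagation matrix for this graph (see :func:`mixed_order_matrix`)."""
        return mixed_order_matrix(self, K, normalization=normalization, variant=variant)


@dataclass
class LabelSet:
    """Per-sample labels in {0, 1} with -1 marking unlabeled samples."""

    labels: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.labels, dtype=int)
        if not np.isin(y, (-1, 0, 1)).all():
            raise ValueError("labels must be 0, 1 or -1 (unlabeled)")
        self.labels = y

    @property
    def labeled_index(self) -> np.ndarray:
        return np.flatnonzero(self.labels >= 0)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_index.size)

    def require_both_classes(self) -> None:
        lab = self.labels[self.labeled_index]
        if lab.size == 0:
            raise ValueError("no labeled samples")
        if not (np.any(lab == 0) and np.any(lab == 1)):
            raise ValueError("labeled subset must contain both classes")


# ---------------------------------------------------------------------------
# loaders


def load_expression(path: str | Path, orientation: str = "samples_by_genes",
                    sep: str | None = None) -> ExpressionMatrix:
    """Load a delimited expression table (one header row, one id column).

    ``orientation`` says how the *file* is laid out; the returned matrix is
    always samples x genes.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    header = pd.read_csv(path, sep=sep, header=None, nrows=1).iloc[0, 1:]
    if header.duplicated().any():
        dupes = header[header.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ids in {path.name}: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path.name}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna() | df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric or missing cell in {path.name} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if orientation == "genes_by_samples":
        numeric = numeric.T
    return ExpressionMatrix(numeric.values.astype(float),
                            list(numeric.index.astype(str)),
                            list(numeric.columns.astype(str)))


def load_gene_graph(path: str | Path, gene_ids: Sequence[str], sep: str = "\t") -> GeneGraph:
    """Load a two-column edge list, restricted to ``gene_ids``, symmetrized, self-loops added.

    Edges naming genes outside ``gene_ids`` are dropped (count logged).
    """
    gene_ids = [str(g) for g in gene_ids]
    edges = pd.read_csv(path, sep=sep, header=None, usecols=[0, 1], dtype=str,
                        comment="#")
    pos = {g: i for i, g in enumerate(gene_ids)}
    g = len(gene_ids)
    A = np.eye(g)
    dropped = 0
    kept = 0
    for a, b in edges.itertuples(index=False):
        ia, ib = pos.get(str(a)), pos.get(str(b))
        if ia is None or ib is None:
            dropped += 1
            continue
        A[ia, ib] = 1.0
        A[ib, ia] = 1.0
        kept += 1
    if dropped:
        logger.warning("load_gene_graph: dropped %d edge(s) naming unknown genes", dropped)
    if kept == 0 and len(edges) > 0:
        raise ValueError("no edge endpoints intersect the provided gene ids")
    return GeneGraph(A, gene_ids)


def load_labels(path: str | Path, sample_ids: Sequence[str], sep: str = ",") -> LabelSet:
    """Load a two-column (sample id, 0/1) table; samples absent from it are unlabeled."""
    sample_ids = [str(s) for s in sample_ids]
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample id, label")
    # tolerate an optional header row
    first = df.iloc[0, 1]
    if first not in ("0", "1"):
        df = df.iloc[1:]
    y = np.full(len(sample_ids), -1, dtype=int)
    pos = {s: i for i, s in enumerate(sample_ids)}
    for sid, lab in df.iloc[:, :2].itertuples(index=False):
        i = pos.get(str(sid))
        if i is None:
            logger.warning("load_labels: unknown sample id %r skipped", sid)
            continue
        if str(lab) not in ("0", "1"):
            raise ValueError(f"label for sample {sid!r} must be 0 or 1, got {lab!r}")
        y[i] = int(lab)
    return LabelSet(y, sample_ids)


# ---------------------------------------------------------------------------
# sample graph


def _knn_similarity(values: np.ndarray, k: int, mu: float) -> np.ndarray:
    """Dense directed kNN similarity matrix (row p keeps its k best neighbours)."""
    n = values.shape[0]
    if n <= k:
        raise ValueError(f"need more samples than neighbours: n={n} <= k={k}; use a smaller k")
    norms = np.linalg.norm(values, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"sample at position {bad} has zero norm; cosine distance undefined")
    rho = cosine_distances(values)
    np.fill_diagonal(rho, 0.0)
    rho = np.clip(rho, 0.0, None)

    # k nearest neighbours by distance, excluding self; ties broken by index order
    order = np.argsort(rho, axis=1, kind="stable")
    neigh = np.empty((n, k), dtype=int)
    for p in range(n):
        row = order[p][order[p] != p]
        neigh[p] = row[:k]
    mean_rho_nn = np.take_along_axis(rho, neigh, axis=1).mean(axis=1)

    # eps_pq = [mean rho(x_p, N_p) + mean rho(x_q, N_q) + rho(x_p, x_q)] / 3
    eps = (mean_rho_nn[:, None] + mean_rho_nn[None, :] + rho) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.exp(-(rho ** 2) / (mu * eps))
    sim[rho == 0.0] = 1.0  # identical profiles: exp(0) = 1 regardless of scale

    # keep the k largest off-diagonal similarities per row, plus the unit diagonal
    kept = np.zeros_like(sim)
    for p in range(n):
        offdiag = sim[p].copy()
        offdiag[p] = -np.inf
        # argsort ascending on (-sim, index) keeps determinism on ties
        top = np.lexsort((np.arange(n), -offdiag))[:k]
        kept[p, top] = sim[p, top]
    np.fill_diagonal(kept, 1.0)
    return kept


def build_sample_graph(X: ExpressionMatrix | np.ndarray, k: int = 10, mu: float = 0.5,
                       symmetrize: bool = True, weighted: bool = True) -> SampleGraph:
    """Build the kNN sample-similarity graph.

    Sim(p, q) = exp(-rho^2(x_p, x_q) / (mu * eps_pq)) on cosine distance rho,
    with the locally adaptive scale eps_pq averaging the neighbourhood radii
    of p and q and their own distance.  Each row keeps its ``k`` strongest
    off-diagonal similarities; the final matrix is the elementwise max of the
    directed graph and its transpose (union symmetrization).

    ``weighted=False`` binarizes kept edges to 1 (the diagonal stays 1).
    ``symmetrize=False`` returns the directed graph (each row exactly ``k``
    off-diagonal nonzeros), mainly for inspection.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if mu <= 0:
        raise ValueError("mu must be positive")
    kept = _knn_similarity(values, k, mu)
    if symmetrize:
        kept = np.maximum(kept, kept.T)
    if not weighted:
        kept = (kept > 0).astype(float)
    return SampleGraph(sparse.csr_matrix(kept), k=k, mu=mu)


def mixed_order_matrix(A: SampleGraph | np.ndarray | sparse.spmatrix, K: int,
                       normalization: str = "sym", variant: str = "average") -> np.ndarray:
    """Average of the power series of the normalized sample adjacency, orders 0..K.

    With Ahat the degree-normalized similarity matrix, returns
    (1/(K+1)) * sum_{k=0..K} Ahat^k  (``variant="average"``), so each sample
    receives information from neighbours up to K hops away.  K=0 is the
    identity.  ``variant="per_term"`` weights order m by 1/(m+1) instead.

    normalization: "sym" -> D^(-1/2) S D^(-1/2) (default), "row" -> D^(-1) S
    (row-stochastic: every row of the result sums to 1), "none" -> raw S.
    """
    if K < 0:
        raise ValueError("propagation order K must be >= 0")
    S = A.similarity if isinstance(A, SampleGraph) else A
    S = np.asarray(S.todense() if sparse.issparse(S) else S, dtype=float)
    deg = S.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("sample graph has a zero-degree row")
    if normalization == "sym":
        d = 1.0 / np.sqrt(deg)
        Ahat = d[:, None] * S * d[None, :]
    elif normalization == "row":
        Ahat = S / deg[:, None]
    elif normalization == "none":
        Ahat = S
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    n = S.shape[0]
    out = np.eye(n)
    power = np.eye(n)
    for m in range(1, K + 1):
        power = power @ Ahat
        out += power if variant == "average" else power / (m + 1)
    if variant == "average":
        out /= K + 1
    elif variant != "per_term":
        raise ValueError(f"unknown variant {variant!r}")
    return out


# ---------------------------------------------------------------------------
# results


def save_results(records, path: str | Path, config: dict | None = None) -> Path:
    """Serialize experiment records to CSV with a JSON config sidecar."""
    path = Path(path)
    rows = []
    for r in records:
        if hasattr(r, "__dataclass_fields__"):
            from dataclasses import asdict
            rows.append(asdict(r))
        elif isinstance(r, dict):
            rows.append(r)
        else:
            raise TypeError(f"cannot serialize record of type {type(r).__name__}")
    df = pd.DataFrame(rows)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"n_records": len(rows), "config": config or {}}, fh, indent=2)
    return path
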