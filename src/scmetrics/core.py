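"""Core data model for integration benchmarking.

The evaluation framework compares an *unintegrated* annotated expression
matrix against an *integration output*, which may take one of three forms:

* a corrected feature matrix (cells x genes),
* a joint embedding (cells x dims), or
* an integrated k-nearest-neighbour graph.

Every metric consumes one of two canonical representations — an embedding or
a kNN graph — and this module provides the adaptation layer that derives
them from any output kind, plus the applicability table that says which
metrics can be computed for which kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

OutputKind = Literal["features", "embedding", "graph"]

#: neighbourhood size used for the metric-input graph
DEFAULT_K = 15
#: number of principal components used when reducing feature matrices
DEFAULT_N_PCS = 50

# Serialized metric names, grouped by category.
BATCH_METRICS: tuple[str, ...] = (
    "PCR_batch",
    "ASW_batch",
    "iLISI",
    "graph_connectivity",
    "kBET",
)
BIO_METRICS: tuple[str, ...] = (
    "NMI_cluster/label",
    "ARI_cluster/label",
    "ASW_label",
    "isolated_label_F1",
    "isolated_label_silhouette",
    "cLISI",
    "cell_cycle_conservation",
    "hvg_overlap",
    "trajectory",
)
ALL_METRICS: tuple[str, ...] = BATCH_METRICS + BIO_METRICS

# Metrics computable from a graph alone.
_GRAPH_METRICS = frozenset(
    {
        "graph_connectivity",
        "kBET",
        "iLISI",
        "NMI_cluster/label",
        "ARI_cluster/label",
        "cLISI",
        "isolated_label_F1",
        "trajectory",
    }
)
# Additional metrics unlocked by an embedding.
_EMBEDDING_EXTRA = frozenset(
    {
        "ASW_batch",
        "PCR_batch",
        "ASW_label",
        "isolated_label_silhouette",
        "cell_cycle_conservation",
    }
)
# Additional metrics unlocked by a corrected feature matrix.
_FEATURE_EXTRA = frozenset({"hvg_overlap"})


class ParameterError(ValueError):
    """Raised for invalid metric or graph parameters."""


class InputError(ValueError):
    """Raised for malformed input data."""


def _as_str_array(x: Sequence) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class AnnotatedMatrix:
    """Cells x features expression matrix with per-cell batch and label.

    ``values`` holds log-normalized expression (dense or CSR); ``batch``
    and ``label`` are per-cell categorical annotations (batch of origin
    and cell identity).
    """

    values: Union[np.ndarray, sp.spmatrix]
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    batch: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids)
        self.feature_ids = _as_str_array(self.feature_ids)
        self.batch = _as_str_array(self.batch)
        self.label = _as_str_array(self.label)
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise InputError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.feature_ids) != m:
            raise InputError(f"{len(self.feature_ids)} feature ids for {m} columns")
        if len(self.batch) != n or len(self.label) != n:
            raise InputError("batch/label length must match number of cells")
        if len(set(self.cell_ids)) != n:
            raise InputError("duplicated cell_ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_cells(self, mask: np.ndarray) -> "AnnotatedMatrix":
        idx = np.where(mask)[0] if mask.dtype == bool else np.asarray(mask)
        return AnnotatedMatrix(
            values=self.values[idx],
            cell_ids=self.cell_ids[idx],
            feature_ids=self.feature_ids,
            batch=self.batch[idx],
            label=self.label[idx],
        )


@dataclass
class Embedding:
    """Joint embedding, rows aligned with the cell order of the task."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise InputError("embedding must be 2-D with >= 2 dimensions")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("embedding contains non-finite coordinates")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class NeighborGraph:
    """Weighted kNN adjacency; weights are connectivity strengths.

    Graphs produced by :func:`build_knn_graph` use weight ``1/distance`` so
    that stronger edges join closer cells.  Graphs supplied by external
    integration methods are taken as given; a graph whose nonzero weights
    are all equal is treated as binary.
    """

    adjacency: sp.csr_matrix
    k: int
    symmetric: bool = False

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency, dtype=float)
        a.setdiag(0)
        a.eliminate_zeros()
        if a.nnz and not np.all(np.isfinite(a.data)):
            raise InputError("graph weights must be finite")
        if a.nnz and a.data.min() < 0:
            raise InputError("graph weights must be nonnegative")
        self.adjacency = a
        if not self.symmetric:
            self.symmetric = (a != a.T).nnz == 0

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def is_binary(self) -> bool:
        if self.adjacency.nnz == 0:
            return True
        d = self.adjacency.data
        return bool(np.allclose(d, d[0]))

    def symmetrized(self) -> "NeighborGraph":
        if self.symmetric:
            return self
        a = self.adjacency.maximum(self.adjacency.T)
        return NeighborGraph(adjacency=a, k=self.k, symmetric=True)


@dataclass
class IntegrationOutput:
    """Tagged union of the three integration output types plus provenance."""

    kind: OutputKind
    payload: Union[AnnotatedMatrix, Embedding, NeighborGraph]
    method: str = "unknown"
    scaled: bool = False
    hvg: bool = False

    def __post_init__(self) -> None:
        expected = {
            "features": AnnotatedMatrix,
            "embedding": Embedding,
            "graph": NeighborGraph,
        }
        if self.kind not in expected:
            raise ParameterError(f"unknown output kind {self.kind!r}")
        if not isinstance(self.payload, expected[self.kind]):
            raise InputError(
                f"payload type {type(self.payload).__name__} does not match kind {self.kind!r}"
            )
        if not self.method:
            raise InputError("method name must be non-empty")


@dataclass
class MetricResult:
    """A single named score in [0, 1], or missing when inapplicable."""

    name: str
    value: Optional[float]
    category: Literal["batch", "bio"] = field(default="bio")

    def __post_init__(self) -> None:
        if self.name in BATCH_METRICS:
            self.category = "batch"
        elif self.name in BIO_METRICS:
            self.category = "bio"


def metric_category(name: str) -> str:
    if name in BATCH_METRICS:
        return "batch"
    if name in BIO_METRICS:
        return "bio"
    raise ParameterError(f"unknown metric {name!r}")


def applicable_metrics(kind: OutputKind) -> frozenset:
    """Metric names computable for an integration output of the given kind.

    Graph metrics run on every kind (all kinds yield a graph); an embedding
    additionally unlocks the silhouette-, regression- and cell-cycle-based
    metrics; a corrected feature matrix unlocks all of them including HVG
    conservation.
    """
    if kind == "graph":
        return frozenset(_GRAPH_METRICS)
    if kind == "embedding":
        return frozenset(_GRAPH_METRICS | _EMBEDDING_EXTRA)
    if kind == "features":
        return frozenset(_GRAPH_METRICS | _EMBEDDING_EXTRA | _FEATURE_EXTRA)
    raise ParameterError(f"unknown output kind {kind!r}")


def pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, clipped at zero for numerical safety."""
    d = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2.0 * (a @ b.T)
    )
    return np.maximum(d, 0.0)


def exact_knn(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact k nearest neighbours by Euclidean distance.

    Ties are broken by cell index so results are fully deterministic.
    Returns ``(indices, distances)`` of shape (n, k), self excluded.
    """
    n = coords.shape[0]
    if k >= n:
        raise ParameterError(f"k={k} must be < number of cells ({n})")
    idx_out = np.empty((n, k), dtype=np.int64)
    dist_out = np.empty((n, k), dtype=float)
    chunk = max(1, int(2e7) // max(n, 1))
    col = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.sqrt(pairwise_sq_dists(coords[start:stop], coords))
        for i in range(start, stop):
            row = d[i - start].copy()
            row[i] = np.inf  # exclude self
            order = np.lexsort((col, row))[:k]
            idx_out[i] = order
            dist_out[i] = row[order]
    return idx_out, dist_out


def knn_to_graph(indices: np.ndarray, distances: np.ndarray, k: int) -> NeighborGraph:
    """Directed kNN lists -> union-symmetrized connectivity graph."""
    n = indices.shape[0]
    rows = np.repeat(np.arange(n), indices.shape[1])
    cols = indices.ravel()
    # connectivity = inverse distance; coincident points get a large weight
    w = 1.0 / np.maximum(distances.ravel(), 1e-12)
    a = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    a = a.maximum(a.T)
    return NeighborGraph(adjacency=a, k=k, symmetric=True)


def build_knn_graph(emb: Embedding, k: int = DEFAULT_K) -> NeighborGraph:
    """Euclidean kNN graph of an embedding, union-symmetrized.

    Each cell is linked to its ``k`` nearest cells (self excluded, distance
    ties broken by cell index); the edge weight is the inverse distance, so
    the graph can serve both connectivity- and distance-based metrics.
    """
    idx, dist = exact_knn(emb.coords, k)
    return knn_to_graph(idx, dist, k)


def pca_embedding(
    values: Union[np.ndarray, sp.spmatrix], n_pcs: int = DEFAULT_N_PCS
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA with a deterministic sign convention.

    Features are centered but not rescaled; each component's sign is chosen
    so its largest-magnitude loading is positive.  The number of components
    is truncated to the available rank.  Returns ``(coords, explained_var)``
    where ``explained_var`` holds the variance of each component.
    """
    x = np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values, float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    n_pcs = min(n_pcs, rank) if rank > 0 else 1
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(n_pcs), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    coords = u * s * flip
    explained = (s**2) / max(x.shape[0] - 1, 1)
    return coords, explained


def adapt_output(
    out: IntegrationOutput,
    n_pcs: int = DEFAULT_N_PCS,
    k: int = DEFAULT_K,
) -> tuple[Optional[Embedding], NeighborGraph]:
    """Derive the (embedding, graph) pair the metrics consume.

    Feature matrices are reduced to their top principal components and a
    kNN graph built on those; embeddings get a kNN graph on Euclidean
    distances; graph outputs pass through unchanged with no embedding.
    """
    if out.kind == "features":
        coords, _ = pca_embedding(out.payload.values, n_pcs=n_pcs)
        if coords.shape[1] < 2:
            coords = np.column_stack([coords, np.zeros(coords.shape[0])])
        emb = Embedding(coords)
        return emb, build_knn_graph(emb, k=k)
    if out.kind == "embedding":
        emb = out.payload
        return emb, build_knn_graph(emb, k=k)
    if out.kind == "graph":
        return None, out.payload.symmetrized()
    raise ParameterError(f"unknown output kind {out.kind!r}")


def align_cells(reference_ids: np.ndarray, other_ids: np.ndarray) -> np.ndarray:
    """Indices that reorder ``other_ids`` to match ``reference_ids``.

    Cell id is the alignment key across unintegrated and integrated
    objects; an error is raised if the id sets differ.
    """
    ref = _as_str_array(reference_ids)
    oth = _as_str_array(other_ids)
    pos = {c: i for i, c in enumerate(oth)}
    missing = [c for c in ref if c not in pos]
    if missing or len(ref) != len(oth):
        extra = sorted(set(oth) - set(ref))
        raise InputError(
            f"cell id sets differ: {len(missing)} missing (e.g. {missing[:5]}), "
            f"{len(extra)} extra (e.g. {extra[:5]})"
        )
    return np.array([pos[c] for c in ref], dtype=np.int64)
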