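"""Graph-distance machinery for evaluating graph-based integration outputs.

Methods such as BBKNN or Conos output an integrated kNN graph rather than
an embedding, and their graphs can have far fewer neighbours per node than
the k = 90 (LISI) or k = 50 (kBET) neighbourhoods the mixing metrics
assume.  Two corrections make these metrics applicable to arbitrary graphs:

* :func:`shortest_path_knn` treats the graph as an embedded space and finds
  each node's k nearest nodes by shortest-path length (Dijkstra), yielding
  neighbourhood lists of a consistent size;
* :func:`extend_neighborhood` grows sparse neighbourhoods by walking powers
  of the row-normalized transition matrix until every node has the target
  number of reachable neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .core import NeighborGraph, ParameterError

#: cap on transition-matrix powers during neighbourhood extension
MAX_DIFFUSION_STEPS = 8


@dataclass
class NeighborhoodList:
    """Per-cell ordered neighbour lists with graph distances.

    ``indices[i]`` and ``distances[i]`` hold up to ``k`` neighbours of cell
    ``i`` sorted by nondecreasing distance (ties broken by node index);
    cells in components smaller than ``k + 1`` keep whatever is reachable.
    ``cells`` records which nodes the lists were computed for.
    """

    cells: np.ndarray
    indices: list
    distances: list
    k: int

    def __len__(self) -> int:
        return len(self.indices)


def edge_lengths(g: NeighborGraph) -> sp.csr_matrix:
    """Edge lengths for shortest-path search.

    Connectivity-weighted graphs use length = 1/weight (stronger edges are
    shorter); binary graphs use unit lengths.
    """
    a = g.adjacency.tocsr(copy=True)
    if g.is_binary:
        a.data = np.ones_like(a.data)
    else:
        a.data = 1.0 / a.data
    return a


def shortest_path_knn(
    g: NeighborGraph,
    k: int,
    sources: Optional[Sequence[int]] = None,
) -> NeighborhoodList:
    """The k nearest nodes of each source by shortest-path length.

    Exact Dijkstra search on the symmetrized graph; ties in path length are
    broken by node index.  Isolated nodes yield empty lists (flagged with a
    warning).  ``sources`` restricts the computation to a subset of nodes,
    which the neighbourhood-sampling metrics use.
    """
    if k < 1:
        raise ParameterError("k must be positive")
    g = g.symmetrized()
    n = g.n_cells
    lengths = edge_lengths(g)
    src = np.arange(n) if sources is None else np.asarray(sources, dtype=int)
    col = np.arange(n)
    indices: list = []
    distances: list = []
    n_isolated = 0
    chunk = max(1, int(4e6) // max(n, 1))
    for start in range(0, len(src), chunk):
        batch = src[start : start + chunk]
        d = dijkstra(lengths, directed=False, indices=batch)
        d = np.atleast_2d(d)
        for row_i, cell in enumerate(batch):
            row = d[row_i]
            row[cell] = np.inf  # no self-entries
            finite = np.isfinite(row)
            if not finite.any():
                n_isolated += 1
                indices.append(np.empty(0, dtype=np.int64))
                distances.append(np.empty(0, dtype=float))
                continue
            order = np.lexsort((col, row))
            order = order[: min(k, int(finite.sum()))]
            indices.append(order.astype(np.int64))
            distances.append(row[order])
    if n_isolated:
        warnings.warn(f"{n_isolated} isolated node(s) have empty neighbourhoods")
    return NeighborhoodList(cells=src, indices=indices, distances=distances, k=k)


def _row_normalize(a: sp.csr_matrix) -> sp.csr_matrix:
    rowsum = np.asarray(a.sum(axis=1)).ravel()
    inv = np.where(rowsum > 0, 1.0 / np.where(rowsum > 0, rowsum, 1.0), 0.0)
    return sp.diags(inv) @ a


def extend_neighborhood(g: NeighborGraph, target_k: int) -> NeighborGraph:
    """Grow neighbourhoods to ``target_k`` neighbours via diffusion.

    Nodes with fewer than ``target_k`` neighbours accumulate new ones from
    successive powers of the row-normalized transition matrix (up to
    ``MAX_DIFFUSION_STEPS`` steps, or until their component is exhausted).
    Existing edges and their weights are never modified; added edges carry
    the diffusion probability with which the node was first reached, damped
    per step so that later-reached nodes rank below direct neighbours.
    """
    if target_k >= g.n_cells:
        raise ParameterError(f"target_k={target_k} must be < n cells ({g.n_cells})")
    a = g.adjacency.tocsr()
    counts = np.diff(a.indptr)
    if np.all(counts >= target_k):
        return g
    p = _row_normalize(a)
    deficient = np.where(counts < target_k)[0]
    reach = a[deficient].astype(bool).tocsr()  # known neighbours of deficient rows
    walk = p[deficient].tocsr()
    extra_rows: list = []
    extra_cols: list = []
    extra_vals: list = []
    extra_counts = np.zeros(len(deficient), dtype=int)
    damp = 1.0
    for _ in range(MAX_DIFFUSION_STEPS):
        walk = (walk @ p).tocsr()
        walk.data[walk.data < 1e-12] = 0
        walk.eliminate_zeros()
        damp *= 1e-3
        new = (walk.astype(bool) > reach).tocoo()  # reached now, not before
        nz_r, nz_c = new.row, new.col
        if len(nz_r):
            keep = deficient[nz_r] != nz_c  # no self loops
            nz_r, nz_c = nz_r[keep], nz_c[keep]
            picked = walk.tocsr()[nz_r, nz_c]
            if sp.issparse(picked):
                picked = picked.toarray()
            vals = np.asarray(picked).ravel() * damp
            extra_rows.append(deficient[nz_r])
            extra_cols.append(nz_c)
            extra_vals.append(np.maximum(vals, 1e-300))
            np.add.at(extra_counts, nz_r, 1)
            reach = reach + sp.csr_matrix(
                (np.ones(len(nz_r), bool), (nz_r, nz_c)), shape=reach.shape
            )
        if np.all(counts[deficient] + extra_counts >= target_k):
            break
    if extra_rows:
        extra = sp.csr_matrix(
            (
                np.concatenate(extra_vals),
                (np.concatenate(extra_rows), np.concatenate(extra_cols)),
            ),
            shape=a.shape,
        )
        a = (a + extra).tocsr()
    return NeighborGraph(adjacency=a, k=max(g.k, target_k), symmetric=False)


def neighbor_sets(g: NeighborGraph, cells: Sequence[int], k: int) -> list:
    """Top-k neighbours of each cell by edge weight (ties by node index)."""
    a = g.adjacency.tocsr()
    out = []
    for c in cells:
        start, stop = a.indptr[c], a.indptr[c + 1]
        idx = a.indices[start:stop]
        w = a.data[start:stop]
        order = np.lexsort((idx, -w))[:k]
        out.append(idx[order])
    return out
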