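"""Local inverse Simpson's index (LISI) over perplexity-weighted neighbourhoods.

The inverse Simpson's index of the category composition of a cell's
neighbourhood measures its effective diversity: how many cells can be drawn
from the neighbour list before one category is seen twice.  Computed on
batch labels (iLISI) it quantifies batch mixing; on cell-identity labels
(cLISI) it quantifies cell-type separation.  Neighbour weights use a
Gaussian kernel whose per-cell bandwidth is calibrated to a fixed
perplexity, as in t-SNE.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import Embedding, NeighborGraph, build_knn_graph, exact_knn
from .graphdist import NeighborhoodList, shortest_path_knn

#: neighbourhood size for LISI scoring
LISI_K = 90
#: perplexity fraction: p = k / 3
PERPLEXITY_FRACTION = 1.0 / 3.0
_LOG_PERP_TOL = 1e-5
_MAX_BISECT = 64


def _perplexity_weights(dist: np.ndarray, perplexity: float) -> np.ndarray:
    """Gaussian-kernel weights with bandwidth set by bisection on beta so
    the Shannon entropy matches log(perplexity) within 1e-5."""
    m = len(dist)
    if m == 0:
        return np.empty(0)
    if m <= 2 or perplexity >= m or np.allclose(dist, dist[0]):
        return np.full(m, 1.0 / m)
    d2 = dist.astype(float) ** 2
    d2 = d2 - d2.min()
    target = np.log(perplexity)
    beta, beta_min, beta_max = 1.0, 0.0, np.inf
    p = np.full(m, 1.0 / m)
    for _ in range(_MAX_BISECT):
        w = np.exp(-beta * d2)
        s = w.sum()
        if s <= 0:
            beta_max = beta
            beta = (beta_min + beta_max) / 2
            continue
        p = w / s
        h = -np.sum(p * np.log(np.maximum(p, 1e-300)))
        if abs(h - target) < _LOG_PERP_TOL:
            break
        if h > target:  # too flat -> narrow the kernel
            beta_min = beta
            beta = beta * 2 if np.isinf(beta_max) else (beta_min + beta_max) / 2
        else:
            beta_max = beta
            beta = (beta_min + beta_max) / 2
    return p


def simpson_index(
    dist: np.ndarray, codes: np.ndarray, n_cat: int, perplexity: float
) -> float:
    """Inverse Simpson's index of one neighbourhood's category mix."""
    p = _perplexity_weights(dist, perplexity)
    if len(p) == 0:
        return np.nan
    mass = np.bincount(codes, weights=p, minlength=n_cat)
    denom = float(np.sum(mass**2))
    return 1.0 / denom if denom > 0 else np.nan


def lisi_per_cell(
    nl: NeighborhoodList, categories: np.ndarray, perplexity: Optional[float] = None
) -> np.ndarray:
    """Raw LISI per cell from precomputed neighbourhood lists."""
    cats, codes = np.unique(np.asarray(categories, dtype=object), return_inverse=True)
    n_cat = len(cats)
    perp = perplexity if perplexity is not None else max(1.0, nl.k * PERPLEXITY_FRACTION)
    out = np.full(len(nl.indices), np.nan)
    for i, (idx, dist) in enumerate(zip(nl.indices, nl.distances)):
        if len(idx) == 0:
            continue
        out[i] = simpson_index(np.asarray(dist), codes[idx], n_cat, perp)
    return out


def graph_lisi_median(
    g: NeighborGraph, categories: np.ndarray, k: int = LISI_K
) -> float:
    """Median raw LISI using shortest-path neighbourhoods of the graph."""
    k = min(k, g.n_cells - 1)
    nl = shortest_path_knn(g, k=k)
    vals = lisi_per_cell(nl, categories)
    vals = vals[np.isfinite(vals)]
    return float(np.median(vals)) if len(vals) else np.nan


def embedding_lisi_median(
    emb: Embedding, categories: np.ndarray, k: int = LISI_K
) -> float:
    """Median raw LISI from exact Euclidean kNN of an embedding (the
    standard, non-graph formulation)."""
    k = min(k, emb.n_cells - 1)
    idx, dist = exact_knn(emb.coords, k)
    nl = NeighborhoodList(
        cells=np.arange(emb.n_cells),
        indices=list(idx),
        distances=list(dist),
        k=k,
    )
    vals = lisi_per_cell(nl, categories)
    vals = vals[np.isfinite(vals)]
    return float(np.median(vals)) if len(vals) else np.nan
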