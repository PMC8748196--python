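"""Batch-effect-removal metrics.

Five scores in [0, 1] where 1 means batch effects are fully removed:
batch silhouette (ASW_batch), principal-component regression of the batch
covariate (PCR_batch), per-label graph connectivity, the kBET neighbourhood
composition test, and graph iLISI.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2 as chi2_dist
from sklearn.metrics import silhouette_samples

from .core import (
    AnnotatedMatrix,
    Embedding,
    NeighborGraph,
    build_knn_graph,
    pca_embedding,
)
from .graphdist import extend_neighborhood, neighbor_sets
from .lisi import LISI_K, graph_lisi_median

#: kBET significance level
KBET_ALPHA = 0.05
#: kBET neighbourhood-size clamp
KBET_K_MIN, KBET_K_MAX = 10, 100
#: kNN graph size used for kBET on embeddings / feature PCAs
KBET_GRAPH_K = 50
#: neighbourhoods sampled per connected component
KBET_MAX_SAMPLES = 500
KBET_SAMPLE_FRACTION = 0.1


def batch_asw(emb: Embedding, batch: np.ndarray, label: np.ndarray) -> Optional[float]:
    """Batch mixing via the absolute silhouette width on batch labels.

    Within each cell-identity label containing at least two batches, the
    silhouette s(i) of each cell w.r.t. its batch assignment is computed
    and folded through 1 - |s(i)|; per-label means are averaged.  1 is
    ideal mixing, 0 strongly separated batches.  Missing when no label
    spans two batches.
    """
    batch = np.asarray(batch, dtype=object)
    label = np.asarray(label, dtype=object)
    scores = []
    for j in sorted(set(label), key=str):
        cells = np.where(label == j)[0]
        if len(set(batch[cells])) < 2 or len(cells) < 3:
            continue
        s = silhouette_samples(emb.coords[cells], batch[cells].astype(str))
        scores.append(float(np.mean(1.0 - np.abs(s))))
    return float(np.mean(scores)) if scores else None


def _one_hot(categories: np.ndarray) -> np.ndarray:
    cats, codes = np.unique(np.asarray(categories, dtype=object), return_inverse=True)
    out = np.zeros((len(codes), len(cats)))
    out[np.arange(len(codes)), codes] = 1.0
    return out


def variance_explained(
    data: Union[np.ndarray, sp.spmatrix, Embedding, AnnotatedMatrix],
    covariate: np.ndarray,
    n_pcs: int = 50,
    categorical: bool = True,
) -> float:
    """Total variance explained by a covariate, Var(C|B), via PC regression.

    The covariate (one-hot batch, or continuous columns) is regressed onto
    each of the top principal components; the per-component contribution is
    the product of the component's variance and the regression R^2, and
    Var(C|B) is the sum over components.
    """
    if isinstance(data, Embedding):
        values = data.coords
    elif isinstance(data, AnnotatedMatrix):
        values = data.values
    else:
        values = data
    coords, var = pca_embedding(values, n_pcs=n_pcs)
    design = _one_hot(covariate) if categorical else np.asarray(covariate, float)
    if design.ndim == 1:
        design = design[:, None]
    design = np.column_stack([np.ones(len(design)), design])
    total = 0.0
    for i in range(coords.shape[1]):
        y = coords[:, i]
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= 0:
            continue
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        total += var[i] * max(r2, 0.0)
    return total


def pcr_batch(
    before: Union[Embedding, AnnotatedMatrix, np.ndarray],
    after: Union[Embedding, AnnotatedMatrix, np.ndarray],
    batch: np.ndarray,
    n_pcs: int = 50,
) -> Optional[float]:
    """Reduction in batch-explained variance after integration.

    Var(C|B) is computed on the top principal components before and after;
    the score is (Var_before - Var_after) / Var_before clipped to [0, 1].
    Missing when the unintegrated data carries no batch signal.
    """
    if len(set(np.asarray(batch, dtype=object))) < 2:
        return None
    var_before = variance_explained(before, batch, n_pcs=n_pcs)
    if var_before <= 0:
        return None
    var_after = variance_explained(after, batch, n_pcs=n_pcs)
    return float(np.clip((var_before - var_after) / var_before, 0.0, 1.0))


def graph_connectivity(g: NeighborGraph, label: np.ndarray) -> float:
    """Mean fraction of each label's cells in its subgraph's largest
    connected component; 1 when every cell identity is fully connected."""
    label = np.asarray(label, dtype=object)
    a = g.symmetrized().adjacency
    fractions = []
    for c in sorted(set(label), key=str):
        cells = np.where(label == c)[0]
        sub = a[cells][:, cells]
        _, comp = connected_components(sub, directed=False)
        largest = int(np.bincount(comp).max())
        fractions.append(largest / len(cells))
    return float(np.mean(fractions))


def _kbet_label_score(
    a: sp.csr_matrix,
    cells: np.ndarray,
    batch: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    graph_k: int,
) -> float:
    """Rejection rate of the local-vs-global batch composition test for
    one label (before the final 1-minus-mean step)."""
    counts = np.bincount(
        np.unique(batch[cells], return_inverse=True)[1]
    )
    k0 = int(np.clip(np.median(counts), KBET_K_MIN, KBET_K_MAX))
    k0 = min(k0, len(cells) - 1)
    sub = a[cells][:, cells]
    n_comp, comp = connected_components(sub, directed=False)
    sizes = np.bincount(comp)
    too_small = sizes[comp] < k0 * 3
    if too_small.mean() > 0.25:
        return 1.0
    label_batches, label_codes = np.unique(batch[cells].astype(str), return_inverse=True)
    freqs = np.bincount(label_codes) / len(cells)
    dof = len(label_batches) - 1
    rejected = 0
    total = 0
    for c in range(n_comp):
        members = np.where(comp == c)[0]
        if len(members) < k0 * 3:
            continue
        comp_codes = label_codes[members]
        comp_graph = NeighborGraph(sub[members][:, members], k=graph_k, symmetric=True)
        if k0 < len(members) - 1:
            comp_graph = extend_neighborhood(comp_graph, target_k=k0)
        n_sample = min(max(1, int(KBET_SAMPLE_FRACTION * len(members))), KBET_MAX_SAMPLES)
        sample = rng.choice(len(members), size=n_sample, replace=False)
        hoods = neighbor_sets(comp_graph, sample, k0)
        for hood in hoods:
            m = len(hood)
            if m == 0 or dof == 0:
                total += 1
                continue
            obs = np.bincount(comp_codes[hood], minlength=len(label_batches))
            exp = freqs * m
            stat = float(np.sum((obs - exp) ** 2 / np.maximum(exp, 1e-300)))
            p = float(chi2_dist.sf(stat, dof))
            rejected += p < alpha
            total += 1
    return rejected / total if total else 1.0


def kbet(
    g_or_emb: Union[NeighborGraph, Embedding],
    batch: np.ndarray,
    label: np.ndarray,
    alpha: float = KBET_ALPHA,
    seed: int = 0,
    return_per_label: bool = False,
):
    """kBET batch-composition test, summarized per label.

    Per cell-identity label, the neighbourhood size k is the median number
    of cells per batch within the label, clamped to [10, 100].  The test is
    run per connected component of the label's subgraph; if more than 25%
    of a label's cells sit in components smaller than k x 3, that label is
    assigned a score of 1 (poor batch removal).  The final score is 1 minus
    the mean per-label rejection rate.  Embedding inputs are converted to a
    k = 50 kNN graph; sparse graph outputs get diffusion-extended
    neighbourhoods so every cell is tested on the same k.
    """
    batch = np.asarray(batch, dtype=object)
    label = np.asarray(label, dtype=object)
    if len(set(batch)) < 2:
        return (None, {}) if return_per_label else None
    if isinstance(g_or_emb, Embedding):
        g = build_knn_graph(g_or_emb, k=min(KBET_GRAPH_K, g_or_emb.n_cells - 1))
    else:
        g = g_or_emb.symmetrized()
    rng = np.random.default_rng(seed)
    a = g.adjacency
    per_label = {}
    for j in sorted(set(label), key=str):
        cells = np.where(label == j)[0]
        if len(set(batch[cells])) < 2:
            continue  # test undefined for single-batch labels
        per_label[j] = _kbet_label_score(a, cells, batch, alpha, rng, g.k)
    if not per_label:
        return (None, {}) if return_per_label else None
    score = float(1.0 - np.mean(list(per_label.values())))
    return (score, per_label) if return_per_label else score


def graph_ilisi(g: NeighborGraph, batch: np.ndarray, k: int = LISI_K) -> Optional[float]:
    """Graph iLISI: median inverse Simpson's index of batch composition in
    shortest-path neighbourhoods, rescaled to [0, 1] by (x - 1)/(B - 1)."""
    batch = np.asarray(batch, dtype=object)
    n_batches = len(set(batch))
    if n_batches < 2:
        return None
    med = graph_lisi_median(g, batch, k=k)
    if not np.isfinite(med):
        return None
    return float(np.clip((med - 1.0) / (n_batches - 1.0), 0.0, 1.0))
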