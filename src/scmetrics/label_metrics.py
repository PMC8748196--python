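"""Cell-identity (label) conservation metrics.

Six scores in [0, 1] where 1 means cell identities are perfectly
conserved: NMI and ARI against a resolution-swept Louvain clustering,
cell-type silhouette, graph cLISI, and the two isolated-label scores that
probe conservation of identities shared by few batches.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Optional

import igraph
import numpy as np
import scipy.sparse as sp
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from .core import Embedding, NeighborGraph, ParameterError
from .lisi import LISI_K, graph_lisi_median

#: Louvain resolution grid: 0.1 to 2.0 in steps of 0.1
RESOLUTIONS: tuple[float, ...] = tuple(np.round(np.arange(1, 21) * 0.1, 1))
LOUVAIN_SEED = 0


@dataclass
class ClusterSweepResult:
    resolutions: tuple
    assignments: list  # membership array per resolution
    objectives: np.ndarray
    best_index: int

    @property
    def best_resolution(self) -> float:
        return self.resolutions[self.best_index]

    @property
    def best_assignment(self) -> np.ndarray:
        return self.assignments[self.best_index]


def _to_igraph(g: NeighborGraph) -> tuple[igraph.Graph, list]:
    a = sp.triu(g.symmetrized().adjacency, k=1).tocoo()
    graph = igraph.Graph(
        n=g.n_cells, edges=list(zip(a.row.tolist(), a.col.tolist()))
    )
    return graph, a.data.tolist()


def louvain_partitions(
    g: NeighborGraph,
    resolutions=RESOLUTIONS,
    seed: int = LOUVAIN_SEED,
) -> list:
    """Louvain (multilevel modularity) communities at each resolution.

    The random number generator is re-seeded before every resolution so
    partitions are reproducible and independent of sweep order.
    """
    if g.n_cells == 0:
        raise ParameterError("empty graph")
    graph, weights = _to_igraph(g)
    out = []
    for res in resolutions:
        igraph.set_random_number_generator(random.Random(seed))
        part = graph.community_multilevel(
            weights=weights if weights else None, resolution=float(res)
        )
        out.append(np.asarray(part.membership, dtype=int))
    return out


def louvain_sweep(
    g: NeighborGraph,
    objective: Callable[[np.ndarray], float],
    resolutions=RESOLUTIONS,
    seed: int = LOUVAIN_SEED,
) -> ClusterSweepResult:
    """Sweep the resolution grid and keep the partition maximizing the
    objective; ties go to the lowest resolution."""
    assignments = louvain_partitions(g, resolutions=resolutions, seed=seed)
    objectives = np.array([objective(m) for m in assignments])
    best = int(np.argmax(objectives))  # argmax takes the first (lowest res) tie
    return ClusterSweepResult(
        resolutions=tuple(resolutions),
        assignments=assignments,
        objectives=objectives,
        best_index=best,
    )


def nmi_score(clusters: np.ndarray, label: np.ndarray) -> float:
    """NMI with arithmetic-mean entropy normalization.

    Two identical trivial partitions (one cluster vs one label) are a
    perfect match and score 1.
    """
    clusters = np.asarray(clusters)
    label = np.asarray(label, dtype=object)
    if len(set(clusters)) == 1 and len(set(label)) == 1:
        return 1.0
    return float(
        normalized_mutual_info_score(
            label.astype(str), clusters, average_method="arithmetic"
        )
    )


def ari_score(clusters: np.ndarray, label: np.ndarray) -> float:
    """Chance-adjusted Rand index."""
    return float(adjusted_rand_score(np.asarray(label, dtype=object).astype(str), clusters))


def nmi_ari_optimized(
    g: NeighborGraph, label: np.ndarray, seed: int = LOUVAIN_SEED
) -> tuple[float, float, ClusterSweepResult]:
    """NMI-optimized Louvain sweep; both NMI and ARI are reported against
    the sweep's best-NMI partition."""
    sweep = louvain_sweep(g, objective=lambda m: nmi_score(m, label), seed=seed)
    best = sweep.best_assignment
    return nmi_score(best, label), ari_score(best, label), sweep


def celltype_asw(emb: Embedding, label: np.ndarray) -> Optional[float]:
    """Cell-type silhouette, affinely mapped from [-1, 1] to [0, 1]."""
    label = np.asarray(label, dtype=object)
    if len(set(label)) < 2:
        return None
    asw = silhouette_score(emb.coords, label.astype(str))
    return float((asw + 1.0) / 2.0)


def graph_clisi(g: NeighborGraph, label: np.ndarray, k: int = LISI_K) -> Optional[float]:
    """Graph cLISI: median inverse Simpson's index of label composition,
    rescaled by (L - x)/(L - 1) so 1 means perfect label separation."""
    label = np.asarray(label, dtype=object)
    n_labels = len(set(label))
    if n_labels < 2:
        return None
    med = graph_lisi_median(g, label, k=k)
    if not np.isfinite(med):
        return None
    return float(np.clip((n_labels - med) / (n_labels - 1.0), 0.0, 1.0))


def isolated_labels(label: np.ndarray, batch: np.ndarray) -> list:
    """Labels present in the fewest batches of the task.

    All labels tied at the minimum batch-presence count are isolated.  When
    every label spans every batch no label is considered isolated and the
    empty list is returned.
    """
    label = np.asarray(label, dtype=object)
    batch = np.asarray(batch, dtype=object)
    presence = {
        j: len(set(batch[label == j])) for j in sorted(set(label), key=str)
    }
    lo = min(presence.values())
    if lo == len(set(batch)):
        return []
    return [j for j, c in presence.items() if c == lo]


def _best_f1(membership: np.ndarray, target: np.ndarray) -> float:
    """Best F1 of any single cluster against the binary target."""
    best = 0.0
    n_true = int(target.sum())
    for c in np.unique(membership):
        inc = membership == c
        tp = int(np.sum(inc & target))
        if tp == 0:
            continue
        precision = tp / int(inc.sum())
        recall = tp / n_true
        best = max(best, 2 * precision * recall / (precision + recall))
    return best


def isolated_label_f1(
    g: NeighborGraph, label: np.ndarray, batch: np.ndarray, seed: int = LOUVAIN_SEED
) -> Optional[float]:
    """Best one-vs-rest cluster F1 for each isolated label, maximized over
    the Louvain resolution sweep, averaged over isolated labels."""
    label = np.asarray(label, dtype=object)
    iso = isolated_labels(label, batch)
    if not iso:
        return None
    assignments = louvain_partitions(g, seed=seed)
    scores = []
    for j in iso:
        target = label == j
        scores.append(max(_best_f1(m, target) for m in assignments))
    return float(np.mean(scores))


def isolated_label_asw(
    emb: Embedding, label: np.ndarray, batch: np.ndarray
) -> Optional[float]:
    """Silhouette of the isolated-vs-rest partition, scaled to [0, 1],
    averaged over isolated labels."""
    label = np.asarray(label, dtype=object)
    iso = isolated_labels(label, batch)
    if not iso:
        return None
    scores = []
    for j in iso:
        binary = (label == j).astype(int)
        if 0 < binary.sum() < len(binary):
            asw = silhouette_score(emb.coords, binary)
            scores.append((asw + 1.0) / 2.0)
    return float(np.mean(scores)) if scores else None
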