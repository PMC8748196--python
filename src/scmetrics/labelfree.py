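"""Conservation of biological variance beyond cell-identity labels.

Three metrics: conservation of cell-cycle variance (via gene-program
scoring and per-batch principal-component regression), conservation of
per-batch highly variable genes, and conservation of a developmental
trajectory (rank correlation of diffusion pseudotime before and after
integration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from .batch_metrics import variance_explained
from .core import (
    AnnotatedMatrix,
    Embedding,
    InputError,
    IntegrationOutput,
    NeighborGraph,
    adapt_output,
    build_knn_graph,
)
from .preprocessing import normalized_dispersion

#: expression bins and controls per gene for gene-set scoring
SCORE_N_BINS = 25
SCORE_CTRL_PER_GENE = 50
#: HVGs per batch for the conservation overlap
HVG_CONSERVATION_N = 500
#: diffusion components used for pseudotime
N_DCS = 15
#: below this many cells in the largest component the trajectory is
#: considered uncomputable
MIN_TRAJECTORY_CELLS = 10


def load_cell_cycle_genes() -> tuple[list, list]:
    """The S-phase and G2/M-phase marker gene symbol lists shipped with
    the package (human symbols; mouse symbols match by capitalization)."""
    out = []
    for name in ("s_genes.txt", "g2m_genes.txt"):
        text = resources.files("scmetrics.data").joinpath(name).read_text()
        out.append([line.strip() for line in text.splitlines() if line.strip()])
    return out[0], out[1]


def score_gene_set(
    adata: AnnotatedMatrix,
    genes: Sequence[str],
    seed: int = 0,
    n_bins: int = SCORE_N_BINS,
    ctrl_per_gene: int = SCORE_CTRL_PER_GENE,
) -> np.ndarray:
    """Per-cell gene-program score: set mean minus bin-matched control mean.

    Genes are matched case-insensitively (so mouse symbols, which differ
    from human only by capitalization, resolve against human lists).  All
    genes are ranked by mean expression and split into ``n_bins`` equal
    bins; for every set gene, ``ctrl_per_gene`` control genes are sampled
    from the non-set genes of its bin (the whole pool when it is smaller,
    widening to the nearest bins when a bin holds only set genes).  The
    score is the mean expression of the set minus the mean expression of
    the controls; when the set covers every gene the controls coincide
    with the set and the score is identically zero.
    """
    feats = adata.feature_ids.astype(str)
    upper = {f.upper(): i for i, f in enumerate(feats)}
    hit = [upper[g.upper()] for g in genes if g.upper() in upper]
    if not hit:
        raise InputError(
            f"none of the {len(list(genes))} gene-set symbols found "
            f"(e.g. {list(genes)[:5]})"
        )
    x = adata.dense()
    mean = x.mean(axis=0)
    order = np.argsort(mean, kind="stable")
    ranks = np.empty(len(mean), dtype=int)
    ranks[order] = np.arange(len(mean))
    bins = ranks * n_bins // len(mean)
    rng = np.random.default_rng(seed)
    set_idx = np.asarray(sorted(set(hit)))
    in_set = np.zeros(len(mean), dtype=bool)
    in_set[set_idx] = True
    if in_set.all():
        return np.zeros(x.shape[0])
    ctrl: set = set()
    for b in np.unique(bins[set_idx]):
        pool = np.where((bins == b) & ~in_set)[0]
        width = 1
        while len(pool) == 0:
            pool = np.where((np.abs(bins - b) <= width) & ~in_set)[0]
            width += 1
        want = ctrl_per_gene * int(np.sum(bins[set_idx] == b))
        if want >= len(pool):
            ctrl.update(pool.tolist())
        else:
            ctrl.update(rng.choice(pool, size=want, replace=False).tolist())
    ctrl_idx = np.asarray(sorted(ctrl))
    return x[:, set_idx].mean(axis=1) - x[:, ctrl_idx].mean(axis=1)


def cell_cycle_phase_scores(
    adata: AnnotatedMatrix, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """S and G2/M phase scores from the shipped marker lists."""
    s_genes, g2m_genes = load_cell_cycle_genes()
    return (
        score_gene_set(adata, s_genes, seed=seed),
        score_gene_set(adata, g2m_genes, seed=seed),
    )


def _representation(data: Union[AnnotatedMatrix, Embedding, np.ndarray]) -> np.ndarray:
    if isinstance(data, AnnotatedMatrix):
        return data.dense()
    if isinstance(data, Embedding):
        return data.coords
    return np.asarray(data, float)


def cc_conservation(
    before: AnnotatedMatrix,
    after: Union[AnnotatedMatrix, Embedding],
    batch: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Optional[float]:
    """Conservation of cell-cycle variance across integration.

    Phase scores are computed on the unintegrated matrix; per batch, their
    variance contribution (principal-component regression) before and after
    integration is compared via 1 - |Var_after - Var_before| / Var_before,
    clipped to [0, 1] and averaged over batches.
    """
    batch = np.asarray(before.batch if batch is None else batch, dtype=object)
    s_score, g2m_score = cell_cycle_phase_scores(before, seed=seed)
    covar = np.column_stack([s_score, g2m_score])
    x_before = _representation(before)
    x_after = _representation(after)
    scores = []
    for b in sorted(set(batch), key=str):
        rows = np.where(batch == b)[0]
        vb = variance_explained(x_before[rows], covar[rows], categorical=False)
        if vb <= 0:
            warnings.warn(f"batch {b!r}: no cell-cycle variance before integration; skipped")
            continue
        va = variance_explained(x_after[rows], covar[rows], categorical=False)
        scores.append(float(np.clip(1.0 - abs(va - vb) / vb, 0.0, 1.0)))
    return float(np.mean(scores)) if scores else None


def hvg_conservation(
    before: AnnotatedMatrix,
    after: AnnotatedMatrix,
    n_hvg: int = HVG_CONSERVATION_N,
) -> float:
    """Mean per-batch overlap coefficient of highly variable genes.

    Per batch, the top ``n_hvg`` HVGs (or half the genes when fewer than
    ``n_hvg`` are present) are selected before and after correction;
    overlap(X, Y) = |X n Y| / min(|X|, |Y|), averaged over batches.
    """
    f_before = set(before.feature_ids.astype(str))
    f_after = set(after.feature_ids.astype(str))
    shared = sorted(f_before & f_after)
    if not shared:
        raise InputError("feature sets of before/after matrices are disjoint")
    from .preprocessing import select_features

    before = select_features(before, shared)
    after = select_features(after, shared)
    feats = before.feature_ids.astype(str)
    scores = []
    for b in sorted(set(before.batch), key=str):
        rows_b = np.where(before.batch == b)[0]
        rows_a = np.where(after.batch == b)[0]
        n = n_hvg if len(shared) >= n_hvg else max(1, len(shared) // 2)
        top = []
        for mat, rows in ((before, rows_b), (after, rows_a)):
            disp = normalized_dispersion(mat.values[rows])
            order = np.lexsort((feats, -disp))
            top.append(set(feats[order[:n]]))
        x, y = top
        scores.append(len(x & y) / min(len(x), len(y)))
    return float(np.mean(scores))


@dataclass
class TrajectoryAnnotation:
    """A developmental continuum: member labels, the pre-integration
    pseudotime per cell (NaN outside the trajectory), and the label of the
    cluster holding the trajectory's starting cells."""

    pseudotime: np.ndarray
    member_labels: list
    root_label: str
    n_dcs: int = 3  # diffusion components used pre-integration

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)


def diffusion_pseudotime(
    g: NeighborGraph, root: int, n_dcs: int = N_DCS
) -> np.ndarray:
    """Diffusion pseudotime: diffusion-map distance of every cell to the
    root cell, on a connected graph.

    The transition matrix is the density-normalized, symmetrically
    rescaled connectivity kernel; with eigenpairs (l_i, psi_i) the
    pseudotime of cell x is the distance
    ``sqrt(sum_i (l_i/(1-l_i))^2 (psi_i(x) - psi_i(root))^2)`` over the
    first ``n_dcs`` nontrivial components, rescaled to max 1.
    """
    evals, psi = diffusion_components(g, n_dcs)
    scale = evals / (1.0 - evals)
    diff = (psi - psi[root]) * scale
    dpt = np.sqrt(np.sum(diff**2, axis=1))
    top = dpt.max()
    return dpt / top if top > 0 else dpt


def diffusion_components(g: NeighborGraph, n_dcs: int = N_DCS) -> tuple[np.ndarray, np.ndarray]:
    """Nontrivial diffusion-map eigenvalues and components of a graph."""
    w = g.symmetrized().adjacency.astype(float)
    n = w.shape[0]
    q = np.asarray(w.sum(axis=1)).ravel()
    q[q == 0] = 1.0
    # density normalization (alpha = 1) then symmetric rescaling
    w1 = sp.diags(1.0 / q) @ w @ sp.diags(1.0 / q)
    d = np.asarray(w1.sum(axis=1)).ravel()
    d[d == 0] = 1.0
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(d))
    kernel = d_inv_sqrt @ w1 @ d_inv_sqrt
    n_comp = min(n_dcs + 1, n - 1)
    if n <= 200:
        evals, evecs = np.linalg.eigh(np.asarray(kernel.todense()))
        evals, evecs = evals[::-1][: n_comp], evecs[:, ::-1][:, :n_comp]
    else:
        from scipy.sparse.linalg import eigsh

        evals, evecs = eigsh(kernel.tocsc(), k=n_comp, which="LA")
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    # drop the trivial stationary component; clip almost-1 eigenvalues
    evals = np.clip(evals[1:], -1.0, 1.0 - 1e-10)
    psi = (1.0 / np.sqrt(d))[:, None] * evecs[:, 1:]
    return evals, psi


def select_root_cell(psi1: np.ndarray, candidates: np.ndarray) -> int:
    """The most extremal candidate on the first diffusion component:
    maximal absolute coordinate, ties broken by cell index."""
    vals = np.abs(psi1[candidates])
    return int(candidates[int(np.argmax(vals))])


def trajectory_conservation(
    traj: TrajectoryAnnotation,
    after: IntegrationOutput,
    label: np.ndarray,
    k: int = 15,
) -> float:
    """Rank agreement of diffusion pseudotime before and after integration.

    The evaluation is restricted to the trajectory's member labels and to
    the largest connected component of the integrated neighbourhood graph;
    the root is re-selected as the most extremal root-cluster cell on the
    first diffusion component.  The score is (Spearman s + 1)/2; if the
    trajectory cannot be computed (fragmented graph, missing root), it is 0.
    """
    label = np.asarray(label, dtype=object)
    member = np.isin(label, np.asarray(traj.member_labels, dtype=object)) & np.isfinite(
        traj.pseudotime
    )
    cells = np.where(member)[0]
    if len(cells) < MIN_TRAJECTORY_CELLS:
        return 0.0
    emb, g = adapt_output(after, k=min(k, max(2, len(cells) - 1)))
    if emb is not None:
        sub_g = build_knn_graph(
            Embedding(emb.coords[cells]), k=min(k, len(cells) - 1)
        )
    else:
        sub_g = NeighborGraph(
            g.adjacency[cells][:, cells], k=g.k, symmetric=True
        )
    _, comp = connected_components(sub_g.adjacency, directed=False)
    lcc = int(np.bincount(comp).argmax())
    in_lcc = np.where(comp == lcc)[0]
    if len(in_lcc) < max(MIN_TRAJECTORY_CELLS, 3):
        return 0.0
    lcc_cells = cells[in_lcc]
    roots_local = np.where(label[lcc_cells] == traj.root_label)[0]
    if len(roots_local) == 0:
        return 0.0
    lcc_graph = NeighborGraph(
        sub_g.adjacency[in_lcc][:, in_lcc], k=sub_g.k, symmetric=True
    )
    n_dcs = min(N_DCS, lcc_graph.n_cells - 2)
    if n_dcs < 1:
        return 0.0
    try:
        evals, psi = diffusion_components(lcc_graph, n_dcs)
        root = select_root_cell(psi[:, 0], roots_local)
        scale = evals / (1.0 - evals)
        diff = (psi - psi[root]) * scale
        after_pt = np.sqrt(np.sum(diff**2, axis=1))
    except Exception:
        return 0.0
    before_pt = traj.pseudotime[lcc_cells]
    s = spearmanr(before_pt, after_pt).statistic
    if not np.isfinite(s):
        return 0.0
    return float((s + 1.0) / 2.0)
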