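"""Synthetic scenario generators for exercising every metric offline.

These generators do not imitate a full scRNA-seq simulator; they guarantee
exactly the statistical structures the metrics read — batch mixing versus
batch shift, cluster separation, per-batch mean-variance structure with a
correlated gene program, and a one-dimensional developmental path — each
behind a single monotone dial, so metric responses can be calibrated
against known ground truth.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core import AnnotatedMatrix, Embedding, NeighborGraph, ParameterError


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    return x / np.maximum(norms, 1e-12)


def make_embedding_scenario(
    n_cells: int = 600,
    n_types: int = 3,
    n_batches: int = 2,
    batch_shift: float = 0.0,
    type_separation: float = 5.0,
    dim: int = 10,
    seed: int = 0,
) -> tuple[Embedding, np.ndarray, np.ndarray]:
    """Gaussian-mixture embedding with tunable batch shift.

    Cell types sit at centers ``type_separation`` from the origin; each
    batch adds a mean offset of magnitude ``batch_shift`` (0 makes batches
    exchangeable).  Unit within-cluster noise.  Returns
    ``(embedding, batch, label)``.
    """
    if n_types * n_batches > n_cells:
        raise ParameterError("need at least one cell per type x batch combination")
    if batch_shift < 0 or type_separation < 0:
        raise ParameterError("shift and separation must be nonnegative")
    rng = np.random.default_rng(seed)
    type_centers = _unit_rows(rng.normal(size=(n_types, dim))) * type_separation
    batch_offsets = _unit_rows(rng.normal(size=(n_batches, dim))) * batch_shift
    types = np.arange(n_cells) % n_types
    batches = (np.arange(n_cells) // n_types) % n_batches
    coords = (
        type_centers[types]
        + batch_offsets[batches]
        + rng.normal(size=(n_cells, dim))
    )
    label = np.array([f"type{t}" for t in types], dtype=object)
    batch = np.array([f"batch{b}" for b in batches], dtype=object)
    return Embedding(coords), batch, label


def make_count_scenario(
    n_cells: int = 500,
    n_genes: int = 300,
    n_batches: int = 2,
    batch_factor: float = 1.0,
    n_types: int = 3,
    cc_genes: bool = True,
    seed: int = 0,
) -> AnnotatedMatrix:
    """Gamma-Poisson count matrix with per-batch scaling factors.

    Gene base means are log-normal; batch ``b`` multiplies them by
    ``batch_factor ** b`` (1 means no batch effect).  Each cell type
    up-regulates its own marker block.  When ``cc_genes`` is set, the
    first genes carry the S/G2M marker symbols and share two latent
    per-cell programs, giving the matrix a cell-cycle-like signal.
    Counts are depth-normalized and log1p-transformed.
    """
    if batch_factor <= 0:
        raise ParameterError("batch_factor must be positive")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    types = np.arange(n_cells) % n_types
    batches = (np.arange(n_cells) // n_types) % n_batches
    mean = np.tile(base, (n_cells, 1))
    # cell-type marker blocks
    block = max(5, n_genes // (4 * n_types))
    marker_start = n_genes - n_types * block
    for t in range(n_types):
        lo = marker_start + t * block
        mean[types == t, lo : lo + block] *= 5.0
    feature_ids = np.array([f"gene{i}" for i in range(n_genes)], dtype=object)
    if cc_genes:
        from .labelfree import load_cell_cycle_genes

        s_genes, g2m_genes = load_cell_cycle_genes()
        s_genes = s_genes[: max(1, n_genes // 10)]
        g2m_genes = g2m_genes[: max(1, n_genes // 10)]
        n_s, n_g = len(s_genes), len(g2m_genes)
        if n_s + n_g > n_genes:
            raise ParameterError("too few genes for the cell-cycle program")
        feature_ids[:n_s] = s_genes
        feature_ids[n_s : n_s + n_g] = g2m_genes
        s_act = rng.gamma(2.0, 1.0, size=n_cells)
        g2m_act = rng.gamma(2.0, 1.0, size=n_cells)
        mean[:, :n_s] *= (0.5 + s_act)[:, None]
        mean[:, n_s : n_s + n_g] *= (0.5 + g2m_act)[:, None]
    mean *= (batch_factor ** batches)[:, None]
    # gamma-Poisson: overdispersed counts with shape 2
    lam = rng.gamma(2.0, mean / 2.0)
    counts = rng.poisson(lam).astype(float)
    totals = counts.sum(axis=1)
    totals[totals == 0] = 1.0
    norm = counts / totals[:, None] * np.median(totals)
    values = np.log1p(norm)
    return AnnotatedMatrix(
        values=values,
        cell_ids=np.array([f"cell{i}" for i in range(n_cells)], dtype=object),
        feature_ids=feature_ids,
        batch=np.array([f"batch{b}" for b in batches], dtype=object),
        label=np.array([f"type{t}" for t in types], dtype=object),
    )


def make_trajectory_scenario(
    n_cells: int = 400,
    n_batches: int = 2,
    noise: float = 0.2,
    n_segments: int = 4,
    dim: int = 10,
    path_length: float = 10.0,
    seed: int = 0,
) -> tuple[Embedding, np.ndarray, np.ndarray, np.ndarray]:
    """Cells along a 1-D latent path embedded in ``dim`` dimensions.

    Latent time is uniform on [0, 1]; labels are ``n_segments`` equal time
    segments (``seg0`` holds the starting cells); Gaussian noise of s.d.
    ``noise`` is drawn per batch.  Returns
    ``(embedding, pseudotime, label, batch)``.
    """
    if noise < 0:
        raise ParameterError("noise must be nonnegative")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    direction = _unit_rows(rng.normal(size=(1, dim)))[0]
    batches = np.arange(n_cells) % n_batches
    coords = np.outer(t * path_length, direction)
    for b in range(n_batches):
        rows = batches == b
        coords[rows] += rng.normal(0.0, max(noise, 1e-12), size=(int(rows.sum()), dim))
    seg = np.minimum((t * n_segments).astype(int), n_segments - 1)
    label = np.array([f"seg{s}" for s in seg], dtype=object)
    batch = np.array([f"batch{b}" for b in batches], dtype=object)
    return Embedding(coords), t, label, batch


def make_fragmented_graph(
    n_components: int = 10,
    component_size: int = 3,
    seed: int = 0,
) -> NeighborGraph:
    """A graph of disconnected cliques — the degenerate case in which
    neighbourhood tests and trajectories become uncomputable."""
    n = n_components * component_size
    blocks = []
    for _ in range(n_components):
        b = np.ones((component_size, component_size)) - np.eye(component_size)
        blocks.append(sp.csr_matrix(b))
    return NeighborGraph(sp.block_diag(blocks, format="csr"), k=component_size - 1)
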