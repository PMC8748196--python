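"""Batch-aware feature selection and per-batch scaling.

Two preprocessing variants are combined into four benchmark flavours:
highly-variable-gene (HVG) selection done per batch so that batch variance
cannot drive the gene ranking, and z-scaling applied separately within each
batch.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .core import AnnotatedMatrix, ParameterError

#: genes selected per batch before pooling
HVG_PER_BATCH = 2000
#: expression-mean bins for dispersion normalization
N_DISPERSION_BINS = 20
#: minimum cells per batch for a dispersion estimate
MIN_CELLS_FOR_DISPERSION = 3


def normalized_dispersion(values) -> np.ndarray:
    """Dispersion (variance/mean) per gene, median/MAD-normalized in bins.

    Genes are placed into 20 quantile bins of mean expression; within each
    bin the dispersion is centered by the bin median and scaled by the bin
    median absolute deviation.  Genes with zero mean get dispersion 0.
    """
    if sp.issparse(values):
        x = np.asarray(values.todense(), dtype=float)
    else:
        x = np.asarray(values, dtype=float)
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    n_bins = min(N_DISPERSION_BINS, max(1, len(mean)))
    # quantile bin edges on the mean; duplicate edges collapse
    edges = np.unique(np.quantile(mean, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        bins = np.zeros(len(mean), dtype=int)
    else:
        bins = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, len(edges) - 2)
    out = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        d = disp[sel]
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        out[sel] = (d - med) / mad if mad > 0 else (d - med)
    return out


def _top_hvg(disp: np.ndarray, feature_ids: np.ndarray, n_top: int) -> np.ndarray:
    # ties in dispersion broken by feature id for determinism
    order = np.lexsort((feature_ids, -disp))
    return np.asarray(feature_ids)[order[:n_top]]


def hvg_batch(
    adata: AnnotatedMatrix,
    n_top: int = 2000,
    n_per_batch: int = HVG_PER_BATCH,
) -> list[str]:
    """Batch-aware highly variable gene selection.

    Per batch, the top ``n_per_batch`` genes by normalized dispersion are
    taken; the pooled candidates are then ranked first by the number of
    batches in which they were highly variable and second by the mean
    normalized dispersion across batches, and the top ``n_top`` returned.
    Batches with too few cells for a dispersion estimate are skipped with
    a warning.
    """
    if n_top > adata.n_features:
        raise ParameterError(
            f"n_top={n_top} exceeds number of features ({adata.n_features})"
        )
    feature_ids = adata.feature_ids.astype(str)
    batches = np.unique(adata.batch)
    hv_count = np.zeros(adata.n_features)
    disp_sum = np.zeros(adata.n_features)
    n_used = 0
    pos = {f: i for i, f in enumerate(feature_ids)}
    for b in sorted(batches):
        mask = adata.batch == b
        if int(mask.sum()) < MIN_CELLS_FOR_DISPERSION:
            warnings.warn(
                f"batch {b!r} has fewer than {MIN_CELLS_FOR_DISPERSION} cells; "
                "skipped for HVG selection"
            )
            continue
        disp = normalized_dispersion(adata.values[np.where(mask)[0]])
        disp_sum += disp
        for f in _top_hvg(disp, feature_ids, min(n_per_batch, adata.n_features)):
            hv_count[pos[f]] += 1
        n_used += 1
    if n_used == 0:
        raise ParameterError("no batch large enough for dispersion estimation")
    mean_disp = disp_sum / n_used
    order = np.lexsort((feature_ids, -mean_disp, -hv_count))
    return list(feature_ids[order[:n_top]])


def scale_batch(adata: AnnotatedMatrix) -> AnnotatedMatrix:
    """z-score each gene to zero mean and unit variance within each batch.

    Genes with zero variance inside a batch are set to all-zero there.
    The population variance (ddof=0) is used, so the operation is
    idempotent up to floating tolerance.
    """
    x = adata.dense().astype(float).copy()
    for b in np.unique(adata.batch):
        rows = np.where(adata.batch == b)[0]
        sub = x[rows]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        centered = sub - mu
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
        x[rows] = scaled
    return AnnotatedMatrix(
        values=x,
        cell_ids=adata.cell_ids,
        feature_ids=adata.feature_ids,
        batch=adata.batch,
        label=adata.label,
    )


def select_features(adata: AnnotatedMatrix, features: list[str]) -> AnnotatedMatrix:
    """Subset the matrix to the named features, in the given order."""
    pos = {f: i for i, f in enumerate(adata.feature_ids.astype(str))}
    missing = [f for f in features if f not in pos]
    if missing:
        raise ParameterError(f"{len(missing)} features not present (e.g. {missing[:5]})")
    idx = np.array([pos[f] for f in features])
    return AnnotatedMatrix(
        values=adata.values[:, idx],
        cell_ids=adata.cell_ids,
        feature_ids=adata.feature_ids[idx],
        batch=adata.batch,
        label=adata.label,
    )
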