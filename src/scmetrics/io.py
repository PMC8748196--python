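"""Container I/O: HDF5 annotated-matrix (.h5ad) and MTX + TSV sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import anndata as ad

from .core import AnnotatedMatrix, Embedding, InputError, IntegrationOutput, NeighborGraph


def to_anndata(mat: AnnotatedMatrix) -> ad.AnnData:
    obs = pd.DataFrame(
        {
            "batch": pd.Categorical(mat.batch.astype(str)),
            "label": pd.Categorical(mat.label.astype(str)),
        },
        index=pd.Index(mat.cell_ids.astype(str), name="cell_id"),
    )
    var = pd.DataFrame(index=pd.Index(mat.feature_ids.astype(str), name="feature_id"))
    x = mat.values
    if sp.issparse(x):
        x = sp.csr_matrix(x)
    else:
        x = np.asarray(x, dtype=np.float64)
    return ad.AnnData(X=x, obs=obs, var=var)


def from_anndata(
    adata: ad.AnnData, batch_key: str = "batch", label_key: str = "label"
) -> AnnotatedMatrix:
    for key in (batch_key, label_key):
        if key not in adata.obs:
            raise InputError(f"obs column {key!r} not found (have {list(adata.obs)})")
    return AnnotatedMatrix(
        values=adata.X,
        cell_ids=np.asarray(adata.obs_names),
        feature_ids=np.asarray(adata.var_names),
        batch=np.asarray(adata.obs[batch_key]).astype(str),
        label=np.asarray(adata.obs[label_key]).astype(str),
    )


def read_h5ad(
    path: Union[str, Path], batch_key: str = "batch", label_key: str = "label"
) -> AnnotatedMatrix:
    return from_anndata(ad.read_h5ad(path), batch_key=batch_key, label_key=label_key)


def write_h5ad(mat: AnnotatedMatrix, path: Union[str, Path]) -> None:
    to_anndata(mat).write_h5ad(Path(path))


def read_integration_output(
    path: Union[str, Path],
    kind: str,
    batch_key: str = "batch",
    label_key: str = "label",
    embedding_key: str = "X_emb",
    graph_key: str = "connectivities",
    method: str = "unknown",
) -> IntegrationOutput:
    """Load an integrated result of the stated kind from an .h5ad container.

    ``features`` reads X; ``embedding`` reads ``obsm[embedding_key]``;
    ``graph`` reads ``obsp[graph_key]``.
    """
    adata = ad.read_h5ad(path)
    if kind == "features":
        payload = from_anndata(adata, batch_key=batch_key, label_key=label_key)
        return IntegrationOutput(kind="features", payload=payload, method=method)
    if kind == "embedding":
        if embedding_key not in adata.obsm:
            raise InputError(f"obsm slot {embedding_key!r} not found")
        return IntegrationOutput(
            kind="embedding",
            payload=Embedding(np.asarray(adata.obsm[embedding_key], float)),
            method=method,
        )
    if kind == "graph":
        if graph_key not in adata.obsp:
            raise InputError(f"obsp slot {graph_key!r} not found")
        k = 15
        params = adata.uns.get("neighbors", {}).get("params", {})
        k = int(params.get("n_neighbors", k))
        return IntegrationOutput(
            kind="graph",
            payload=NeighborGraph(sp.csr_matrix(adata.obsp[graph_key]), k=k),
            method=method,
        )
    raise InputError(f"unknown output kind {kind!r}")


def write_embedding_h5ad(
    mat: AnnotatedMatrix, emb: Embedding, path: Union[str, Path], key: str = "X_emb"
) -> None:
    adata = to_anndata(mat)
    adata.obsm[key] = np.asarray(emb.coords, float)
    adata.write_h5ad(Path(path))


def write_graph_h5ad(
    mat: AnnotatedMatrix, g: NeighborGraph, path: Union[str, Path]
) -> None:
    adata = to_anndata(mat)
    adata.obsp["connectivities"] = sp.csr_matrix(g.adjacency)
    adata.uns["neighbors"] = {
        "connectivities_key": "connectivities",
        "params": {"n_neighbors": int(g.k), "metric": "euclidean"},
    }
    adata.write_h5ad(Path(path))


def read_mtx(
    mtx_path: Union[str, Path],
    cells_tsv: Union[str, Path],
    features_tsv: Union[str, Path],
    batch_key: str = "batch",
    label_key: str = "label",
) -> AnnotatedMatrix:
    """Dependency-light fallback: MTX matrix with two TSV sidecars.

    The cell TSV must have a ``cell_id`` column plus the batch/label
    columns; the feature TSV a ``feature_id`` column (or one unnamed
    column of ids).
    """
    x = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    cells = pd.read_csv(cells_tsv, sep="\t")
    feats = pd.read_csv(features_tsv, sep="\t")
    if "cell_id" not in cells.columns:
        raise InputError("cell metadata TSV needs a 'cell_id' column")
    fcol = "feature_id" if "feature_id" in feats.columns else feats.columns[0]
    for key in (batch_key, label_key):
        if key not in cells.columns:
            raise InputError(f"cell metadata TSV lacks column {key!r}")
    return AnnotatedMatrix(
        values=x,
        cell_ids=cells["cell_id"].to_numpy(),
        feature_ids=feats[fcol].to_numpy(),
        batch=cells[batch_key].to_numpy(),
        label=cells[label_key].to_numpy(),
    )


def write_mtx(
    mat: AnnotatedMatrix,
    mtx_path: Union[str, Path],
    cells_tsv: Union[str, Path],
    features_tsv: Union[str, Path],
) -> None:
    x = mat.values if sp.issparse(mat.values) else sp.csr_matrix(np.asarray(mat.values))
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(x))
    pd.DataFrame(
        {"cell_id": mat.cell_ids, "batch": mat.batch, "label": mat.label}
    ).to_csv(cells_tsv, sep="\t", index=False)
    pd.DataFrame({"feature_id": mat.feature_ids}).to_csv(
        features_tsv, sep="\t", index=False
    )


def write_metric_results(
    results: dict, csv_path: Union[str, Path], json_path: Optional[Union[str, Path]] = None
) -> None:
    """Write a {run_name: {metric: value}} mapping as CSV (and JSON)."""
    df = pd.DataFrame(results).T
    df.index.name = "run"
    df.to_csv(csv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    run: {m: (None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)) for m, v in row.items()}
                    for run, row in results.items()
                },
                fh,
                indent=2,
            )
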