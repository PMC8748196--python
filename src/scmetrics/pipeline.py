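"""One-call evaluation of an integration output against its unintegrated input."""

from __future__ import annotations

import logging
import time
from typing import Optional

import numpy as np

from . import batch_metrics as bm
from . import label_metrics as lm
from . import labelfree as lf
from .core import (
    ALL_METRICS,
    AnnotatedMatrix,
    Embedding,
    IntegrationOutput,
    adapt_output,
    align_cells,
    applicable_metrics,
)
from .lisi import embedding_lisi_median, graph_lisi_median

logger = logging.getLogger("scmetrics")


def _scaled_lisi(median: float, n_cat: int, direction: str) -> Optional[float]:
    if not np.isfinite(median) or n_cat < 2:
        return None
    if direction == "mixing":
        return float(np.clip((median - 1.0) / (n_cat - 1.0), 0.0, 1.0))
    return float(np.clip((n_cat - median) / (n_cat - 1.0), 0.0, 1.0))


def run_metrics(
    unintegrated: AnnotatedMatrix,
    output: IntegrationOutput,
    trajectory: Optional[lf.TrajectoryAnnotation] = None,
    seed: int = 0,
    n_pcs: int = 50,
    k: int = 15,
) -> dict:
    """Compute every metric applicable to the output kind.

    Returns a ``{metric_name: value_or_None}`` mapping over all 14 metrics;
    metrics inapplicable to the output kind (or whose preconditions fail)
    are ``None``.  Feature-matrix outputs are re-aligned to the
    unintegrated cell order by cell id.
    """
    if output.kind == "features":
        idx = align_cells(unintegrated.cell_ids, output.payload.cell_ids)
        if not np.array_equal(idx, np.arange(len(idx))):
            output = IntegrationOutput(
                kind="features",
                payload=output.payload.subset_cells(idx),
                method=output.method,
                scaled=output.scaled,
                hvg=output.hvg,
            )
    batch, label = unintegrated.batch, unintegrated.label
    emb, graph = adapt_output(output, n_pcs=n_pcs, k=k)
    allowed = applicable_metrics(output.kind)
    n_batches = len(set(batch))
    n_labels = len(set(label))
    results: dict = {m: None for m in ALL_METRICS}

    def _run(name, fn):
        if name not in allowed:
            logger.info("%s: skipped (not applicable to %s output)", name, output.kind)
            return
        t0 = time.perf_counter()
        try:
            results[name] = fn()
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("%s: failed (%s)", name, exc)
            results[name] = None
        if results[name] is None:
            logger.info("%s: missing (precondition not met)", name)
        else:
            logger.info("%s = %.4f (%.2fs)", name, results[name], time.perf_counter() - t0)

    nmi_ari: dict = {}

    def _cluster():
        if not nmi_ari:
            nmi, ari, _ = lm.nmi_ari_optimized(graph, label, seed=seed)
            nmi_ari["NMI"] = nmi
            nmi_ari["ARI"] = ari

    _run("graph_connectivity", lambda: bm.graph_connectivity(graph, label))
    _run(
        "kBET",
        lambda: bm.kbet(emb if emb is not None else graph, batch, label, seed=seed),
    )
    _run(
        "iLISI",
        lambda: _scaled_lisi(
            embedding_lisi_median(emb, batch)
            if emb is not None
            else graph_lisi_median(graph, batch),
            n_batches,
            "mixing",
        ),
    )
    _run(
        "cLISI",
        lambda: _scaled_lisi(
            embedding_lisi_median(emb, label)
            if emb is not None
            else graph_lisi_median(graph, label),
            n_labels,
            "separation",
        ),
    )
    _run("NMI_cluster/label", lambda: (_cluster(), nmi_ari["NMI"])[1])
    _run("ARI_cluster/label", lambda: (_cluster(), nmi_ari["ARI"])[1])
    _run("isolated_label_F1", lambda: lm.isolated_label_f1(graph, label, batch, seed=seed))
    if trajectory is not None:
        _run("trajectory", lambda: lf.trajectory_conservation(trajectory, output, label, k=k))
    else:
        logger.info("trajectory: skipped (no trajectory annotation supplied)")
    if emb is not None:
        _run("ASW_batch", lambda: bm.batch_asw(emb, batch, label))
        _run("ASW_label", lambda: lm.celltype_asw(emb, label))
        _run("isolated_label_silhouette", lambda: lm.isolated_label_asw(emb, label, batch))
        _run("PCR_batch", lambda: bm.pcr_batch(unintegrated.values, emb, batch, n_pcs=n_pcs))
        _run("cell_cycle_conservation", lambda: lf.cc_conservation(unintegrated, emb, seed=seed))
    if output.kind == "features":
        _run("hvg_overlap", lambda: lf.hvg_conservation(unintegrated, output.payload))
    return results
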