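"""Batch-removal metrics: silhouette mixing, PC regression, connectivity,
kBET and graph iLISI."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from scmetrics.batch_metrics import (
    batch_asw,
    graph_connectivity,
    graph_ilisi,
    kbet,
    pcr_batch,
    variance_explained,
)
from scmetrics.core import Embedding, NeighborGraph, build_knn_graph, pca_embedding
from scmetrics.fixtures import make_embedding_scenario, make_fragmented_graph
from scmetrics.lisi import simpson_index


# ---------------------------------------------------------------- silhouette


def manual_silhouette(points, assignment):
    """Hand silhouette arithmetic for tiny configurations."""
    points = np.asarray(points, float)
    out = []
    for i, p in enumerate(points):
        own = [j for j in range(len(points)) if assignment[j] == assignment[i] and j != i]
        a = np.mean([np.linalg.norm(p - points[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(p - points[j]) for j in range(len(points)) if assignment[j] == c])
            for c in set(assignment)
            if c != assignment[i]
        )
        out.append((b - a) / max(a, b))
    return np.array(out)


@pytest.fixture()
def eight_point_toy():
    # two labels x two batches in the plane; batches offset inside labels
    points = np.array(
        [[0, 0], [0, 1], [0.5, 0], [0.5, 1],
         [10, 0], [10, 1], [10.5, 0], [10.5, 1]],
        dtype=float,
    )
    label = np.array(["L1"] * 4 + ["L2"] * 4, dtype=object)
    batch = np.array(["a", "a", "b", "b"] * 2, dtype=object)
    return points, batch, label


def test_batch_asw_matches_manual_silhouette(eight_point_toy):
    points, batch, label = eight_point_toy
    expected = []
    for lab in ("L1", "L2"):
        cells = label == lab
        s = manual_silhouette(points[cells], batch[cells])
        expected.append(np.mean(1.0 - np.abs(s)))
    got = batch_asw(Embedding(points), batch, label)
    assert got == pytest.approx(np.mean(expected), abs=1e-12)


def test_batch_asw_endpoints():
    rng = np.random.default_rng(0)
    # interleaved batches in one label -> near 1
    mixed = Embedding(rng.normal(size=(200, 4)))
    batch = np.array(["a", "b"] * 100, dtype=object)
    label = np.array(["t"] * 200, dtype=object)
    assert batch_asw(mixed, batch, label) > 0.85
    # two tight, distant batch sub-clusters inside one label -> near 0
    coords = np.vstack([rng.normal(0, 0.01, (50, 2)), rng.normal(100, 0.01, (50, 2))])
    split = Embedding(coords)
    batch2 = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
    assert batch_asw(split, batch2, np.array(["t"] * 100, dtype=object)) < 0.05


def test_batch_asw_missing_without_multibatch_label(mixture_scenario):
    emb, _, label = mixture_scenario
    single = np.array(["only"] * emb.n_cells, dtype=object)
    assert batch_asw(emb, single, label) is None


# ----------------------------------------------------------------------- PCR


def test_pcr_zero_when_nothing_changes(mixture_scenario):
    emb, batch, _ = mixture_scenario
    assert pcr_batch(emb, emb, batch) == 0.0


def test_pcr_term_by_term_oracle(rng):
    x = rng.normal(size=(80, 6))
    batch = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
    coords, var = pca_embedding(x, n_pcs=6)
    onehot = (batch == "b").astype(float)
    expected = 0.0
    for i in range(coords.shape[1]):
        y = coords[:, i]
        design = np.column_stack([np.ones(80), onehot])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r2 = 1 - np.sum((y - design @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
        expected += var[i] * r2
    assert variance_explained(x, batch) == pytest.approx(expected, rel=1e-9)


def test_pcr_near_one_when_batch_axis_removed(rng):
    # batch effect exactly along one axis dominating the variance
    n = 100
    base = rng.normal(size=(n, 4))
    batch = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
    shift = np.zeros((n, 1))
    shift[50:] = 25.0
    before = np.hstack([shift + rng.normal(scale=0.1, size=(n, 1)), base])
    after = np.hstack([np.zeros((n, 1)), base])
    score = pcr_batch(before, after, batch)
    assert score > 0.95


def test_pcr_missing_without_batch_signal():
    x = np.tile(np.arange(10.0)[:, None], (1, 3))
    batch = np.array(["a"] * 10, dtype=object)
    assert pcr_batch(x, x, batch) is None


# -------------------------------------------------------- graph connectivity


def test_connectivity_one_when_labels_connected(mixture_scenario):
    emb, _, label = mixture_scenario
    g = build_knn_graph(emb, 15)
    assert graph_connectivity(g, label) == 1.0


def test_connectivity_split_label_contributes_half():
    g = make_fragmented_graph(2, 10)  # one label spread over two components
    label = np.array(["t"] * 20, dtype=object)
    assert graph_connectivity(g, label) == 0.5


def test_connectivity_matches_unionfind_oracle(rng):
    a = sp.random(100, 100, density=0.03, random_state=1, format="csr")
    a = a.maximum(a.T)
    g = NeighborGraph(a, k=3)
    label = np.array([f"l{i % 3}" for i in range(100)], dtype=object)
    g_nx = nx.from_scipy_sparse_array(g.adjacency)
    expected = np.mean(
        [
            max(len(c) for c in nx.connected_components(g_nx.subgraph(np.where(label == l)[0])))
            / np.sum(label == l)
            for l in sorted(set(label))
        ]
    )
    assert graph_connectivity(g, label) == pytest.approx(expected)


# ---------------------------------------------------------------------- kBET


def test_kbet_fragmented_label_scores_one():
    # 30 cells in 10 disconnected triplets: every component is smaller than
    # k x 3 with k clamped to 10, so the per-label score is 1
    g = make_fragmented_graph(10, 3)
    batch = np.array(["a", "b"] * 15, dtype=object)
    label = np.array(["t"] * 30, dtype=object)
    final, per_label = kbet(g, batch, label, return_per_label=True)
    assert per_label["t"] == 1.0
    assert final == 0.0


def test_kbet_type_one_error_calibrated():
    """Under exchangeable batches the rejection rate stays near alpha."""
    rates = []
    for seed in range(20):
        emb, batch, label = make_embedding_scenario(
            n_cells=2000, n_types=1, n_batches=2, batch_shift=0.0, seed=100 + seed
        )
        score = kbet(emb, batch, label, seed=seed)
        rates.append(1.0 - score)  # single label: rejection rate
    assert abs(np.mean(rates) - 0.05) <= 0.03


def test_kbet_separated_batches_near_zero():
    emb, batch, label = make_embedding_scenario(
        n_cells=1200, n_types=2, n_batches=2, batch_shift=40.0, seed=4
    )
    assert kbet(emb, batch, label, seed=0) <= 0.05


def test_kbet_missing_for_single_batch(mixture_scenario):
    emb, _, label = mixture_scenario
    batch = np.array(["only"] * emb.n_cells, dtype=object)
    assert kbet(emb, batch, label) is None


# ---------------------------------------------------------------------- LISI


def test_simpson_uniform_kernel_hand_computed():
    # 10 neighbours split 6/4 between two batches, equal distances ->
    # uniform weights, index = 1 / (0.6^2 + 0.4^2)
    dist = np.ones(10)
    codes = np.array([0] * 6 + [1] * 4)
    got = simpson_index(dist, codes, 2, perplexity=10)
    assert got == pytest.approx(1.0 / 0.52, rel=1e-9)


def test_ilisi_endpoints():
    # perfectly separated batches -> 0
    emb, batch, label = make_embedding_scenario(
        n_cells=400, n_types=1, n_batches=2, batch_shift=60.0, seed=8
    )
    g = build_knn_graph(emb, 15)
    assert graph_ilisi(g, batch) == pytest.approx(0.0, abs=0.02)
    # exchangeable batches -> near 1
    emb2, batch2, _ = make_embedding_scenario(
        n_cells=400, n_types=1, n_batches=2, batch_shift=0.0, seed=8
    )
    g2 = build_knn_graph(emb2, 15)
    assert graph_ilisi(g2, batch2) > 0.9
    assert graph_ilisi(g2, np.array(["only"] * 400, dtype=object)) is None


# ------------------------------------------------- monotone fixture response


def test_batch_metrics_decrease_with_batch_shift():
    """Raising the synthetic batch shift worsens every mixing metric."""
    levels = [0.0, 0.5, 1.5]
    med = {m: [] for m in ("asw", "kbet", "ilisi")}
    for delta in levels:
        vals = {m: [] for m in med}
        for seed in range(5):
            emb, batch, label = make_embedding_scenario(
                n_cells=450, n_types=1, n_batches=2, batch_shift=delta, seed=seed
            )
            g = build_knn_graph(emb, 15)
            vals["asw"].append(batch_asw(emb, batch, label))
            vals["kbet"].append(kbet(emb, batch, label, seed=seed))
            vals["ilisi"].append(graph_ilisi(g, batch))
        for m in med:
            med[m].append(np.median(vals[m]))
    for m, series in med.items():
        assert series[0] > series[1] > series[2], (m, series)
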