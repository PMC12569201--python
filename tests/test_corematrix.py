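"""Normalization, embedding, clustering, integration and phase contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from osnatlas import corematrix
from osnatlas.corematrix import (
    DataError,
    assign_phases,
    cluster_graph,
    embed_and_graph,
    integrate_conditions,
    normalize,
)

from conftest import make_expr


# ---------------------------------------------------------------- normalize

def test_normalize_examples():
    adata = make_expr(np.array([[10.0, 0.0], [2.0, 3.0]]))
    out = normalize(adata, target_sum=10)
    x = np.asarray(out.X.todense())
    assert np.allclose(x[0], [np.log1p(10), 0.0])
    lib = 5.0
    assert np.allclose(x[1], np.log1p(np.array([2, 3]) * 10 / lib))


def test_normalize_three_gene_toy():
    adata = make_expr(np.array([[2.0, 3.0, 5.0]]))
    out = normalize(adata, target_sum=10)
    assert np.allclose(
        np.asarray(out.X.todense())[0], np.log1p([2.0, 3.0, 5.0])
    )


def test_normalize_drops_empty_cells_with_warning(caplog):
    adata = make_expr(np.array([[1.0, 1.0], [0.0, 0.0]]))
    with caplog.at_level("WARNING"):
        out = normalize(adata)
    assert out.n_obs == 1
    assert "zero library size" in caplog.text


def test_normalize_rejects_negative_counts():
    with pytest.raises(DataError):
        normalize(make_expr(np.array([[-1.0, 2.0]])))


def test_normalize_scale_equivariant():
    """Multiplying a cell's counts by a constant leaves its profile unchanged."""
    rng = np.random.default_rng(0)
    vals = rng.poisson(2.0, size=(5, 40)).astype(float)
    vals[0] += 1  # no zero rows
    out1 = normalize(make_expr(vals), target_sum=1e4)
    scaled = vals.copy()
    scaled[2] *= 7
    out2 = normalize(make_expr(scaled), target_sum=1e4)
    assert np.allclose(
        np.asarray(out1.X.todense())[2], np.asarray(out2.X.todense())[2]
    )


# ----------------------------------------------------------- embed_and_graph

def test_separated_blobs_have_no_cross_edges():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.1, size=(30, 20))
    b = rng.normal(50, 0.1, size=(30, 20))
    adata = make_expr(np.abs(np.vstack([a, b])))
    g = embed_and_graph(adata, n_hvg=20, n_pcs=5, k=5, seed=0)
    adj = g.adjacency.tocoo()
    cross = ((adj.row < 30) & (adj.col >= 30)) | ((adj.row >= 30) & (adj.col < 30))
    assert not cross.any()
    # brute-force confirmation: max within-blob distance << min cross distance
    from scipy.spatial.distance import cdist

    d_cross = cdist(g.pcs[:30], g.pcs[30:]).min()
    d_within = cdist(g.pcs[:30], g.pcs[:30]).max()
    assert d_cross > 10 * d_within


def test_duplicate_cells_are_mutual_neighbors():
    vals = np.vstack([np.ones((2, 10)), np.zeros((1, 10)) + 5.0])
    g = embed_and_graph(make_expr(vals), n_hvg=10, n_pcs=2, k=1, seed=0)
    assert g.adjacency[0, 1] == g.adjacency[1, 0]


def test_rank2_data_fully_captured_by_two_pcs():
    rng = np.random.default_rng(0)
    basis = rng.normal(size=(2, 30))
    coefs = rng.normal(size=(40, 2))
    vals = coefs @ basis
    vals -= vals.min()
    adata = make_expr(vals)
    g = embed_and_graph(adata, n_hvg=30, n_pcs=2, k=3, seed=0)
    # reconstruction residual ~ 0: PC coordinates explain all variance
    centered = vals - vals.mean(axis=0)
    total = (centered**2).sum()
    explained = (g.pcs**2).sum()
    assert abs(total - explained) / total < 1e-8


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(2)
    vals = np.abs(rng.normal(size=(50, 30)))
    g1 = embed_and_graph(make_expr(vals), n_hvg=30, n_pcs=5, k=3, seed=0)
    g2 = embed_and_graph(make_expr(vals), n_hvg=30, n_pcs=5, k=3, seed=0)
    assert np.allclose(g1.pcs, g2.pcs)


def test_hvg_request_larger_than_genes_rejected():
    with pytest.raises(ValueError):
        corematrix.select_hvg(make_expr(np.ones((3, 4))), 10)


# -------------------------------------------------------------- cluster_graph

def _clique_graph(sizes):
    n = sum(sizes)
    adj = sparse.lil_matrix((n, n))
    start = 0
    for s in sizes:
        for i in range(start, start + s):
            for j in range(i + 1, start + s):
                adj[i, j] = adj[j, i] = 1.0
        start += s
    return adj.tocsr()


# high resolutions legitimately fragment cliques under RB modularity
@pytest.mark.parametrize("resolution", [0.1, 1.0, 2.0])
def test_two_disconnected_cliques_two_clusters(resolution):
    adj = _clique_graph([10, 10])
    labels = cluster_graph(adj, resolution=resolution, seed=0)
    assert len(np.unique(labels)) == 2
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1


def test_single_clique_single_cluster_low_resolution():
    labels = cluster_graph(_clique_graph([12]), resolution=0.5, seed=0)
    assert len(np.unique(labels)) == 1


def test_empty_graph_rejected():
    with pytest.raises(DataError):
        cluster_graph(sparse.csr_matrix((0, 0)), 1.0, 0)


def test_cluster_labels_contiguous_and_permutation_stable():
    adj = _clique_graph([8, 8, 8])
    labels = cluster_graph(adj, resolution=1.0, seed=0)
    assert sorted(np.unique(labels)) == list(range(labels.max() + 1))
    # permuting node order only relabels the partition
    perm = np.random.default_rng(0).permutation(24)
    padj = adj[perm][:, perm]
    plabels = cluster_graph(padj, resolution=1.0, seed=0)
    df = pd.DataFrame({"orig": labels[perm], "perm": plabels})
    assert (df.groupby("orig")["perm"].nunique() == 1).all()
    assert (df.groupby("perm")["orig"].nunique() == 1).all()


# ------------------------------------------------------- integrate_conditions

def test_concat_is_identity_on_values():
    rng = np.random.default_rng(0)
    a = make_expr(rng.poisson(2, (10, 20)).astype(float))
    b = make_expr(rng.poisson(2, (8, 20)).astype(float),
                  cells=[f"d{i}" for i in range(8)])
    joint = integrate_conditions(a, b, mode="concat")
    stacked = np.vstack([np.asarray(a.X.todense()), np.asarray(b.X.todense())])
    assert np.array_equal(np.asarray(joint.X.todense()), stacked)
    assert list(joint.obs["condition"]) == ["control"] * 10 + ["pcd_blocked"] * 8


def test_gene_mismatch_rejected():
    a = make_expr(np.ones((3, 3)), genes=["a", "b", "c"])
    b = make_expr(np.ones((3, 3)), genes=["a", "b", "d"])
    with pytest.raises(DataError, match="d"):
        integrate_conditions(a, b)


def test_mnn_correct_removes_constant_shift():
    rng = np.random.default_rng(0)
    base = np.abs(rng.normal(5, 1, size=(200, 30)))
    ctrl = make_expr(base)
    blocked = make_expr(base + 2.0, cells=[f"d{i}" for i in range(200)])
    before = 2.0
    joint = integrate_conditions(ctrl, blocked, mode="mnn_correct", seed=0)
    X = np.asarray(joint.X.todense())
    after = np.abs(X[200:].mean(axis=0) - X[:200].mean(axis=0)).mean()
    assert after < 0.1 * before


def test_mnn_correct_leaves_exclusive_population_separable():
    rng = np.random.default_rng(1)
    shared_c = np.abs(rng.normal(5, 0.5, size=(40, 20)))
    shared_b = np.abs(rng.normal(5, 0.5, size=(40, 20)))
    exclusive = np.abs(rng.normal(15, 0.5, size=(20, 20)))
    ctrl = make_expr(shared_c)
    blocked = make_expr(np.vstack([shared_b, exclusive]),
                        cells=[f"d{i}" for i in range(60)])
    joint = integrate_conditions(ctrl, blocked, mode="mnn_correct", seed=0)
    X = np.asarray(joint.X.todense())
    from sklearn.metrics import silhouette_score

    labels = np.array([0] * 80 + [1] * 20)
    assert silhouette_score(X, labels) > 0


# --------------------------------------------------------------- assign_phases

POOLS = {"42h": "mid", "64h": "late", "24h": "early", "80h": "late"}


def test_pool_mapping_mid():
    cells = pd.DataFrame(
        dict(condition=["control"], pool=["42h"]), index=["c0"]
    )
    out = assign_phases(cells, POOLS)
    assert out.loc["c0", "phase"] == "mid"


def test_control_cells_reclassified_by_reference_majority():
    """Control cells pooled 'mid' in a 95%-late reference cluster move to late."""
    n_ref = 40
    cells = pd.DataFrame(
        dict(
            condition=["pcd_blocked"] * n_ref + ["control"] * 5,
            pool=["64h"] * 38 + ["42h"] * 2 + ["42h"] * 5,
        ),
        index=[f"c{i}" for i in range(n_ref + 5)],
    )
    clusters = np.zeros(n_ref + 5, dtype=int)
    out = assign_phases(cells, POOLS, clusters)
    assert (out.loc[out["condition"] == "control", "phase"] == "late").all()


def test_unanimous_direct_mapping_is_identity():
    cells = pd.DataFrame(
        dict(condition=["control", "pcd_blocked"], pool=["24h", "24h"]),
        index=["a", "b"],
    )
    out = assign_phases(cells, POOLS, np.zeros(2, int))
    assert list(out["phase"]) == ["early", "early"]


def test_mixed_reference_cluster_left_untouched():
    cells = pd.DataFrame(
        dict(
            condition=["pcd_blocked"] * 10 + ["control"] * 4,
            pool=["42h"] * 5 + ["64h"] * 5 + ["42h"] * 4,
        ),
        index=[f"c{i}" for i in range(14)],
    )
    out = assign_phases(cells, POOLS, np.zeros(14, int))
    assert (out.loc[out["condition"] == "control", "phase"] == "mid").all()


def test_unknown_pool_rejected():
    cells = pd.DataFrame(dict(condition=["control"], pool=["99h"]), index=["c"])
    with pytest.raises(DataError):
        assign_phases(cells, POOLS)
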