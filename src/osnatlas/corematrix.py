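"""Normalization, embedding, graph clustering, integration, phase labels.

The scaffold on which annotation and death-fate detection run.  The
normalization is a depth-scaled log1p transform (counts-per-``target_sum``);
rank-based statistics downstream are insensitive to the monotone choice.
Cross-condition integration defaults to plain concatenation (synthetic
conditions share no batch effect), with an optional mutual-nearest-neighbor
shift correction for real batch structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)


class DataError(ValueError):
    pass


def normalize(counts: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """log1p(count * target_sum / library size), dropping empty cells.

    Cells with zero library size are dropped with a logged warning.  The
    target_sum used is recorded in ``.uns`` so downstream fold-change
    pseudocounts can match it.
    """
    X = counts.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    if X.nnz and X.data.min() < 0:
        raise DataError("negative counts")
    lib = np.asarray(X.sum(axis=1)).ravel()
    keep = lib > 0
    if not keep.all():
        log.warning("dropping %d cells with zero library size", (~keep).sum())
    X = X[keep].astype(np.float64)
    lib = lib[keep]
    scaled = sparse.diags(target_sum / lib) @ X
    scaled.data = np.log1p(scaled.data)
    out = ad.AnnData(
        X=scaled.tocsr(),
        obs=counts.obs.iloc[keep].copy(),
        var=counts.var.copy(),
    )
    out.uns["target_sum"] = float(target_sum)
    out.uns["provenance"] = "lognorm"
    return out


@dataclass
class NeighborGraph:
    """Symmetric kNN graph with PC coordinates."""

    adjacency: sparse.csr_matrix  # symmetric, weights = Euclidean PC distance
    pcs: np.ndarray
    k: int

    def igraph(self) -> igraph.Graph:
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        g = igraph.Graph(
            n=self.adjacency.shape[0],
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        )
        return g


def select_hvg(expr: ad.AnnData, n_hvg: int) -> np.ndarray:
    """Indices of the ``n_hvg`` highest-variance genes (ties by index)."""
    if n_hvg > expr.n_vars:
        raise ValueError(f"n_hvg={n_hvg} exceeds {expr.n_vars} genes")
    X = expr.X
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = sq - mean**2
    order = np.lexsort((np.arange(len(var)), -var))
    return np.sort(order[:n_hvg])


def embed_and_graph(
    expr: ad.AnnData,
    n_hvg: int = 2000,
    n_pcs: int = 50,
    k: int = 15,
    seed: int = 0,
) -> NeighborGraph:
    """PCA on highly variable genes plus a union-symmetrized kNN graph.

    PC signs follow a fixed convention: the largest-|loading| coordinate of
    each component is made positive, so the embedding is deterministic.
    """
    n_hvg = min(n_hvg, expr.n_vars)
    if n_pcs >= min(n_hvg, expr.n_obs):
        n_pcs = max(1, min(n_hvg, expr.n_obs) - 1)
    hvg = select_hvg(expr, n_hvg)
    X = expr.X[:, hvg]
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(X)
    # deterministic sign convention
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            pcs[:, j] *= -1
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(pcs))).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(len(pcs)), idx.shape[1] - 1)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    adj = sparse.csr_matrix((vals, (rows, cols)), shape=(len(pcs),) * 2)
    adj = adj.maximum(adj.T)  # union symmetrization
    return NeighborGraph(adjacency=adj, pcs=pcs, k=k)


def cluster_graph(
    graph: NeighborGraph | sparse.spmatrix,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden modularity communities with a resolution parameter.

    Labels are contiguous integers from 0, canonically ordered by the
    smallest member index so they are stable under cell permutation.
    """
    adj = graph.adjacency if isinstance(graph, NeighborGraph) else sparse.csr_matrix(graph)
    if adj.shape[0] == 0:
        raise DataError("empty graph")
    coo = sparse.triu(adj, k=1).tocoo()
    g = igraph.Graph(n=adj.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # canonical relabeling: order clusters by first occurrence
    order = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    return labels


def integrate_conditions(
    ctrl: ad.AnnData,
    blocked: ad.AnnData,
    mode: str = "concat",
    n_pcs: int = 30,
    k_anchor: int = 10,
    seed: int = 0,
) -> ad.AnnData:
    """Stack the two conditions into one matrix with a condition covariate.

    ``concat`` is the identity on values.  ``mnn_correct`` shifts each
    PCD-blocked cell by the mean difference vector to its mutual nearest
    control neighbors in PC space; blocked cells without mutual anchors
    borrow the average correction of anchored blocked cells among their
    neighbors, and cells in fully anchor-free neighborhoods
    (condition-exclusive populations) are left uncorrected.
    """
    if list(ctrl.var_names) != list(blocked.var_names):
        missing = set(ctrl.var_names) ^ set(blocked.var_names)
        raise DataError(f"gene sets differ; symmetric difference: {sorted(missing)[:10]}")
    ctrl = ctrl.copy()
    blocked = blocked.copy()
    ctrl.obs["condition"] = ctrl.obs.get("condition", "control")
    blocked.obs["condition"] = blocked.obs.get("condition", "pcd_blocked")
    joint = ad.concat([ctrl, blocked], join="outer", merge="same", index_unique=None)
    joint.var = ctrl.var.copy()
    joint.uns.update(ctrl.uns)
    if mode == "concat":
        return joint
    if mode != "mnn_correct":
        raise ValueError(f"unknown integration mode {mode!r}")

    Xc = np.asarray(ctrl.X.todense()) if sparse.issparse(ctrl.X) else np.asarray(ctrl.X)
    Xb = np.asarray(blocked.X.todense()) if sparse.issparse(blocked.X) else np.asarray(blocked.X)
    pca = PCA(n_components=min(n_pcs, min(Xc.shape[1], Xc.shape[0] + Xb.shape[0]) - 1),
              svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(np.vstack([Xc, Xb]))
    pc, pb = pcs[: len(Xc)], pcs[len(Xc):]
    kk = min(k_anchor, len(pc), len(pb))
    nb_of_b = NearestNeighbors(n_neighbors=kk).fit(pc)
    _, b2c = nb_of_b.kneighbors(pb)
    nb_of_c = NearestNeighbors(n_neighbors=kk).fit(pb)
    _, c2b = nb_of_c.kneighbors(pc)
    c_sets = [set(row) for row in c2b]
    deltas = np.zeros_like(Xb)
    anchored = np.zeros(len(pb), dtype=bool)
    for i in range(len(pb)):
        partners = [j for j in b2c[i] if i in c_sets[j]]
        if partners:
            deltas[i] = Xc[partners].mean(axis=0) - Xb[i]
            anchored[i] = True
    if anchored.any() and not anchored.all():
        # unanchored cells borrow the mean correction of anchored cells
        # among their blocked-side neighbors; fully anchor-free
        # neighborhoods (exclusive populations) stay untouched
        kk_b = min(k_anchor, len(pb) - 1)
        nb_b = NearestNeighbors(n_neighbors=kk_b + 1).fit(pb)
        _, b2b = nb_b.kneighbors(pb)
        for i in np.where(~anchored)[0]:
            near = [j for j in b2b[i][1:] if anchored[j]]
            if near:
                deltas[i] = deltas[near].mean(axis=0)
    corrected = Xb + deltas
    log.info("mnn_correct: %d/%d blocked cells anchored", int(anchored.sum()), len(pb))
    Xj = np.vstack([Xc, corrected])
    out = ad.AnnData(X=sparse.csr_matrix(Xj), obs=joint.obs.copy(), var=joint.var.copy())
    out.uns.update(joint.uns)
    return out


def assign_phases(
    cells: pd.DataFrame,
    pools: dict[str, str],
    clusters: np.ndarray | None = None,
    reference_condition: str = "pcd_blocked",
    majority_frac: float = 0.75,
) -> pd.DataFrame:
    """Map time pools to phases; re-classify control cells by cluster majority.

    Each cell's pool label is mapped through ``pools`` to a phase.  When a
    cluster labeling is supplied, the majority phase of each cluster is
    computed on the reference (PCD-blocked) condition and, when that
    majority is decisive (at least ``majority_frac`` of reference cells),
    the cluster phase is extrapolated to every cell of the cluster in both
    conditions — recovering cells whose collection pool mixed
    developmental stages.  Clusters whose reference cells straddle phases
    are left untouched: reassigning there would fabricate asymmetries
    between conditions.  Clusters with no reference cells keep their own
    pool phases (logged).
    """
    out = cells.copy()
    unknown = set(out["pool"].unique()) - set(pools)
    if unknown:
        raise DataError(f"pools without a phase mapping: {sorted(unknown)}")
    out["phase"] = out["pool"].map(pools)
    if clusters is None:
        return out
    out["_cluster"] = np.asarray(clusters)
    ref = out[out["condition"] == reference_condition]
    for cl, grp in out.groupby("_cluster"):
        ref_phases = ref.loc[ref["_cluster"] == cl, "phase"]
        if ref_phases.empty:
            log.info("cluster %s has no %s cells; keeping pool phases", cl, reference_condition)
            continue
        counts = ref_phases.value_counts()
        if counts.iloc[0] / counts.sum() < majority_frac:
            continue
        maj = counts.index[0]
        mask = (out["_cluster"] == cl) & (out["phase"] != maj)
        if mask.any():
            out.loc[mask, "phase"] = maj
    return out.drop(columns="_cluster")
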