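"""Class tree in TF space, graph-geodesic pseudotime, abundance regression."""

from __future__ import annotations

import logging
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.sparse import csgraph
from scipy.spatial.distance import pdist, squareform

from .lineage import UNANNOTATED

log = logging.getLogger(__name__)


def class_tree(
    expr: ad.AnnData,
    class_labels: pd.Series,
    tf_panel: Sequence[str],
    linkage: str = "average",
) -> str:
    """Hierarchical tree over classes in differentially-expressed-TF space.

    Each class is summarized by its mean expression vector restricted to
    the TF panel; the tree is agglomerative (average linkage by default)
    on the Euclidean distance matrix and returned as a Newick string with
    branch lengths.  Classes are processed in alphabetical order so the
    output is deterministic.
    """
    panel = [g for g in tf_panel if g in set(expr.var_names)]
    if not panel:
        raise ValueError("TF panel has no genes present in the matrix")
    labels = pd.Series(class_labels)
    classes = sorted(c for c in labels.unique() if c != UNANNOTATED)
    if len(classes) < 3:
        raise ValueError("need at least 3 classes for a tree")
    idx = [list(expr.var_names).index(g) for g in panel]
    X = expr.X[:, idx]
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)
    profiles = np.vstack([
        X[(labels == c).to_numpy()].mean(axis=0) for c in classes
    ])
    dist = pdist(profiles, metric="euclidean")
    Z = hierarchy.linkage(dist, method=linkage)
    tree = hierarchy.to_tree(Z)

    def newick(node, parent_height: float) -> str:
        length = max(parent_height - getattr(node, "dist", 0.0), 0.0)
        if node.is_leaf():
            return f"{classes[node.id]}:{length:.10g}"
        left = newick(node.get_left(), node.dist)
        right = newick(node.get_right(), node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({newick(tree.get_left(), tree.dist)},{newick(tree.get_right(), tree.dist)});"


def pseudotime(
    data,
    cells: pd.DataFrame,
    lineage_col: str = "lineage",
    phase_col: str = "phase",
    n_pcs: int = 10,
    n_hvg: int = 300,
    k: int = 15,
    n_smooth: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Graph-geodesic pseudotime per lineage, scaled to [0, 1].

    Each lineage is extracted and re-embedded on its own (lineage-specific
    PCA and kNN graph) — global embeddings mix lineages and fragment
    per-lineage subgraphs.  The root is the medoid of the lineage's
    early-phase cells ("the tip of the early stage"); pseudotime is the
    shortest-path distance along the weighted graph (edge weights =
    PC-space distances), denoised by ``n_smooth`` rounds of neighbor
    averaging (the cheap analogue of projecting cells onto a principal
    curve) and min-max scaled to [0, 1] per lineage.
    Disconnected components get their own roots; lineages without early
    cells root at their earliest available phase (logged).  Cells outside
    any lineage get NaN.

    ``data`` is the normalized expression AnnData (preferred), or an
    existing :class:`~osnatlas.corematrix.NeighborGraph` / sparse
    adjacency to reuse a precomputed global graph.
    """
    import anndata as ad

    from .corematrix import embed_and_graph

    is_expr = isinstance(data, ad.AnnData)
    if not is_expr:
        adjacency = getattr(data, "adjacency", data)
        pcs = getattr(data, "pcs", None)
    pt = pd.Series(np.nan, index=cells.index, name="pseudotime")
    phase_rank = {"early": 0, "mid": 1, "late": 2}
    for lin, grp in cells.groupby(lineage_col):
        if lin == UNANNOTATED or len(grp) < 3:
            continue
        idx = np.where(cells.index.isin(grp.index))[0]
        if is_expr:
            sub_expr = data[cells.index[idx]]
            g = embed_and_graph(sub_expr, n_hvg=min(n_hvg, sub_expr.n_vars),
                                n_pcs=min(n_pcs, len(idx) - 1),
                                k=min(k, len(idx) - 1), seed=seed)
            sub, coords_all = g.adjacency, g.pcs
        else:
            sub = adjacency[idx][:, idx]
            coords_all = pcs[idx] if pcs is not None else None
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        dist_all = np.full(len(idx), np.nan)
        phases = grp[phase_col].map(phase_rank).to_numpy()
        for kk in range(n_comp):
            members = np.where(comp == kk)[0]
            ph = phases[members]
            best = ph.min()
            if best > 0:
                log.info("lineage %s component %d has no early cells; rooting at %s",
                         lin, kk, {v: p for p, v in phase_rank.items()}[best])
            roots = members[ph == best]
            if coords_all is not None and len(roots) > 1:
                coords = coords_all[roots]
                med = np.argmin(((coords[:, None] - coords[None]) ** 2).sum(-1).sum(1))
                root = roots[med]
            else:
                root = roots[0]
            d = csgraph.dijkstra(sub, directed=False, indices=root)
            dist_all[members] = d[members]
        if n_smooth > 0:
            A = (sub > 0).astype(float) + sparse.eye(sub.shape[0])
            A = sparse.diags(1.0 / np.asarray(A.sum(axis=1)).ravel()) @ A
            finite = np.isfinite(dist_all)
            vals = np.where(finite, dist_all, 0.0)
            for _ in range(n_smooth):
                vals = A @ vals
            dist_all = np.where(finite, vals, dist_all)
        lo, hi = np.nanmin(dist_all), np.nanmax(dist_all)
        scaled = (dist_all - lo) / (hi - lo) if hi > lo else np.zeros_like(dist_all)
        pt.iloc[idx] = scaled
    return pt


def abundance_regression(
    observed: Sequence[float],
    expected: Sequence[float],
) -> dict:
    """OLS of observed class fractions on expected fractions.

    Returns slope, intercept, r2, f_pvalue and the residuals — the
    quantitative check that atlas composition mirrors the anatomical
    expectation.
    """
    observed = np.asarray(observed, float)
    expected = np.asarray(expected, float)
    if len(observed) != len(expected) or len(observed) < 3:
        raise ValueError("need >= 3 paired fractions")
    if not (np.isfinite(observed).all() and np.isfinite(expected).all()):
        raise ValueError("fractions must be finite")
    if np.allclose(expected.var(), 0):
        raise ValueError("expected fractions have zero variance")
    X = sm.add_constant(expected)
    fit = sm.OLS(observed, X).fit()
    return dict(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        residuals=(observed - fit.fittedvalues).tolist(),
    )
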