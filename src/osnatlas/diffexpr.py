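"""Rank-sum marker detection and population comparisons.

One-vs-rest Wilcoxon/Mann-Whitney marker detection with the standard
single-cell filters: a gene is tested for a group only when its detection
fraction reaches ``min_pct`` in at least one side and its log2 fold change
clears ``logfc_threshold`` (positive only when ``only_pos``).  Fold
changes are computed on depth-normalized (expm1 back-transformed) means
with a pseudocount of 1/target_sum, making the filter exactly specified.
Multiple-testing correction is Bonferroni (the default) or
Benjamini-Hochberg, scoped to the genes actually tested per group for
marker detection and to all detected genes for two-population comparisons.
"""

from __future__ import annotations

import logging
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

log = logging.getLogger(__name__)

DEFAULT_LOGFC = 0.25
DEFAULT_MIN_PCT = 0.25
ALPHA = 0.05


def rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    sides: str = "two",
) -> tuple[float, float]:
    """Mann-Whitney U test with midrank ties.

    Uses the exact null distribution when n+m <= 20 and there are no ties,
    and the normal approximation with tie and continuity correction
    otherwise.  ``sides`` is one of two / greater / less (of x vs y).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sides]
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    if not no_ties and np.all(pooled == pooled[0]):
        # fully tied data: U at its null mean, no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_p(p, method: str = "bonferroni", n_tests: int | None = None) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment over ``n_tests`` tests."""
    p = np.asarray(p, float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests is None:
        n_tests = len(p)
    if n_tests < len(p):
        raise ValueError(f"n_tests={n_tests} < number of p-values ({len(p)})")
    if method == "bonferroni":
        return np.minimum(1.0, p * n_tests)
    if method == "bh":
        if p.size == 0:
            return p.copy()
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * n_tests / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise ValueError(f"unknown correction {method!r}")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def _group_stats(expr: ad.AnnData, mask: np.ndarray, pseudocount: float = 0.0):
    """(mean of expm1 values, detection fraction) within ``mask`` cells."""
    X = expr.X[mask]
    if sparse.issparse(X):
        ex = X.copy()
        ex.data = np.expm1(ex.data)
        mean = np.asarray(ex.mean(axis=0)).ravel()
        pct = np.asarray((X > 0).mean(axis=0)).ravel()
    else:
        mean = np.expm1(X).mean(axis=0)
        pct = (X > 0).mean(axis=0)
    return mean, pct


def _vector_ranksum(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Two-sided asymptotic rank-sum p per column (tie + continuity corrected)."""
    if Xa.shape[1] == 0:
        return np.empty(0)
    res = stats.mannwhitneyu(Xa, Xb, alternative="two-sided",
                             method="asymptotic", axis=0)
    p = np.atleast_1d(np.asarray(res.pvalue, float))
    # columns that are entirely tied produce nan; no evidence -> p = 1
    return np.nan_to_num(p, nan=1.0)


def find_markers(
    expr: ad.AnnData,
    groups: Sequence,
    logfc_threshold: float = DEFAULT_LOGFC,
    min_pct: float = DEFAULT_MIN_PCT,
    only_pos: bool = True,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-rest rank-sum markers per group with standard filters.

    Returns a table of (gene, group, log2FC, pct_in, pct_out, p_raw,
    p_adj, significant), sorted by (group, p_adj, -log2FC).  The
    correction is applied per group over the genes that passed the
    pre-filters for that group.
    """
    groups = np.asarray(groups)
    if len(groups) != expr.n_obs:
        raise ValueError("one group label per cell required")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("at least two groups required")
    pc = 1.0 / float(expr.uns.get("target_sum", 1e4))
    genes = np.asarray(expr.var_names)

    rows = []
    for g in uniq:
        mask = groups == g
        if mask.sum() == 1:
            log.warning("group %s has a single cell; statistics are unreliable", g)
        mean_in, pct_in = _group_stats(expr, mask, pc)
        mean_out, pct_out = _group_stats(expr, ~mask, pc)
        log2fc = np.log2((mean_in + pc) / (mean_out + pc))
        detect = np.maximum(pct_in, pct_out) >= min_pct
        fc_ok = log2fc >= logfc_threshold if only_pos else np.abs(log2fc) >= logfc_threshold
        tested = np.where(detect & fc_ok)[0]
        if len(tested) == 0:
            continue
        Xa = _dense(expr.X[mask][:, tested])
        Xb = _dense(expr.X[~mask][:, tested])
        p_raw = _vector_ranksum(Xa, Xb)
        p_adj = adjust_p(p_raw, method=correction, n_tests=len(tested))
        for j, gi in enumerate(tested):
            rows.append(
                dict(
                    gene=genes[gi], group=g, log2FC=float(log2fc[gi]),
                    pct_in=float(pct_in[gi]), pct_out=float(pct_out[gi]),
                    p_raw=float(p_raw[j]), p_adj=float(p_adj[j]),
                )
            )
    table = pd.DataFrame(
        rows, columns=["gene", "group", "log2FC", "pct_in", "pct_out", "p_raw", "p_adj"]
    )
    if len(table):
        table["significant"] = table["p_adj"] < ALPHA
        table = table.sort_values(
            ["group", "p_adj", "log2FC"], ascending=[True, True, False],
            kind="mergesort", key=lambda s: s.astype(str) if s.name == "group" else s,
        ).reset_index(drop=True)
    else:
        table["significant"] = pd.Series(dtype=bool)
    table.attrs["correction_scope"] = "genes tested per group"
    return table


def compare_populations(
    expr: ad.AnnData,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    logfc_threshold: float = DEFAULT_LOGFC,
    min_pct: float = DEFAULT_MIN_PCT,
    rgs_genes: Sequence[str] = ("rpr", "grim", "skl"),
    tf_genes: Sequence[str] = (),
    pseudobulk_groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-sided comparison of two disjoint cell populations.

    Both enrichment directions are reported; Bonferroni correction uses
    all detected genes (nonzero in at least one cell of the union) as its
    scope.  Output includes ``neglog10_p_adj`` for volcano plots and flags
    for pro-apoptotic and transcription-factor genes.  When
    ``pseudobulk_groups`` is given, cells are first aggregated to replicate
    means and the test runs on replicates instead of cells.
    """
    a = pd.Index(cells_a)
    b = pd.Index(cells_b)
    if len(a.intersection(b)):
        raise ValueError("cell sets overlap")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each population needs >= 3 cells")
    sub = expr[list(a) + list(b)]
    pc = 1.0 / float(expr.uns.get("target_sum", 1e4))
    mask_a = np.arange(sub.n_obs) < len(a)
    detected = np.asarray((sub.X > 0).sum(axis=0)).ravel() > 0
    n_detected = int(detected.sum())
    mean_a, pct_a = _group_stats(sub, mask_a, pc)
    mean_b, pct_b = _group_stats(sub, ~mask_a, pc)
    log2fc = np.log2((mean_a + pc) / (mean_b + pc))
    keep = detected & (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(log2fc) >= logfc_threshold)
    tested = np.where(keep)[0]
    if len(tested) == 0:
        cols = ["gene", "log2FC", "pct_in", "pct_out", "p_raw", "p_adj",
                "neglog10_p_adj", "significant", "is_rgs", "is_tf"]
        return pd.DataFrame(columns=cols)
    if pseudobulk_groups is not None:
        reps = pd.Series(np.asarray(pseudobulk_groups), index=sub.obs_names)
        dense = _dense(sub.X[:, tested])
        df = pd.DataFrame(dense, index=sub.obs_names)
        agg_a = df[mask_a].groupby(reps[mask_a]).mean().to_numpy()
        agg_b = df[~mask_a].groupby(reps[~mask_a]).mean().to_numpy()
        p_raw = _vector_ranksum(agg_a, agg_b)
    else:
        p_raw = _vector_ranksum(_dense(sub.X[mask_a][:, tested]),
                                _dense(sub.X[~mask_a][:, tested]))
    p_adj = adjust_p(p_raw, method="bonferroni", n_tests=n_detected)
    genes = np.asarray(sub.var_names)[tested]
    out = pd.DataFrame(
        dict(
            gene=genes,
            log2FC=log2fc[tested],
            pct_in=pct_a[tested],
            pct_out=pct_b[tested],
            p_raw=p_raw,
            p_adj=p_adj,
            neglog10_p_adj=-np.log10(np.maximum(p_adj, 1e-300)),
            significant=p_adj < ALPHA,
            is_rgs=np.isin(genes, list(rgs_genes)),
            is_tf=np.isin(genes, list(tf_genes)),
        )
    ).sort_values(["p_adj", "log2FC"], ascending=[True, False], kind="mergesort").reset_index(drop=True)
    out.attrs["correction_scope"] = f"all detected genes (n={n_detected})"
    return out


def select_tf_panel(markers: pd.DataFrame, tf_list) -> tuple[str, ...]:
    """Union of significant marker genes intersected with a TF list."""
    tf_genes = set(tf_list.genes if hasattr(tf_list, "genes") else tf_list)
    if not tf_genes:
        raise ValueError("TF list is empty")
    if not len(markers):
        return ()
    sig = markers[markers["significant"]]["gene"] if "significant" in markers else markers["gene"]
    panel = sorted(set(sig) & tf_genes)
    return tuple(panel)
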