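"""Binned-control gene-set ("module") scoring and the pro-apoptotic RGS score.

The module score of a gene set in a cell is the mean expression of the set
genes minus the mean expression of a pool of expression-matched control
genes: all genes are ranked by their dataset-mean expression, cut into
``n_bins`` equal-frequency bins, and for each set gene ``n_ctrl`` control
genes are sampled (without replacement when possible) from its bin, with
set genes excluded from their own control pool.  The RGS score is this
module score applied to the three pro-apoptotic genes rpr, grim and skl —
deliberately excluding the hid analogue, which is not a selective marker
of cells fated to die.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .diffexpr import adjust_p

log = logging.getLogger(__name__)

DEFAULT_RGS_GENES = ("rpr", "grim", "skl")
DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100


class GeneSetError(ValueError):
    pass


@dataclass
class GeneSet:
    """A named, duplicate-free collection of gene IDs."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise GeneSetError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise GeneSetError(f"gene set {self.name!r} has duplicate IDs")
        self.genes = tuple(self.genes)

    def intersect(self, var_names) -> tuple[list[str], list[str]]:
        present = [g for g in self.genes if g in set(var_names)]
        missing = [g for g in self.genes if g not in set(var_names)]
        return present, missing


@dataclass
class ScoreVector:
    """Per-cell module score with its sampling provenance."""

    values: pd.Series  # indexed by cell barcode
    gene_set: str
    n_bins: int
    n_ctrl: int
    seed: int
    missing_genes: tuple[str, ...] = field(default_factory=tuple)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def module_score(
    expr: ad.AnnData,
    gene_set: GeneSet,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> ScoreVector:
    """Binned-control module score of ``gene_set`` in every cell."""
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")
    present, missing = gene_set.intersect(expr.var_names)
    if missing:
        log.warning("gene set %s: %d genes missing from matrix: %s",
                    gene_set.name, len(missing), missing[:8])
    if not present:
        raise GeneSetError(f"gene set {gene_set.name!r} entirely absent from matrix")

    rng = np.random.default_rng(seed)
    gene_mean = np.asarray(expr.X.mean(axis=0)).ravel()
    n_genes = expr.n_vars
    # equal-frequency bins on dataset-mean expression; ties broken by index
    order = np.lexsort((np.arange(n_genes), gene_mean))
    rank = np.empty(n_genes, dtype=np.int64)
    rank[order] = np.arange(n_genes)
    bins = (rank * n_bins) // n_genes

    name_to_idx = {g: i for i, g in enumerate(expr.var_names)}
    set_idx = np.array([name_to_idx[g] for g in present])
    set_mask = np.zeros(n_genes, bool)
    set_mask[set_idx] = True

    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.where((bins == bins[gi]) & ~set_mask)[0]
        if len(pool) == 0:
            log.warning("bin %d has no control candidates; sampling all non-set genes",
                        bins[gi])
            pool = np.where(~set_mask)[0]
        replace = len(pool) < n_ctrl
        if replace:
            log.info("bin %d: %d candidates < n_ctrl=%d, sampling with replacement",
                     bins[gi], len(pool), n_ctrl)
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_all = np.concatenate(ctrl_idx)

    X = expr.X
    if sparse.issparse(X):
        X = X.tocsc()
        set_mean = np.asarray(X[:, set_idx].mean(axis=1)).ravel()
        ctrl_mean = np.asarray(X[:, ctrl_all].mean(axis=1)).ravel()
    else:
        set_mean = np.asarray(X)[:, set_idx].mean(axis=1)
        ctrl_mean = np.asarray(X)[:, ctrl_all].mean(axis=1)
    scores = set_mean - ctrl_mean
    return ScoreVector(
        values=pd.Series(scores, index=expr.obs_names, name=gene_set.name),
        gene_set=gene_set.name,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        missing_genes=tuple(missing),
    )


def rgs_score(
    expr: ad.AnnData,
    rgs_set: GeneSet | None = None,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
    hid_gene: str = "hid",
) -> ScoreVector:
    """Pro-apoptotic RGS score: module score of {rpr, grim, skl}.

    The hid analogue must not be part of the set — it is expressed at
    similar levels in dying and surviving cells and would dilute the score.
    """
    if rgs_set is None:
        rgs_set = GeneSet("RGS", DEFAULT_RGS_GENES)
    if hid_gene in rgs_set.genes:
        raise GeneSetError(f"{hid_gene!r} must not be part of the RGS set")
    sv = module_score(expr, rgs_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    return sv


def score_by_group(
    score: ScoreVector | pd.Series,
    groups: pd.Series | np.ndarray,
    correction: str = "bh",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Rank groups by median score, with pairwise rank-sum tests.

    Returns one row per group: n, median, rank (1 = highest median),
    ``min_p_adj`` (smallest corrected pairwise p against any other group)
    and ``tested`` (False when the group has fewer than ``min_cells``
    cells, in which case its tests are skipped).
    """
    values = score.values if isinstance(score, ScoreVector) else score
    groups = pd.Series(np.asarray(groups), index=values.index, name="group")
    if groups.isna().any():
        raise ValueError("every cell needs a group label")
    med = values.groupby(groups).median()
    n = values.groupby(groups).size()
    ranks = med.rank(ascending=False, method="min").astype(int)

    names = list(med.index)
    pair_p: dict[tuple[str, str], float] = {}
    testable = {g for g in names if n[g] >= min_cells}
    pairs = [(a, b) for a, b in itertools.combinations(names, 2)
             if a in testable and b in testable]
    raw = []
    for a, b in pairs:
        xa = values[groups == a].to_numpy()
        xb = values[groups == b].to_numpy()
        if np.array_equal(np.sort(xa), np.sort(xb)):
            raw.append(1.0)
        else:
            raw.append(float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue))
    adj = adjust_p(np.array(raw), method=correction, n_tests=len(raw)) if raw else np.array([])
    for (a, b), p in zip(pairs, adj):
        pair_p[(a, b)] = pair_p[(b, a)] = float(p)

    rows = []
    for g in names:
        ps = [pair_p[(g, o)] for o in names if (g, o) in pair_p]
        rows.append(
            dict(
                group=g,
                n=int(n[g]),
                median=float(med[g]),
                rank=int(ranks[g]),
                min_p_adj=(min(ps) if ps else np.nan),
                tested=g in testable and bool(ps),
            )
        )
    out = pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
    return out
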