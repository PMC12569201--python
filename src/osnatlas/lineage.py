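"""Iterative retrograde annotation of developing neuron lineages.

Neuron classes are recognizable late in development by their diagnostic
tuning receptor, but receptor expression starts too late to label younger
cells.  The algorithm here therefore works backwards: receptor-expressing
clusters seed the lineage labels (iteration 0); each subsequent iteration
extracts marker genes for every labeled lineage, module-scores the still
unlabeled clusters against every lineage's markers, and assigns each
cluster to its top-scoring lineage when the winning margin is clear.
Near-ties are resolved in favor of the lineage whose already-labeled cells
are closest on the neighbor graph — preferring short, continuous
differentiation trajectories over jumps across the manifold.  When
class-level iterations stall, co-housed classes are pooled by sensillum,
sensillar markers extracted, and remaining clusters assigned at the
sensillum level before a final class-level pass.  Labels are frozen once
assigned within a run; every assignment records its iteration, score,
margin and tie-break provenance for audit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

from .diffexpr import find_markers
from .genescore import DEFAULT_N_BINS, DEFAULT_N_CTRL, GeneSet, module_score

log = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


@dataclass
class SensillumModel:
    """Which neuron classes are co-housed, and their identities."""

    sensilla: dict[str, list[str]]  # sensillum -> ordered class list
    categories: dict[str, str] = field(default_factory=dict)  # sensillum -> ab/at/...
    receptors: dict[str, list[str]] = field(default_factory=dict)  # class -> genes
    precursor_types: dict[str, str] = field(default_factory=dict)  # class -> Naa/...

    def __post_init__(self):
        seen: set[str] = set()
        for s, cl in self.sensilla.items():
            if not 1 <= len(cl) <= 4:
                raise ValueError(f"sensillum {s} must house 1-4 classes")
            dup = seen & set(cl)
            if dup:
                raise ValueError(f"classes in multiple sensilla: {sorted(dup)}")
            seen |= set(cl)

    @property
    def classes(self) -> list[str]:
        return [c for cl in self.sensilla.values() for c in cl]

    def sensillum_of(self, cls: str) -> str:
        for s, cl in self.sensilla.items():
            if cls in cl:
                return s
        raise KeyError(cls)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            dict(sensilla=self.sensilla, categories=self.categories,
                 receptors=self.receptors, precursor_types=self.precursor_types),
            indent=1, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "SensillumModel":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(
            sensilla=d["sensilla"],
            categories=d.get("categories", {}),
            receptors=d.get("receptors", {}),
            precursor_types=d.get("precursor_types", {}),
        )


@dataclass
class LineageAnnotation:
    """Per-cell lineage labels plus the per-cluster audit trail."""

    cells: pd.DataFrame  # index barcode: lineage, sensillum, iteration
    clusters: pd.DataFrame  # index cluster: lineage, iteration, score, margin, tiebreak

    def annotated_fraction(self) -> float:
        return float((self.cells["lineage"] != UNANNOTATED).mean())


def _cluster_mean(values: pd.Series, clusters: np.ndarray) -> pd.Series:
    return values.groupby(pd.Series(clusters, index=values.index)).mean()


def annotate_cell_types(
    expr: ad.AnnData,
    clusters: np.ndarray,
    marker_library: dict[str, GeneSet],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    margin_floor: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Label each cluster with its best-scoring broad cell type.

    Each cluster receives the cell type whose marker-set module score has
    the highest cluster mean; the margin to the runner-up is reported and
    clusters below ``margin_floor`` are flagged ambiguous.
    """
    if len(marker_library) < 2:
        raise ValueError("marker library needs at least two cell types")
    clusters = np.asarray(clusters)
    scores = {}
    for i, (name, gs) in enumerate(sorted(marker_library.items())):
        sv = module_score(expr, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + i)
        scores[name] = _cluster_mean(sv.values, clusters)
    table = pd.DataFrame(scores)
    top = table.idxmax(axis=1)
    best = table.max(axis=1)
    runner = table.apply(lambda r: r.drop(top[r.name]).max(), axis=1)
    out = pd.DataFrame(
        dict(cell_type=top, score=best, runner_up=runner, margin=best - runner)
    )
    out["ambiguous"] = out["margin"] < margin_floor
    out.index.name = "cluster"
    return out


def seed_lineages(
    expr: ad.AnnData,
    clusters: np.ndarray,
    model: SensillumModel,
    min_frac_expressing: float = 0.2,
    subcluster: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, dict[int, str], pd.DataFrame]:
    """Iteration-0 lineage seeding from diagnostic receptor expression.

    A cluster is seeded with class L when every receptor gene of L is
    detected in at least ``min_frac_expressing`` of its cells and no other
    class passes the same bar.  Clusters passing for two or more classes
    are re-clustered once at higher resolution and their children re-tested.
    Returns the (possibly refined) cluster labels, the cluster -> class
    seeding, and an audit table of receptor detection fractions.
    """
    from .corematrix import cluster_graph, embed_and_graph

    clusters = np.asarray(clusters).copy()
    name_to_idx = {g: i for i, g in enumerate(expr.var_names)}

    def detect_frac(cell_mask: np.ndarray) -> dict[str, float]:
        sub = expr.X[cell_mask]
        fracs = {}
        for cls, genes in model.receptors.items():
            if not genes:
                fracs[cls] = 0.0
                continue
            idx = [name_to_idx[g] for g in genes if g in name_to_idx]
            if not idx:
                fracs[cls] = 0.0
                continue
            per_gene = np.asarray((sub[:, idx] > 0).mean(axis=0)).ravel()
            fracs[cls] = float(per_gene.min())
        return fracs

    seeding: dict[int, str] = {}
    audit_rows = []
    next_id = int(clusters.max()) + 1 if len(clusters) else 0
    pending = list(np.unique(clusters))
    refined_from: dict[int, int] = {}
    while pending:
        cl = pending.pop(0)
        mask = clusters == cl
        if mask.sum() == 0:
            continue
        fracs = detect_frac(mask)
        passing = [c for c, f in fracs.items() if f >= min_frac_expressing]
        audit_rows.append(dict(cluster=cl, n=int(mask.sum()),
                               passing=",".join(passing),
                               top_frac=max(fracs.values()) if fracs else 0.0))
        if len(passing) == 1:
            seeding[cl] = passing[0]
        elif len(passing) >= 2 and subcluster and cl not in refined_from and mask.sum() >= 6:
            # mixed receptor cluster: subcluster once at higher resolution
            sub = expr[mask]
            g = embed_and_graph(sub, n_hvg=min(500, sub.n_vars),
                                n_pcs=min(10, sub.n_obs - 1), k=min(10, sub.n_obs - 1),
                                seed=seed)
            kids = cluster_graph(g, resolution=2.0, seed=seed)
            if kids.max() > 0:
                new_ids = kids + next_id
                clusters[mask] = new_ids
                for nid in np.unique(new_ids):
                    refined_from[int(nid)] = int(cl)
                    pending.append(int(nid))
                next_id = int(new_ids.max()) + 1
            else:
                log.info("cluster %s stayed mixed after subclustering", cl)
    if not seeding:
        raise ValueError(
            "no cluster was seeded by receptor expression; "
            "consider lowering min_frac_expressing"
        )
    audit = pd.DataFrame(audit_rows).set_index("cluster")
    return clusters, seeding, audit


def _median_graph_distance(
    adjacency: sparse.spmatrix,
    sources: np.ndarray,
    target_sets: dict[str, np.ndarray],
    max_sources: int = 20,
) -> dict[str, float]:
    """Median unweighted geodesic from ``sources`` to each target cell set."""
    if len(sources) > max_sources:
        sources = sources[np.linspace(0, len(sources) - 1, max_sources).astype(int)]
    dist = csgraph.dijkstra(adjacency, directed=False, indices=sources,
                            unweighted=True)
    out = {}
    for name, targets in target_sets.items():
        d = dist[:, targets].ravel()
        d = d[np.isfinite(d)]
        out[name] = float(np.median(d)) if len(d) else math.inf
    return out


def retrograde_iterate(
    expr: ad.AnnData,
    clusters: np.ndarray,
    seeding: dict[int, str],
    model: SensillumModel,
    graph=None,
    logfc_threshold: float = 0.25,
    min_pct: float = 0.25,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    margin_floor: float = 0.05,
    score_floor: float = 0.0,
    max_markers: int = 50,
    max_iters: int = 10,
    seed: int = 0,
) -> LineageAnnotation:
    """Propagate lineage labels backward through development.

    See the module docstring for the algorithm.  ``graph`` (a
    :class:`~osnatlas.corematrix.NeighborGraph` or sparse adjacency) is
    used only for near-tie resolution; with ``margin_floor`` set to
    infinity no propagation happens at all, which is useful for auditing
    the seeding in isolation.
    """
    if not seeding:
        raise ValueError("iteration-0 seeding is empty")
    clusters = np.asarray(clusters)
    adjacency = getattr(graph, "adjacency", graph)
    cluster_ids = list(np.unique(clusters))
    assigned: dict[int, str] = dict(seeding)
    audit: dict[int, dict] = {
        cl: dict(lineage=c, iteration=0, score=np.nan, margin=np.nan, tiebreak="receptor")
        for cl, c in seeding.items()
    }

    def class_labels() -> np.ndarray:
        lab = np.full(expr.n_obs, UNANNOTATED, dtype=object)
        for cl, c in assigned.items():
            lab[clusters == cl] = c
        return lab

    def marker_sets(labels: np.ndarray, level: str) -> dict[str, list[str]]:
        present = [g for g in pd.unique(labels) if g != UNANNOTATED]
        if len(pd.unique(labels)) < 2:
            return {}
        table = find_markers(expr, labels, logfc_threshold=logfc_threshold,
                             min_pct=min_pct, only_pos=True, correction="bonferroni")
        sets = {}
        for g in present:
            sig = table[(table["group"] == g) & table["significant"]]
            genes = list(sig["gene"].head(max_markers))
            if genes:
                sets[g] = genes
            else:
                log.info("%s %s yielded no markers this iteration", level, g)
        return sets

    def score_clusters(sets: dict[str, list[str]], it: int) -> pd.DataFrame:
        cols = {}
        for i, (name, genes) in enumerate(sorted(sets.items())):
            sv = module_score(expr, GeneSet(name, tuple(genes)),
                              n_bins=n_bins, n_ctrl=n_ctrl,
                              seed=seed + 1000 * it + i)
            cols[name] = _cluster_mean(sv.values, clusters)
        return pd.DataFrame(cols)

    def try_assign(cl: int, row: pd.Series, it: int, allowed: list[str] | None,
                   label_of: dict[str, str] | None = None) -> tuple[str, str] | None:
        r = row if allowed is None else row[row.index.intersection(allowed)]
        if r.empty:
            return None
        r = r.sort_values(ascending=False, kind="mergesort")
        top, best = r.index[0], float(r.iloc[0])
        if best <= score_floor:
            return None
        margin = best - float(r.iloc[1]) if len(r) > 1 else math.inf
        if margin >= margin_floor:
            return top, "margin"
        if not math.isfinite(margin_floor) or adjacency is None:
            # an infinite near-tie window is not a tie; and without a graph
            # we cannot arbitrate - leave unassigned (logged)
            if adjacency is None:
                log.warning("cluster %s: near-tie but no graph; left unassigned", cl)
            return None
        cands = list(r.index[r >= best - margin_floor])
        targets = {}
        lab = class_labels()
        for cand in cands:
            members = (label_of or {}).get(cand, cand)
            tgt = np.where(np.isin(lab, members if isinstance(members, list) else [members]))[0]
            if len(tgt):
                targets[cand] = tgt
        if not targets:
            return None
        src = np.where(clusters == cl)[0]
        dists = _median_graph_distance(adjacency, src, targets)
        winner = min(sorted(dists), key=lambda c: (dists[c], c))
        if not math.isfinite(dists[winner]):
            return None
        return winner, "graph_distance"

    it = 0
    stalled = False
    while it < max_iters and not stalled:
        it += 1
        labels = class_labels()
        sets = marker_sets(labels, "class")
        if not sets:
            break
        scores = score_clusters(sets, it)
        new = 0
        for cl in cluster_ids:
            if cl in assigned or cl not in scores.index:
                continue
            res = try_assign(cl, scores.loc[cl], it, allowed=None)
            if res:
                cls, how = res
                assigned[cl] = cls
                audit[cl] = dict(lineage=cls, iteration=it,
                                 score=float(scores.loc[cl, cls]),
                                 margin=float(scores.loc[cl].max() - scores.loc[cl].drop(cls).max())
                                 if len(scores.columns) > 1 else math.inf,
                                 tiebreak=how)
                new += 1
        log.info("iteration %d: %d new cluster assignments", it, new)
        stalled = new == 0

    remaining = [cl for cl in cluster_ids if cl not in assigned]
    if remaining and math.isfinite(margin_floor):
        # sensillum-level fallback for the stragglers
        labels = class_labels()
        sens_of = {c: model.sensillum_of(c) for c in model.classes}
        sens_labels = np.array(
            [sens_of.get(l, UNANNOTATED) for l in labels], dtype=object
        )
        sens_sets = marker_sets(sens_labels, "sensillum")
        if sens_sets:
            it += 1
            cols = {}
            for i, (name, genes) in enumerate(sorted(sens_sets.items())):
                sv = module_score(expr, GeneSet(name, tuple(genes)),
                                  n_bins=n_bins, n_ctrl=n_ctrl,
                                  seed=seed + 5_000_000 + i)
                cols[name] = _cluster_mean(sv.values, clusters)
            sens_scores = pd.DataFrame(cols)
            class_sets = marker_sets(labels, "class")
            class_scores = score_clusters(class_sets, it + 1) if class_sets else pd.DataFrame()
            label_of_sens = {s: cl for s, cl in model.sensilla.items()}
            for cl in remaining:
                if cl not in sens_scores.index:
                    continue
                res = try_assign(cl, sens_scores.loc[cl], it,
                                 allowed=None, label_of=label_of_sens)
                if res is None:
                    continue
                sname, how = res
                house = model.sensilla[sname]
                if len(house) == 1:
                    cls = house[0]
                elif len(class_scores) and cl in class_scores.index:
                    sub = class_scores.loc[cl, class_scores.columns.intersection(house)]
                    if sub.empty:
                        continue
                    cls = sub.idxmax()
                else:
                    continue
                assigned[cl] = cls
                audit[cl] = dict(lineage=cls, iteration=it,
                                 score=float(sens_scores.loc[cl, sname]),
                                 margin=np.nan, tiebreak=f"sensillum:{how}")

    labels = class_labels()
    sens_of = {c: model.sensillum_of(c) for c in model.classes}
    cells = pd.DataFrame(
        dict(
            lineage=labels,
            sensillum=[sens_of.get(l, UNANNOTATED) for l in labels],
            cluster=clusters,
            iteration=[audit.get(cl, {}).get("iteration", -1) for cl in clusters],
        ),
        index=expr.obs_names,
    )
    cl_table = pd.DataFrame.from_dict(audit, orient="index").reindex(cluster_ids)
    cl_table["lineage"] = cl_table["lineage"].fillna(UNANNOTATED)
    cl_table.index.name = "cluster"
    return LineageAnnotation(cells=cells, clusters=cl_table)


def assign_precursor_types(
    expr: ad.AnnData,
    class_labels: pd.Series,
    known_map: dict[str, str],
    min_pct: float = 0.4,
    logfc_threshold: float = 0.25,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    max_iters: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Iteratively map neuron classes to precursor types (Naa/Nab/Nba/Nbb).

    ``known_map`` seeds at least one class per usable type; each round
    extracts precursor-type markers from the currently mapped classes
    (detection filter 0.4, the stricter threshold appropriate for
    lineage-wide programs), module-scores the unmapped classes and assigns
    the argmax, until a fixpoint.  Classes whose scores are tied remain
    unmapped and are flagged - some classes genuinely cannot be assigned.
    """
    class_labels = pd.Series(class_labels)
    classes = [c for c in pd.unique(class_labels) if c != UNANNOTATED]
    mapping = dict(known_map)
    types_seeded = sorted(set(mapping.values()))
    if not types_seeded:
        raise ValueError("known_map must seed at least one class per usable type")
    status: dict[str, dict] = {
        c: dict(precursor=mapping.get(c), iteration=0 if c in mapping else -1,
                score=np.nan, margin=np.nan, flagged=False)
        for c in classes
    }
    for it in range(1, max_iters + 1):
        unmapped = [c for c in classes if mapping.get(c) is None]
        if not unmapped:
            break
        type_of_cell = class_labels.map(lambda c: mapping.get(c) or UNANNOTATED)
        if len(pd.unique(type_of_cell)) < 2:
            break
        table = find_markers(expr, type_of_cell.to_numpy(),
                             logfc_threshold=logfc_threshold, min_pct=min_pct,
                             only_pos=True, correction="bonferroni")
        sets = {}
        for t in sorted(set(mapping[c] for c in mapping if mapping.get(c))):
            sig = table[(table["group"] == t) & table["significant"]]
            if len(sig):
                sets[t] = list(sig["gene"].head(50))
        if not sets:
            break
        scores = {}
        for i, (t, genes) in enumerate(sorted(sets.items())):
            sv = module_score(expr, GeneSet(t, tuple(genes)), n_bins=n_bins,
                              n_ctrl=n_ctrl, seed=seed + 100 * it + i)
            scores[t] = sv.values.groupby(class_labels).mean()
        sm = pd.DataFrame(scores)
        changed = False
        for c in unmapped:
            if c not in sm.index:
                continue
            row = sm.loc[c].sort_values(ascending=False, kind="mergesort")
            if len(row) > 1 and np.isclose(row.iloc[0], row.iloc[1]):
                status[c].update(flagged=True)
                continue
            mapping[c] = row.index[0]
            status[c].update(precursor=row.index[0], iteration=it,
                             score=float(row.iloc[0]),
                             margin=float(row.iloc[0] - row.iloc[1]) if len(row) > 1 else math.inf,
                             flagged=False)
            changed = True
        if not changed:
            break
    out = pd.DataFrame.from_dict(status, orient="index")
    out.index.name = "class"
    out["precursor"] = out["precursor"].fillna(UNANNOTATED)
    return out.sort_index()
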