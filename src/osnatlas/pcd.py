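"""Detection of death-fated ("undead") neuron populations.

Three lines of evidence identify populations that are normally removed by
programmed cell death but survive when PCD is blocked:

* ``exclusive_cluster`` — a joint cluster composed (almost) entirely of
  PCD-blocked cells, confirmed by an elevated pro-apoptotic RGS score.
* ``abundance_reequilibration`` — a class that is depleted relative to its
  co-housed classes in the control condition, with the deficit shrinking
  by at least half when PCD is blocked.
* ``rgs_rank`` — the class ranking highest for RGS score within its
  sensillum, significantly above every co-housed class.

Abundances are computed on mid-and-later cells (the developmental window
in which death has already acted), with blocked-exclusive clusters removed
from the denominator so that undead populations do not distort the shared
composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genescore import ScoreVector, score_by_group
from .lineage import UNANNOTATED, SensillumModel

log = logging.getLogger(__name__)

PHASE_ORDER = {"early": 0, "mid": 1, "late": 2}


@dataclass
class UndeadCall:
    target: str  # lineage name or "cluster:<id>"
    evidence: str  # exclusive_cluster | abundance_reequilibration | rgs_rank
    statistics: dict

    def as_row(self) -> dict:
        return dict(target=self.target, evidence=self.evidence, **self.statistics)


def detect_exclusive_clusters(
    clusters: np.ndarray,
    conditions: np.ndarray,
    rgs: ScoreVector | pd.Series | None = None,
    min_frac_blocked: float = 0.9,
    min_size: int = 20,
    blocked_label: str = "pcd_blocked",
) -> pd.DataFrame:
    """Flag joint clusters composed almost entirely of PCD-blocked cells.

    A cluster is flagged when its blocked-cell fraction reaches
    ``min_frac_blocked`` and it has at least ``min_size`` cells; a binomial
    test against the global blocked fraction is reported.  When an RGS
    score is supplied, flagged clusters are promoted to undead calls only
    if their median RGS exceeds the across-cluster median of medians.
    """
    clusters = np.asarray(clusters)
    conditions = np.asarray(conditions)
    if blocked_label not in conditions:
        raise ValueError(f"no {blocked_label!r} cells in condition labels")
    if len(np.unique(conditions)) < 2:
        raise ValueError("both conditions are required")
    global_frac = float((conditions == blocked_label).mean())
    rgs_values = rgs.values if isinstance(rgs, ScoreVector) else rgs

    rows = []
    med_by_cluster = {}
    for cl in np.unique(clusters):
        mask = clusters == cl
        n = int(mask.sum())
        n_blocked = int((conditions[mask] == blocked_label).sum())
        frac = n_blocked / n
        p = float(stats.binomtest(n_blocked, n, global_frac, alternative="greater").pvalue)
        med = float(np.median(np.asarray(rgs_values)[mask])) if rgs_values is not None else np.nan
        med_by_cluster[cl] = med
        rows.append(dict(cluster=cl, n=n, frac_blocked=frac, binom_p=p, rgs_median=med))
    table = pd.DataFrame(rows).set_index("cluster")
    table["exclusive"] = (table["frac_blocked"] >= min_frac_blocked) & (table["n"] >= min_size)
    if rgs_values is not None:
        overall = float(np.median(list(med_by_cluster.values())))
        table["rgs_elevated"] = table["rgs_median"] > overall
        table["undead_call"] = table["exclusive"] & table["rgs_elevated"]
    else:
        table["rgs_elevated"] = np.nan
        table["undead_call"] = table["exclusive"]
    return table


def differential_abundance(
    cells: pd.DataFrame,
    exclusive_clusters: set | None = None,
    phase_floor: str = "mid",
    model: SensillumModel | None = None,
    deficit_threshold: float = 0.25,
    shrink_factor: float = 0.5,
    alpha: float = 0.05,
    min_cells: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-lineage abundance in both conditions with partial-death flags.

    ``cells`` needs columns condition, phase, lineage and (when exclusive
    clusters are to be excluded) cluster.  Proportions are computed per
    condition over annotated cells at ``phase_floor`` or later, excluding
    blocked-exclusive clusters.  Within each multi-class sensillum each
    class is compared to the most abundant co-housed class: a class is
    flagged ``partial_death`` when its control deficit (1 - ratio to the
    co-housed maximum) exceeds ``deficit_threshold``, is statistically
    supported (two-proportion test), and shrinks by at least
    ``shrink_factor`` in the blocked condition.  Classes with fewer than
    ``min_cells`` control cells are not candidates: re-equilibration is
    evidence about classes present in both conditions, while fully dying
    classes are captured by the exclusive-cluster route.
    """
    rng = np.random.default_rng(seed)
    df = cells.copy()
    floor = PHASE_ORDER[phase_floor]
    df = df[df["phase"].map(PHASE_ORDER).fillna(-1) >= floor]
    df = df[df["lineage"] != UNANNOTATED]
    if exclusive_clusters:
        df = df[~df["cluster"].isin(set(exclusive_clusters))]
    counts = df.groupby(["condition", "lineage"]).size().unstack(fill_value=0)
    if counts.shape[0] < 2:
        raise ValueError("annotation must cover both conditions")
    props = counts.div(counts.sum(axis=1), axis=0)

    lineages = list(counts.columns)
    out = pd.DataFrame(
        dict(
            n_control=counts.reindex(["control"]).fillna(0).iloc[0].astype(int),
            n_blocked=counts.reindex(["pcd_blocked"]).fillna(0).iloc[0].astype(int),
            prop_control=props.reindex(["control"]).fillna(0).iloc[0],
            prop_blocked=props.reindex(["pcd_blocked"]).fillna(0).iloc[0],
        ),
        index=lineages,
    )
    out["ratio_blocked_control"] = out["prop_blocked"] / out["prop_control"].replace(0, np.nan)
    out["sensillum"] = [
        model.sensillum_of(l) if (model and l in model.classes) else ""
        for l in lineages
    ]
    out["deficit_control"] = np.nan
    out["deficit_blocked"] = np.nan
    out["deficit_ci_low"] = np.nan
    out["deficit_ci_high"] = np.nan
    out["two_prop_p"] = np.nan
    out["partial_death"] = False

    if model is None:
        out.index.name = "lineage"
        return out

    tot = counts.sum(axis=1)
    for sname, house in model.sensilla.items():
        present = [c for c in house if c in out.index]
        if len(present) < 2:
            continue  # single-class sensilla carry no within-sensillum signal
        for cond, col in (("control", "deficit_control"), ("pcd_blocked", "deficit_blocked")):
            if cond not in counts.index:
                continue
            sub = counts.loc[cond, present]
            ref = sub.max()
            for c in present:
                out.loc[c, col] = 1.0 - (sub[c] / ref if ref > 0 else np.nan)
        for c in present:
            if out.loc[c, "n_control"] < min_cells:
                continue
            others = [o for o in present if o != c]
            ref_cls = counts.loc["control", others].idxmax()
            n_c, n_r = counts.loc["control", c], counts.loc["control", ref_cls]
            if n_c + n_r == 0 or n_c >= n_r:
                continue
            # under equal representation the class holds half the pooled cells
            p = float(stats.binomtest(int(n_c), int(n_c + n_r), 0.5,
                                      alternative="less").pvalue)
            out.loc[c, "two_prop_p"] = p
            d_ctrl = 1.0 - n_c / n_r
            nb_c = counts.loc["pcd_blocked", c] if "pcd_blocked" in counts.index else 0
            nb_r = counts.loc["pcd_blocked", ref_cls] if "pcd_blocked" in counts.index else 0
            d_blk = 1.0 - nb_c / nb_r if nb_r > 0 else np.nan
            # bootstrap CI on the control deficit (cell-level resampling)
            boots = rng.binomial(int(n_c + n_r), n_c / (n_c + n_r), size=n_boot)
            ratios = boots / np.maximum(n_c + n_r - boots, 1)
            ci = np.quantile(1.0 - ratios, [0.025, 0.975])
            out.loc[c, ["deficit_ci_low", "deficit_ci_high"]] = ci
            flagged = (
                d_ctrl > deficit_threshold
                and p < alpha
                and np.isfinite(d_blk)
                and d_blk <= (1.0 - shrink_factor) * d_ctrl
            )
            out.loc[c, "partial_death"] = bool(flagged)
    out.index.name = "lineage"
    return out


def rank_rgs_by_sensillum(
    rgs: ScoreVector | pd.Series,
    annotation: pd.DataFrame,
    model: SensillumModel,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Rank classes by median RGS within each sensillum; flag the top class.

    The top-ranked class is flagged when its median RGS enrichment is
    positive and its pairwise rank-sum test against every co-housed class
    is significant after correction — the signature of a lineage with
    embedded death-fated cells.  The positive-median gate matters: with
    hundreds of cells per class, small systematic differences between
    classes reach significance even when neither shows any pro-apoptotic
    enrichment.
    """
    values = rgs.values if isinstance(rgs, ScoreVector) else rgs
    lineages = annotation["lineage"] if "lineage" in annotation else annotation.iloc[:, 0]
    rows = []
    for sname, house in model.sensilla.items():
        mask = lineages.isin(house)
        if not mask.any():
            continue
        sub_scores = values[mask.to_numpy()]
        sub_groups = lineages[mask].to_numpy()
        ranked = score_by_group(pd.Series(np.asarray(sub_scores),
                                          index=lineages.index[mask]),
                                sub_groups, correction=correction)
        present = list(ranked["group"])
        top = ranked.iloc[0]
        for _, r in ranked.iterrows():
            flag = False
            if r["rank"] == 1 and len(present) > 1 and r["tested"] and r["median"] > 0:
                # significant against every co-housed class, not just one
                g = r["group"]
                xg = np.asarray(sub_scores)[sub_groups == g]
                ps = []
                for o in present:
                    if o == g:
                        continue
                    xo = np.asarray(sub_scores)[sub_groups == o]
                    if min(len(xg), len(xo)) < 3:
                        ps.append(1.0)
                        continue
                    ps.append(float(stats.mannwhitneyu(xg, xo, alternative="greater").pvalue))
                from .diffexpr import adjust_p

                adj = adjust_p(np.array(ps), method=correction, n_tests=len(ps))
                flag = bool(len(adj) and adj.max() < alpha)
            rows.append(dict(sensillum=sname, lineage=r["group"], n=r["n"],
                             rgs_median=r["median"], rank=r["rank"],
                             min_p_adj=r["min_p_adj"], top_flagged=flag))
    out = pd.DataFrame(rows)
    return out.sort_values(["sensillum", "rank"]).reset_index(drop=True) if len(out) else out


def infer_sensillum_subtypes(
    abundance: pd.DataFrame,
    model: SensillumModel,
) -> pd.DataFrame:
    """Infer the fraction of sensilla lacking each partial-death class.

    For a sensillum housing a depleted class, the fraction of sensilla
    missing that class is estimated as 1 - (class proportion / co-housed
    maximum proportion) per condition; ratios above 1 are clipped (logged).
    The blocked-condition fraction shrinking toward zero is the expected
    signature of re-equilibration.
    """
    rows = []
    for sname, house in model.sensilla.items():
        present = [c for c in house if c in abundance.index]
        if len(present) < 2:
            continue
        if not abundance.loc[present, "partial_death"].any():
            continue
        for cond, col in (("control", "prop_control"), ("pcd_blocked", "prop_blocked")):
            props = abundance.loc[present, col]
            ref = props.max()
            for c in present:
                frac = 1.0 - (props[c] / ref if ref > 0 else np.nan)
                if frac < 0:
                    log.info("clipping negative lacking-fraction for %s/%s", sname, c)
                    frac = 0.0
                lo = abundance.loc[c, "deficit_ci_low"] if cond == "control" else np.nan
                hi = abundance.loc[c, "deficit_ci_high"] if cond == "control" else np.nan
                rows.append(dict(sensillum=sname, lineage=c, condition=cond,
                                 frac_lacking=float(np.clip(frac, 0.0, 1.0)),
                                 ci_low=lo, ci_high=hi,
                                 partial_death=bool(abundance.loc[c, "partial_death"])))
    return pd.DataFrame(rows)


def call_undead(
    exclusive: pd.DataFrame,
    abundance: pd.DataFrame,
    rgs_ranks: pd.DataFrame | None = None,
    cluster_lineages: dict | None = None,
) -> pd.DataFrame:
    """Aggregate the three evidence streams into a single call table."""
    calls: list[UndeadCall] = []
    for cl, row in exclusive[exclusive["undead_call"]].iterrows():
        target = (cluster_lineages or {}).get(cl, f"cluster:{cl}")
        calls.append(UndeadCall(str(target), "exclusive_cluster",
                                dict(cluster=cl, frac_blocked=row["frac_blocked"],
                                     binom_p=row["binom_p"], rgs_median=row["rgs_median"])))
    for lin, row in abundance[abundance["partial_death"]].iterrows():
        calls.append(UndeadCall(str(lin), "abundance_reequilibration",
                                dict(deficit_control=row["deficit_control"],
                                     deficit_blocked=row["deficit_blocked"],
                                     two_prop_p=row["two_prop_p"])))
    if rgs_ranks is not None and len(rgs_ranks):
        for _, row in rgs_ranks[rgs_ranks["top_flagged"]].iterrows():
            calls.append(UndeadCall(str(row["lineage"]), "rgs_rank",
                                    dict(sensillum=row["sensillum"],
                                         rgs_median=row["rgs_median"])))
    if not calls:
        return pd.DataFrame(columns=["target", "evidence"])
    return pd.DataFrame([c.as_row() for c in calls])
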