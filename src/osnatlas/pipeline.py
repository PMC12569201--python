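"""End-to-end pipeline: simulate -> cluster -> annotate -> detect -> report.

``run_pipeline`` executes the full analysis on either a simulated
paired-condition atlas (the default) or a pair of on-disk 10x MTX
directories, and emits a machine-readable results dictionary (written as
JSON when an output directory is given).  Every stage is seeded, so a
rerun with the same configuration produces a byte-identical results file.
When ground truth is available (simulated input) the report additionally
contains accuracy metrics against the planted labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import corematrix, downstream, pcd, tenx
from .diffexpr import find_markers, select_tf_panel
from .genescore import GeneSet, rgs_score
from .lineage import UNANNOTATED, SensillumModel, retrograde_iterate, seed_lineages
from .simdata import PHASE_POOLS, SimulationConfig, simulate_atlas

log = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run."""

    sim: SimulationConfig | None = None
    control_dir: str | None = None
    blocked_dir: str | None = None
    model: SensillumModel | None = None  # required for on-disk input
    target_sum: float = 1e4
    n_hvg: int = 2000
    n_pcs: int = 50
    k: int = 15
    resolution: float = 6.0
    min_frac_expressing: float = 0.2
    margin_floor: float = 0.05
    max_iters: int = 10
    n_bins: int = 24
    n_ctrl: int = 100
    min_frac_blocked: float = 0.9
    min_cluster_size: int = 20
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "PipelineConfig":
        return cls(sim=SimulationConfig(seed=seed), seed=seed)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full analysis and return the results dictionary."""
    cfg = config
    results: dict = {"schema_version": RESULTS_SCHEMA_VERSION,
                     "seed": cfg.seed, "stages": {}}

    # ---- input ----------------------------------------------------------
    truth = None
    if cfg.sim is not None:
        ctrl, blocked, cells, truth = simulate_atlas(cfg.sim)
        model = truth.sensillum_model()
    else:
        if not (cfg.control_dir and cfg.blocked_dir):
            raise StageError("input", "either sim config or both input dirs required")
        if cfg.model is None:
            raise StageError("annotate", "a sensillum model is required for on-disk input")
        ctrl = tenx.read_tenx(cfg.control_dir)
        blocked = tenx.read_tenx(cfg.blocked_dir)
        ctrl.obs["condition"] = "control"
        blocked.obs["condition"] = "pcd_blocked"
        if "pool" not in ctrl.obs:
            ctrl.obs["pool"] = "36h"
            blocked.obs["pool"] = "36h"
        if "phase" not in ctrl.obs:
            ctrl.obs["phase"] = "mid"
            blocked.obs["phase"] = "mid"
        model = cfg.model
    results["stages"]["input"] = dict(
        n_control=int(ctrl.n_obs), n_blocked=int(blocked.n_obs), n_genes=int(ctrl.n_vars)
    )

    # ---- normalize + integrate ------------------------------------------
    joint_counts = corematrix.integrate_conditions(ctrl, blocked, mode="concat")
    expr = corematrix.normalize(joint_counts, target_sum=cfg.target_sum)

    # ---- embed, graph, cluster ------------------------------------------
    graph = corematrix.embed_and_graph(expr, n_hvg=cfg.n_hvg, n_pcs=cfg.n_pcs,
                                       k=cfg.k, seed=cfg.seed)
    clusters = corematrix.cluster_graph(graph, resolution=cfg.resolution, seed=cfg.seed)
    results["stages"]["cluster"] = dict(n_clusters=int(clusters.max() + 1),
                                        resolution=cfg.resolution)

    # ---- phases ---------------------------------------------------------
    pools = {p: ph for ph, ps in PHASE_POOLS.items() for p in ps}
    cell_table = corematrix.assign_phases(expr.obs, pools, clusters)

    # refine cluster units by phase: a cluster spanning the whole
    # differentiation continuum would otherwise dilute late receptor
    # expression and hide condition-exclusive branches inside mixed units
    refined = pd.factorize(
        pd.Series(clusters).astype(str) + ":" + cell_table["phase"].to_numpy()
    )[0]
    clusters = np.asarray(refined)
    results["stages"]["cluster"]["n_units_phase_refined"] = int(clusters.max() + 1)

    # ---- lineage annotation ---------------------------------------------
    clusters2, seeding, seed_audit = seed_lineages(
        expr, clusters, model, min_frac_expressing=cfg.min_frac_expressing, seed=cfg.seed
    )
    annotation = retrograde_iterate(
        expr, clusters2, seeding, model, graph=graph,
        margin_floor=cfg.margin_floor, n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl,
        max_iters=cfg.max_iters, seed=cfg.seed,
    )
    ann = annotation.cells.join(cell_table[["condition", "phase"]])
    results["stages"]["annotate"] = dict(
        n_seeded=len(seeding),
        annotated_fraction=_round(annotation.annotated_fraction()),
        iterations=int(annotation.clusters["iteration"].max()),
    )

    # ---- RGS scoring ----------------------------------------------------
    rgs = rgs_score(expr, n_bins=cfg.n_bins, n_ctrl=cfg.n_ctrl, seed=cfg.seed)

    # ---- undead detection -----------------------------------------------
    exclusive = pcd.detect_exclusive_clusters(
        clusters2, ann["condition"].to_numpy(), rgs=rgs,
        min_frac_blocked=cfg.min_frac_blocked, min_size=cfg.min_cluster_size,
    )
    excl_set = set(exclusive.index[exclusive["undead_call"]])
    abundance = pcd.differential_abundance(
        ann.assign(cluster=clusters2), exclusive_clusters=excl_set,
        model=model, seed=cfg.seed,
    )
    rgs_ranks = pcd.rank_rgs_by_sensillum(rgs, annotation.cells, model)
    subtypes = pcd.infer_sensillum_subtypes(abundance, model)
    cluster_lineages = annotation.clusters["lineage"].to_dict()
    calls = pcd.call_undead(exclusive, abundance, rgs_ranks, cluster_lineages)
    results["stages"]["detect"] = dict(
        n_exclusive=int(exclusive["undead_call"].sum()),
        exclusive_lineages=sorted(
            {str(cluster_lineages.get(c, f"cluster:{c}")) for c in excl_set}
        ),
        partial_death=sorted(map(str, abundance.index[abundance["partial_death"]])),
        partial_death_deficits={
            str(lin): dict(
                control=_round(float(abundance.loc[lin, "deficit_control"])),
                blocked=_round(float(abundance.loc[lin, "deficit_blocked"])),
            )
            for lin in abundance.index[abundance["partial_death"]]
        },
        rgs_top_flagged=sorted(map(str, rgs_ranks[rgs_ranks["top_flagged"]]["lineage"]))
        if len(rgs_ranks) else [],
    )

    # ---- downstream -----------------------------------------------------
    ann_cells = ann[ann["lineage"] != UNANNOTATED]
    tf_list = None
    if truth is not None:
        tf_list = sorted({g for gl in truth.tfs.values() for g in gl})
    newick = None
    if tf_list and ann_cells["lineage"].nunique() >= 3:
        markers = find_markers(expr[ann_cells.index], ann_cells["lineage"].to_numpy())
        panel = select_tf_panel(markers, tf_list)
        if len(panel) >= 2:
            newick = downstream.class_tree(expr, annotation.cells["lineage"], panel)
            results["stages"]["tree"] = dict(n_tf=len(panel), newick=newick)

    pt = downstream.pseudotime(expr, ann.assign(phase=ann["phase"]), seed=cfg.seed)

    # abundance regression: observed control fractions vs planted expectation
    regression = None
    if truth is not None:
        obs_cells = ann[(ann["condition"] == "control")
                        & (ann["phase"].isin(["mid", "late"]))
                        & (ann["lineage"] != UNANNOTATED)]
        observed = obs_cells["lineage"].value_counts(normalize=True)
        tcells = truth.cells
        texp = tcells[(tcells["condition"] == "control")
                      & (tcells["phase"].isin(["mid", "late"]))]
        expected = texp["true_class"].value_counts(normalize=True)
        common = sorted(set(observed.index) & set(expected.index))
        if len(common) >= 3:
            try:
                regression = downstream.abundance_regression(
                    observed[common].to_numpy(), expected[common].to_numpy()
                )
            except ValueError as exc:  # e.g. perfectly uniform composition
                log.info("abundance regression skipped: %s", exc)
            else:
                results["stages"]["regression"] = {
                    k: _round(v) if not isinstance(v, list) else [_round(x) for x in v]
                    for k, v in regression.items()
                }

    # ---- truth-based evaluation -----------------------------------------
    if truth is not None:
        tc = truth.cells.loc[ann.index]
        midlate = tc["phase"].isin(["mid", "late"])
        correct = (ann["lineage"] == tc["true_class"]) & midlate
        acc = float(correct[midlate].mean())
        unann = ann["lineage"] == UNANNOTATED
        early_share = float(tc.loc[unann, "phase"].eq("early").mean()) if unann.any() else np.nan

        truth_full = {c for c, f in truth.death_fates.items() if f == "full"}
        truth_partial = {c for c, f in truth.death_fates.items() if f.startswith("partial")}
        called_full = {str(cluster_lineages.get(c, f"cluster:{c}")) for c in excl_set}
        called_partial = set(map(str, abundance.index[abundance["partial_death"]]))
        tp = len(called_full & truth_full) + len(called_partial & truth_partial)
        fp = len(called_full - truth_full) + len(called_partial - truth_partial)
        fn = len(truth_full - called_full) + len(truth_partial - called_partial)
        recall = tp / (tp + fn) if tp + fn else np.nan
        precision = tp / (tp + fp) if tp + fp else np.nan

        spearman = []
        for lin, grp in ann_cells.groupby("lineage"):
            t = truth.cells.loc[grp.index, "latent_time"]
            p = pt[grp.index]
            ok = p.notna() & t.notna()
            if ok.sum() >= 10:
                from scipy.stats import spearmanr

                rho = spearmanr(t[ok], p[ok]).statistic
                spearman.append(float(rho))
        results["evaluation"] = dict(
            annotation_accuracy_mid_late=_round(acc),
            unannotated_fraction=_round(float(unann.mean())),
            unannotated_early_share=_round(early_share),
            undead_recall=_round(recall),
            undead_precision=_round(precision),
            pseudotime_spearman_mean=_round(float(np.mean(spearman))) if spearman else None,
            n_lineages_pseudotime=len(spearman),
        )

    # ---- write ----------------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = json.dumps(results, indent=1, sort_keys=True)
        (outdir / "results.json").write_text(payload)
        ann.assign(pseudotime=pt).to_csv(outdir / "annotation.tsv", sep="\t")
        calls.to_csv(outdir / "undead_calls.tsv", sep="\t", index=False)
        abundance.to_csv(outdir / "abundance.tsv", sep="\t")
        if len(subtypes):
            subtypes.to_csv(outdir / "sensillum_subtypes.tsv", sep="\t", index=False)
    return results
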