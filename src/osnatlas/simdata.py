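"""Synthetic paired-condition antennal atlas generator.

Emulates the data model of a developing olfactory-sensory-neuron (OSN)
snRNA-seq experiment performed in two genotypes: a control and a
"PCD-blocked" condition in which programmed cell death is suppressed
(e.g. by a caspase inhibitor).  Cells belong to neuron classes housed in
sensilla (stereotyped combinations of 1-4 co-developing classes), progress
through an early/mid/late pupal continuum, switch on class-specific marker
and transcription-factor (TF) programs along a latent developmental time,
and express a diagnostic sensory receptor only late in development.

Death fates are planted per class:

* ``none``      — the class survives in both conditions.
* ``full``      — all cells die at the end of the early phase; the control
                  condition contains only early cells, the blocked condition
                  the full continuum ("undead" neurons).
* ``partial:r`` — a fraction ``r`` of cells die from the mid phase onward;
                  the control condition is depleted, the blocked one is not.

Death-fated cells upregulate a trio of pro-apoptotic genes (the rpr/grim/skl
analogues) by ``logfc_marker`` log2 units, while a fourth "hid-like" gene is
expressed equally everywhere — mirroring the selective transcriptional
signature of cells fated to die.

Counts are negative binomial (gamma-Poisson) with gene-level baselines,
log-normal cell size factors, a uniform ambient-contamination fraction and
mean-dependent zero-inflation (dropout concentrated on lowly expressed
entries).  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

PHASES = ("early", "mid", "late")

#: collection-time pools (hours after puparium formation) per phase,
#: mirroring the early (18-30 h), mid (36-48 h) and late (56-80 h) pooling.
PHASE_POOLS = {
    "early": ("18h", "24h", "30h"),
    "mid": ("36h", "42h", "48h"),
    "late": ("56h", "64h", "80h"),
}

#: sensillum morphological categories cycled over when naming sensilla.
SENSILLUM_CATEGORIES = ("ab", "at", "ai", "ac", "sac")

PRECURSOR_TYPES = ("Naa", "Nab", "Nba", "Nbb")


class ConfigurationError(ValueError):
    """Raised when a :class:`SimulationConfig` violates its invariants."""


def _parse_fate(fate: str) -> tuple[str, float]:
    """Parse a death-fate string into ``(kind, rate)``."""
    if fate == "none":
        return "none", 0.0
    if fate == "full":
        return "full", 1.0
    if fate.startswith("partial:"):
        rate = float(fate.split(":", 1)[1])
        if not 0.0 < rate < 1.0:
            raise ConfigurationError(
                f"partial death rate must lie in (0, 1), got {rate}"
            )
        return "partial", rate
    raise ConfigurationError(f"unknown death fate {fate!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic paired-condition atlas.

    Defaults describe the standard desk-scale study: two conditions of
    roughly 4,000 cells each, 2,000 genes, 14 neuron classes housed in
    6 sensilla of 1-4 classes, with three full-death classes and one
    partial-death class (rate 0.4).
    """

    n_genes: int = 2000
    n_sensilla: int = 6
    classes_per_sensillum: Sequence[int] = (4, 3, 3, 2, 1, 1)
    #: class name -> "none" | "full" | "partial:<rate>"; None selects the
    #: default planting (full death in the first three multi-class sensilla,
    #: partial(0.4) in the fourth).
    death_fates: Mapping[str, str] | None = None
    cells_per_class_per_phase: int = 100
    phases: Sequence[str] = PHASES
    marker_genes_per_class: int = 40
    tf_genes_per_class: int = 4
    tf_genes_per_sensillum: int = 4
    tf_genes_per_category: int = 4
    precursor_genes_per_type: int = 8
    #: shared developmental program: genes ramping up (and down) with
    #: latent time in every neuron class, with onset midpoints staggered
    #: across development — the waves of maturation gene expression that
    #: make the pupal continuum transcriptionally ordered.
    time_genes_per_direction: int = 60
    receptor_onset_phase: str = "late"
    n_categories: int | None = None
    baseline_mean: float = 0.5
    special_base_mean: float = 0.5
    receptor_off_mean: float = 0.01
    receptor_on_mean: float = 1.0
    hid_mean: float = 0.5
    dispersion: float = 10.0
    logfc_marker: float = 2.0
    #: logistic ramp of program activation in latent time t in [0, 1]:
    #: a(t) = 1 / (1 + exp(-ramp_steepness * (t - ramp_midpoint))).
    ramp_steepness: float = 8.0
    ramp_midpoint: float = 0.35
    size_factor_sigma: float = 0.3
    dropout_rate: float = 0.2
    ambient_fraction: float = 0.02
    #: if > 0, a tandem trio of genes is co-expressed across two classes,
    #: emulating a readthrough-transcription confound (off by default).
    readthrough_trio: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_sensilla <= 0 or len(self.classes_per_sensillum) != self.n_sensilla:
            raise ConfigurationError(
                "classes_per_sensillum must list one entry per sensillum"
            )
        if any(not 1 <= k <= 4 for k in self.classes_per_sensillum):
            raise ConfigurationError("each sensillum houses 1-4 classes")
        if sum(self.classes_per_sensillum) == 0:
            raise ConfigurationError("at least one class is required")
        if self.receptor_onset_phase not in self.phases:
            raise ConfigurationError("receptor_onset_phase must be a phase label")
        if not 0 <= self.dropout_rate < 1 or not 0 <= self.ambient_fraction < 1:
            raise ConfigurationError("rates must lie in [0, 1)")

    # -- derived layout ---------------------------------------------------

    def sensillum_names(self) -> list[str]:
        cats = self.category_labels()
        counts: dict[str, int] = {}
        names = []
        for cat in cats:
            counts[cat] = counts.get(cat, 0) + 1
            names.append(f"{cat}{counts[cat]}")
        return names

    def category_labels(self) -> list[str]:
        if self.n_categories is not None:
            pool = [f"cat{i + 1}" for i in range(self.n_categories)]
        else:
            pool = list(SENSILLUM_CATEGORIES)
        return [pool[i % len(pool)] for i in range(self.n_sensilla)]

    def class_names(self) -> list[str]:
        names = []
        for sname, k in zip(self.sensillum_names(), self.classes_per_sensillum):
            for j in range(k):
                names.append(f"{sname}{chr(ord('A') + j)}")
        return names

    def resolved_death_fates(self) -> dict[str, str]:
        classes = self.class_names()
        if self.death_fates is not None:
            unknown = set(self.death_fates) - set(classes)
            if unknown:
                raise ConfigurationError(f"death fates for unknown classes: {unknown}")
            fates = {c: self.death_fates.get(c, "none") for c in classes}
            for f in fates.values():
                _parse_fate(f)
            return fates
        # default planting: last class of the first three multi-class
        # sensilla dies fully; last class of the fourth dies partially.
        fates = {c: "none" for c in classes}
        multi = [
            s
            for s, k in zip(self.sensillum_names(), self.classes_per_sensillum)
            if k >= 2
        ]
        sens_of = {}
        for sname, k in zip(self.sensillum_names(), self.classes_per_sensillum):
            for j in range(k):
                sens_of[f"{sname}{chr(ord('A') + j)}"] = sname
        by_sens: dict[str, list[str]] = {}
        for c in classes:
            by_sens.setdefault(sens_of[c], []).append(c)
        for i, s in enumerate(multi[:4]):
            victim = by_sens[s][-1]
            fates[victim] = "full" if i < 3 else "partial:0.4"
        return fates


@dataclass
class TruthBundle:
    """Planted ground truth accompanying a simulated atlas."""

    cells: pd.DataFrame  # index barcode: condition, pool, phase, latent_time,
    #                      true_class, sensillum, precursor, death_fated
    markers: dict[str, list[str]]
    tfs: dict[str, list[str]]
    receptors: dict[str, list[str]]
    precursor_genes: dict[str, list[str]]
    rgs_genes: list[str]
    hid_gene: str
    class_to_sensillum: dict[str, str]
    class_to_precursor: dict[str, str]
    sensillum_category: dict[str, str]
    death_fates: dict[str, str]
    class_tree_newick: str

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["cells"] = None  # cell table is written separately as TSV
        return json.dumps(payload, indent=1, sort_keys=True)

    def sensillum_model(self):
        """Build the matching :class:`~osnatlas.lineage.SensillumModel`."""
        from .lineage import SensillumModel

        sensilla: dict[str, list[str]] = {}
        for c, s in self.class_to_sensillum.items():
            sensilla.setdefault(s, []).append(c)
        for s in sensilla:
            sensilla[s] = sorted(sensilla[s])
        return SensillumModel(
            sensilla=sensilla,
            categories=dict(self.sensillum_category),
            receptors={c: list(g) for c, g in self.receptors.items()},
            precursor_types=dict(self.class_to_precursor),
        )


def _activation(t: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-cfg.ramp_steepness * (t - cfg.ramp_midpoint)))


def _build_truth_tree(cfg: SimulationConfig) -> str:
    """Newick tree over classes: category -> sensillum -> class."""
    sens = cfg.sensillum_names()
    cats = cfg.category_labels()
    classes_by_sens = {}
    for sname, k in zip(sens, cfg.classes_per_sensillum):
        classes_by_sens[sname] = [f"{sname}{chr(ord('A') + j)}" for j in range(k)]
    by_cat: dict[str, list[str]] = {}
    for sname, cat in zip(sens, cats):
        by_cat.setdefault(cat, []).append(sname)

    def sens_clade(sname: str) -> str:
        kids = classes_by_sens[sname]
        return kids[0] if len(kids) == 1 else "(" + ",".join(kids) + ")"

    cat_clades = []
    for cat in sorted(by_cat):
        clades = [sens_clade(s) for s in by_cat[cat]]
        cat_clades.append(clades[0] if len(clades) == 1 else "(" + ",".join(clades) + ")")
    if len(cat_clades) == 1:
        return cat_clades[0] + ";"
    return "(" + ",".join(cat_clades) + ");"


def simulate_atlas(
    config: SimulationConfig,
) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame, TruthBundle]:
    """Simulate a paired control / PCD-blocked atlas with planted truth.

    Returns ``(control, pcd_blocked, cells, truth)`` where the two AnnData
    objects carry raw integer counts (cells x genes, sparse CSR), ``cells``
    is the concatenated per-cell metadata table and ``truth`` bundles every
    planted label and gene program.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    classes = cfg.class_names()
    sens_names = cfg.sensillum_names()
    cats = dict(zip(sens_names, cfg.category_labels()))
    class_sens = {}
    for sname, k in zip(sens_names, cfg.classes_per_sensillum):
        for j in range(k):
            class_sens[f"{sname}{chr(ord('A') + j)}"] = sname
    class_prec = {}
    for sname, k in zip(sens_names, cfg.classes_per_sensillum):
        for j in range(k):
            class_prec[f"{sname}{chr(ord('A') + j)}"] = PRECURSOR_TYPES[j % 4]
    fates = cfg.resolved_death_fates()

    # ---- gene layout -----------------------------------------------------
    genes: list[str] = []
    markers: dict[str, list[str]] = {}
    tfs: dict[str, list[str]] = {c: [] for c in classes}
    receptors: dict[str, list[str]] = {}
    prec_genes: dict[str, list[str]] = {}

    for c in classes:
        markers[c] = [f"mk_{c}_{i}" for i in range(cfg.marker_genes_per_class)]
        genes += markers[c]
    for c in classes:
        own = [f"tf_{c}_{i}" for i in range(cfg.tf_genes_per_class)]
        tfs[c] += own
        genes += own
    sens_tfs = {s: [f"tf_{s}_s{i}" for i in range(cfg.tf_genes_per_sensillum)] for s in sens_names}
    for s, gl in sens_tfs.items():
        genes += gl
    cat_names = sorted(set(cats.values()))
    cat_tfs = {k: [f"tf_{k}_c{i}" for i in range(cfg.tf_genes_per_category)] for k in cat_names}
    for k in cat_names:
        genes += cat_tfs[k]
    for c in classes:
        tfs[c] = tfs[c] + sens_tfs[class_sens[c]] + cat_tfs[cats[class_sens[c]]]
    for i, c in enumerate(classes):
        receptors[c] = [f"Or{i + 1}"]
        genes += receptors[c]
    for p in PRECURSOR_TYPES:
        prec_genes[p] = [f"prg_{p}_{i}" for i in range(cfg.precursor_genes_per_type)]
        genes += prec_genes[p]
    time_up = [f"dev_up_{i:03d}" for i in range(cfg.time_genes_per_direction)]
    time_dn = [f"dev_dn_{i:03d}" for i in range(cfg.time_genes_per_direction)]
    genes += time_up + time_dn
    rgs = ["rpr", "grim", "skl"]
    hid = "hid"
    genes += rgs + [hid]
    if len(genes) > cfg.n_genes:
        raise ConfigurationError(
            f"n_genes={cfg.n_genes} too small for the planted programs "
            f"({len(genes)} structured genes required)"
        )
    n_bg = cfg.n_genes - len(genes)
    genes += [f"bg_{i:04d}" for i in range(n_bg)]
    gene_index = {g: i for i, g in enumerate(genes)}
    G = len(genes)

    # gene baselines: background genes log-normal around baseline_mean,
    # structured genes at their off-state means.
    base = rng.lognormal(np.log(cfg.baseline_mean) - 0.5, 1.0, size=G)
    for gl in list(markers.values()):
        for g in gl:
            base[gene_index[g]] = cfg.special_base_mean
    for c in classes:
        for g in tfs[c]:
            base[gene_index[g]] = cfg.special_base_mean
    for gl in prec_genes.values():
        for g in gl:
            base[gene_index[g]] = cfg.special_base_mean
    for gl in receptors.values():
        for g in gl:
            base[gene_index[g]] = cfg.receptor_off_mean
    for g in time_up + time_dn:
        base[gene_index[g]] = cfg.special_base_mean
    for g in rgs:
        base[gene_index[g]] = cfg.special_base_mean
    base[gene_index[hid]] = cfg.hid_mean
    # staggered onset midpoints spread over development
    n_t = cfg.time_genes_per_direction
    time_mid = np.linspace(0.1, 0.9, n_t) if n_t else np.array([])

    # ---- cell roster -----------------------------------------------------
    phase_band = {p: (i / 3.0, (i + 1) / 3.0) for i, p in enumerate(cfg.phases)}
    onset_t = phase_band[cfg.receptor_onset_phase][0]

    rows: list[dict] = []
    n0 = cfg.cells_per_class_per_phase
    for cond in ("control", "pcd_blocked"):
        for c in classes:
            kind, rate = _parse_fate(fates[c])
            for pi, phase in enumerate(cfg.phases):
                if cond == "control" and kind == "full" and pi > 0:
                    continue  # died at end of early phase
                fated_draw = rng.random(n0)
                if kind == "full":
                    fated = np.ones(n0, bool)
                elif kind == "partial" and pi > 0:
                    fated = fated_draw < rate
                else:
                    fated = np.zeros(n0, bool)
                keep = ~fated if (cond == "control" and kind == "partial" and pi > 0) else np.ones(n0, bool)
                t = rng.uniform(*phase_band[phase], size=n0)
                pool = rng.choice(PHASE_POOLS[phase], size=n0)
                for i in range(n0):
                    if not keep[i]:
                        continue
                    rows.append(
                        dict(
                            condition=cond,
                            pool=pool[i],
                            phase=phase,
                            latent_time=t[i],
                            true_class=c,
                            sensillum=class_sens[c],
                            precursor=class_prec[c],
                            death_fated=bool(fated[i]),
                        )
                    )
    cells = pd.DataFrame(rows)
    # deterministic shuffle so class blocks are not contiguous
    perm = rng.permutation(len(cells))
    cells = cells.iloc[perm].reset_index(drop=True)
    cells.index = [
        f"{('CTL' if cond == 'control' else 'BLK')}-{i:05d}"
        for i, cond in enumerate(cells["condition"])
    ]
    cells.index.name = "barcode"

    # ---- mean matrix and sampling ---------------------------------------
    def _sample(cond: str) -> tuple[ad.AnnData, pd.DataFrame]:
        sub = cells[cells["condition"] == cond]
        n = len(sub)
        mean = np.tile(base[None, :], (n, 1))
        a = _activation(sub["latent_time"].to_numpy(), cfg)
        mult = 2.0 ** (cfg.logfc_marker * a)
        for c in classes:
            mask = (sub["true_class"] == c).to_numpy()
            if not mask.any():
                continue
            idx = [gene_index[g] for g in markers[c] + tfs[c]]
            mean[np.ix_(mask, idx)] *= mult[mask, None]
            ridx = [gene_index[g] for g in receptors[c]]
            late = mask & (sub["latent_time"].to_numpy() >= onset_t)
            if late.any():
                # diagnostic on-state: receptors switch from near-silent to
                # robustly expressed at onset
                mean[np.ix_(late, ridx)] *= cfg.receptor_on_mean / cfg.receptor_off_mean
        for p in PRECURSOR_TYPES:
            mask = (sub["precursor"] == p).to_numpy()
            idx = [gene_index[g] for g in prec_genes[p]]
            mean[np.ix_(mask, idx)] *= 2.0 ** cfg.logfc_marker
        if n_t:
            t_all = sub["latent_time"].to_numpy()
            ramps = 1.0 / (1.0 + np.exp(-cfg.ramp_steepness * (t_all[:, None] - time_mid[None, :])))
            up_idx = [gene_index[g] for g in time_up]
            dn_idx = [gene_index[g] for g in time_dn]
            mean[:, up_idx] *= 2.0 ** (cfg.logfc_marker * ramps)
            mean[:, dn_idx] *= 2.0 ** (cfg.logfc_marker * (1.0 - ramps))
        fated = sub["death_fated"].to_numpy()
        if fated.any():
            idx = [gene_index[g] for g in rgs]
            mean[np.ix_(fated, idx)] *= 2.0 ** cfg.logfc_marker
        if cfg.readthrough_trio and len(classes) >= 2:
            trio = [gene_index[f"bg_{i:04d}"] for i in range(min(3, n_bg))]
            both = sub["true_class"].isin(classes[:2]).to_numpy()
            mean[np.ix_(both, trio)] *= 2.0 ** cfg.logfc_marker

        size = rng.lognormal(0.0, cfg.size_factor_sigma, size=n)
        mean *= size[:, None]
        if cfg.ambient_fraction > 0:
            ambient = mean.mean(axis=0)
            mean = (1 - cfg.ambient_fraction) * mean + cfg.ambient_fraction * ambient[None, :]
        lam = rng.gamma(cfg.dispersion, mean / cfg.dispersion)
        counts = rng.poisson(lam)
        if cfg.dropout_rate > 0:
            # zero-inflation concentrated on lowly expressed entries:
            # P(drop) = dropout_rate * exp(-mu), the usual droplet pattern
            p_drop = cfg.dropout_rate * np.exp(-mean)
            counts = counts * (rng.random(counts.shape) >= p_drop)
        X = sparse.csr_matrix(counts.astype(np.int64))
        adata = ad.AnnData(
            X=X,
            obs=sub[["condition", "pool", "phase"]].copy(),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
        return adata, sub

    ctrl, _ = _sample("control")
    blocked, _ = _sample("pcd_blocked")

    truth = TruthBundle(
        cells=cells,
        markers=markers,
        tfs=tfs,
        receptors=receptors,
        precursor_genes=prec_genes,
        rgs_genes=rgs,
        hid_gene=hid,
        class_to_sensillum=class_sens,
        class_to_precursor=class_prec,
        sensillum_category={s: cats[s] for s in sens_names},
        death_fates=fates,
        class_tree_newick=_build_truth_tree(cfg),
    )
    cell_table = cells[["condition", "pool", "phase"]].copy()
    return ctrl, blocked, cell_table, truth
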