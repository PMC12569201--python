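# Methods

This note documents the models, algorithms and numerical choices behind
`osnatlas`, and what the synthetic benchmark does and does not establish.

## Data model and scaffold

Matrices live in AnnData (cells × genes); on disk, 10x-convention MTX
triplets (genes × cells) with `features.tsv`/`barcodes.tsv`. Normalization
is depth-scaled log1p: `value = log1p(count * target_sum / libsize)` with
`target_sum = 10,000`; cells with zero library size are dropped with a
warning. Every rank-based statistic downstream is invariant to this
monotone choice, which is why a fully specifiable transform is used rather
than a regularized-NB residual model. Embedding is PCA (default 50
components, full SVD, deterministic sign convention: the largest-|loading|
coordinate of each component is positive) on the top-variance genes,
followed by a union-symmetrized kNN graph (k = 15, Euclidean PC
distances) and Leiden clustering (RB-configuration modularity, seeded;
default resolutions 0.5 coarse / 6.0 fine). Cross-condition integration
defaults to plain concatenation — the synthetic conditions share no batch
effect — with an optional mutual-nearest-neighbor shift correction for
real batch structure; blocked cells without mutual anchors borrow the mean
correction of anchored neighbors, and fully anchor-free neighborhoods
(condition-exclusive populations) are deliberately left uncorrected so
that undead clusters stay separable.

Collection-time pools map to early/mid/late phases. When a cluster's
PCD-blocked cells are decisively one phase (≥ 75% majority), that phase is
extrapolated to all cells of the cluster in both conditions — recovering
pools that mixed stages. Mixed-phase clusters are left untouched: a
one-sided reassignment there would fabricate condition-exclusive phase
units, which we observed directly before adding the dominance gate.

In the pipeline, cluster units are further refined by phase
(cluster × phase). A Leiden community can span a lineage's whole
differentiation continuum; as a single unit it would dilute late receptor
expression below the seeding bar and hide PCD-blocked-exclusive branches
(the control contributes early cells, the blocked condition the whole
trajectory). Splitting units by phase is the pipeline analogue of
reconstructing each sensillum separately before looking for exclusive
clusters.

## Module score and RGS score

For a gene set S: all genes are ranked by dataset-mean expression (ties by
gene index) and cut into `n_bins` (default 24) equal-frequency bins; for
each set gene, `n_ctrl` (default 100) control genes are sampled without
replacement from its bin, set genes excluded from their own control pool
(with-replacement sampling, logged, when a bin is smaller than `n_ctrl`).
The score is mean(set genes) − mean(pooled control genes), per cell,
deterministic under the seed. The RGS score is this module score on
{rpr, grim, skl}; the hid analogue is excluded because it is expressed
equally in dying and surviving cells and would dilute the signal. The
score is computed on log-normalized values; the binning-and-sampling
defaults are the established convention for this style of scorer — the
method statement fixes the algorithm, not these constants.

## Marker detection

One-vs-rest Mann–Whitney tests with midrank ties: exact null when
n + m ≤ 20 without ties, normal approximation with tie and continuity
correction otherwise. A gene is tested only if max(pct_in, pct_out) ≥
`min_pct` (0.25; 0.4 for precursor-type programs) and log₂FC ≥ 0.25
(both directions for two-population comparisons), with
log₂FC = log₂((mean_in + pc)/(mean_out + pc)) on expm1-back-transformed
values and pc = 1/target_sum. Correction is Bonferroni by default —
scoped to genes tested per group for marker detection, and to all
detected genes for two-population (volcano) comparisons; both scopes are
recorded in the table metadata. Two-population comparisons run at cell
level by default; a replicate-aggregated ("pseudobulk") mode is available
via `pseudobulk_groups` because the aggregation unit for such comparisons
is genuinely ambiguous in practice — neither mode is claimed canonical.

## Retrograde annotation

Seeding: a fine cluster is labelled with class L iff every receptor gene
of L is detected in ≥ `min_frac_expressing` of its cells and no other
class passes; clusters passing for ≥ 2 classes are re-clustered once at
higher resolution and the children re-tested. The default bar is 0.2:
off-state receptor detection is ~1–2% while the on-state is ~50%, and a
unit mixing pre-onset cells dilutes the on-fraction roughly twofold, so
the bar must sit an order of magnitude above background and below ~0.25.

Iteration: markers per labelled lineage → module scores of every cluster →
assign each unlabelled cluster its top-scoring lineage when the margin to
the runner-up is ≥ `margin_floor` (0.05 score units) and the top score is
positive. Near-ties (margin < floor) are resolved by the median
unweighted graph geodesic from the cluster's cells to each candidate
lineage's labelled cells — the operational form of preferring short,
continuous differentiation trajectories; the tie-break is recorded per
cluster, and is disabled entirely when `margin_floor` is infinite (an
infinite near-tie window is not a tie), which reduces the run to the
seeding alone for auditing. Labels freeze once assigned within a run;
stability across seeds is assessed by re-running. After class-level
iterations stall, sensillar markers (co-housed classes pooled) assign the
remaining clusters at sensillum level before a final class-level pass.
Iteration counts, scores, margins and tie-break provenance are kept per
cluster so a human can review what the automated argmax did — the
score-conflict rule is an explicit stand-in for manual inspection of top
markers.

Precursor-type assignment works the same way at class level: seeded
classes per type (Naa/Nab/Nba/Nbb), marker extraction at min_pct 0.4,
iterative argmax to fixpoint; classes with tied scores stay unmapped and
are flagged rather than forced.

## Undead detection

- **Exclusive clusters**: blocked-cell fraction ≥ 0.9 (not 1.0, to
  tolerate annotation bleed-through) and size ≥ 20; a binomial test
  against the global blocked fraction is reported; promotion to an undead
  call additionally requires the cluster's median RGS above the
  across-cluster median.
- **Differential abundance**: proportions per condition over annotated
  cells at mid phase or later, exclusive clusters removed from the
  denominator (so adding an undead cluster never moves surviving-lineage
  proportions). Within each multi-class sensillum, each class is compared
  to its most abundant co-housed class; a class is flagged partial-death
  when its control deficit (1 − ratio to the co-housed maximum) exceeds
  0.25, is supported by a binomial two-proportion test, and shrinks by at
  least half in the blocked condition. Full restoration is not required
  because the blocked atlas may itself lack some undead cells. Classes
  with < 20 control cells among included cells are not candidates:
  re-equilibration is evidence about classes present in both conditions,
  while fully dying classes are captured by the exclusive-cluster route.
  Confidence intervals come from a seeded 1,000-resample cell-level
  bootstrap (the design has no biological replicates).
- **RGS ranking**: classes ranked by median RGS within each sensillum;
  the top class is flagged when its median enrichment is positive and its
  one-sided rank-sum test against every co-housed class survives
  correction. The positive-median gate is essential: with hundreds of
  cells per class, sub-0.05-unit systematic differences between two
  surviving classes reach significance, and rank alone would false-flag.
- **Subtype inference**: for sensilla with a partial-death class, the
  fraction of sensilla lacking that class is 1 − (class proportion /
  co-housed maximum), clipped to [0, 1], reported per condition with the
  bootstrap CI.

All numeric thresholds above (0.9, 20, 0.25, one-half) are declared
defaults exposed in configuration; no published criterion fixes them.

## Downstream

- **Class tree**: per-class mean expression restricted to the
  differentially expressed TF panel; Euclidean distances; agglomerative
  average linkage (the feature space is specified by the method, the
  linkage is not — average is the conventional choice); Newick output
  with branch lengths and deterministic (alphabetical) leaf processing.
- **Pseudotime**: each lineage is extracted and re-embedded on its own
  (top-300-variance genes, 10 PCs, k = 15) — global embeddings fragment
  per-lineage subgraphs and mix lineages. The root is the PC-space medoid
  of the lineage's early cells; pseudotime is the Dijkstra distance along
  the distance-weighted graph, denoised by five rounds of neighbor
  averaging (a cheap analogue of projecting cells onto a principal
  curve), min-max scaled to [0, 1] per lineage, with per-component roots
  when a subgraph is disconnected. This geodesic construction replaces a
  principal-graph method deliberately: pseudotime is used descriptively
  (ordering receptor onset), and a fully specifiable geodesic suffices.
- **Abundance regression**: ordinary least squares of observed on
  expected class fractions, with R², the F-test p-value and residuals.

## The synthetic study

The generator emulates: NB (gamma–Poisson) counts with log-normal cell
size factors (σ = 0.3) and gene-level baselines; per-cell latent time
uniform within its phase third; class marker/TF programs activating along
a logistic ramp (steepness 8, midpoint 0.35); staggered waves of shared
developmental genes (60 up + 60 down, onset midpoints spread over
[0.1, 0.9]) — the global maturation programs that make the pupal
continuum transcriptionally ordered; receptors near-silent (mean 0.01)
before the late phase and robustly expressed (mean 1.0) after onset;
precursor-type programs shared across classes of a type; sensillum- and
category-level TF sharing that plants a class hierarchy; RGS trio
upregulated 2^logfc (default logfc 2) only in death-fated cells with a
hid-like gene flat everywhere; mean-dependent zero-inflation
(P(drop) = 0.2·e^(−μ), the droplet pattern in which dropouts concentrate
on lowly expressed entries); and a uniform 2% ambient fraction. Death
fates: full-death classes are present in the control condition only as
early cells (death acts at the early/mid transition); partial(r) classes
lose a Binomial(n, r) subset of mid/late control cells, and the
corresponding blocked cells carry the death-fated flag. Defaults: 2,000
genes, 14 classes in 6 sensilla (4/3/3/2/1/1), 100 cells per class per
phase, 40 markers + 12 TFs per class, three full-death classes and one
partial(0.4) — roughly 4,000 cells per condition, sized for desk-scale
runs of a few minutes.

What the generator does **not** emulate: doublets, between-condition batch
effects, structured ambient contamination, cell-cycle or stress programs,
unequal per-lineage cell sampling, and receptor co-expression beyond one
optional readthrough-like tandem trio (off by default). Passing the
benchmark therefore demonstrates that the algorithms recover the
structure they target under realistic count noise — not that they are
robust to every artefact of real droplet data.

Within-test problem sizes are scaled-down variants of the same generator
(2–4 sensilla, 25–50 cells per class per phase, 600–700 genes) so the
full suite and the acceptance script each finish in minutes on one CPU.

## Determinism

Every stochastic step (simulation, PCA solver, Leiden, control-gene
sampling, bootstraps) takes an explicit seed threaded from the
configuration; results JSON files are written with sorted keys and
reproduce byte for byte under identical configuration.

## Known limitations

- The annotation transfers labels at cluster granularity; cells of a
  minority class inside an impure cluster inherit the majority label.
- The exclusive-cluster route depends on the clustering separating the
  undead branch from shared early segments; the phase-refined units make
  this reliable in the benchmark but very short-lived populations could
  still merge with shared units.
- The RGS positive-median gate assumes the score is centred near zero for
  unaffected cells, which holds for binned-control scoring but would not
  for un-centred signature scores.
- Pseudotime fidelity is bounded by per-cell noise around the expression
  trajectory; rank correlation with latent time saturates once program
  activation saturates, which is why the shared staggered-wave genes
  matter for ordering late cells.
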