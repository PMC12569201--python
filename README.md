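# osnatlas

Tools for annotating developing olfactory sensory neuron (OSN) lineages in
single-nucleus RNA-seq atlases and for detecting neuron populations that are
normally eliminated by programmed cell death (PCD).

## The problem

During *Drosophila* pupal development, each antennal sensillum houses a
stereotyped combination of 1–4 sensory neurons descended from a single
precursor; specific precursors are removed by PCD. Profiling a **control**
atlas alongside a **PCD-blocked** atlas (caspase inhibition) makes the
death-fated, "undead" neurons observable — but only if the atlas can be
annotated far earlier in development than the diagnostic receptor genes are
expressed, and only if the two conditions can be compared quantitatively.

`osnatlas` implements that computational core for anyone analysing paired
condition snRNA-seq atlases of developing neural lineages:

- **Retrograde lineage annotation.** Receptor-positive late clusters seed
  class labels (iteration 0). Each iteration then extracts rank-sum marker
  genes for every labelled lineage (log₂FC ≥ 0.25, detection ≥ 0.25,
  Bonferroni-adjusted p < 0.05), module-scores the unlabelled clusters
  against each lineage's markers, and assigns clusters whose winning margin
  is clear; near-ties go to the lineage whose labelled cells are closest on
  the neighbor graph (shortest, continuous differentiation trajectories).
  When class-level iterations stall, co-housed classes are pooled per
  sensillum for a sensillar-marker pass.
- **Binned-control module scoring.** score(c) = mean expression of set genes
  − mean of expression-matched control genes drawn from equal-frequency bins
  of dataset-mean expression. The **RGS score** applies this to the
  pro-apoptotic trio *rpr*, *grim*, *skl* (deliberately excluding *hid*,
  which does not mark death-fated cells) as a per-cell death-fate likelihood.
- **Undead-neuron detection** by three evidence streams: clusters exclusive
  to the PCD-blocked condition (confirmed by elevated RGS), within-sensillum
  differential abundance whose control deficit re-equilibrates when PCD is
  blocked, and sensillar RGS ranking.
- **Downstream analyses**: hierarchical class trees in differentially
  expressed TF space (Newick output), per-lineage graph-geodesic pseudotime,
  and observed-vs-expected abundance regression.
- **A synthetic-data generator** producing paired control/PCD-blocked count
  matrices with planted lineage structure, phase continua, late receptor
  onset, staggered developmental gene waves, full/partial death fates with
  RGS upregulation, and full ground truth — so the entire pipeline is
  testable end to end.

## Worked example

```python
from osnatlas import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig.default(seed=1))
print(results["stages"]["detect"]["exclusive_lineages"])
print(results["stages"]["detect"]["partial_death"])
print(results["evaluation"])
```

prints (seed 1):

```
['ab1D', 'ai1C', 'at1C']
['ac1B']
{'annotation_accuracy_mid_late': 0.953655, 'unannotated_fraction': 0.0,
 'unannotated_early_share': nan, 'undead_recall': 1.0,
 'undead_precision': 1.0, 'pseudotime_spearman_mean': 0.904847,
 'n_lineages_pseudotime': 14}
```

The default study simulates ~3,500 control and 4,200 PCD-blocked cells
(2,000 genes; 14 classes in 6 sensilla) with three fully death-fated classes
and one partially death-fated class (rate 0.4). The pipeline recovers the
three full-death lineages as PCD-blocked-exclusive clusters and the partial
one through abundance re-equilibration — recall and precision 1.0 against
the planted truth — and annotates 95% of mid/late cells correctly.

The same stages are available from the shell:

```bash
osnatlas simulate --seed 1 --out atlas/
osnatlas cluster  --in atlas/ --resolution 6.0 --seed 1 --out clusters.tsv
osnatlas annotate --in atlas/ --model atlas/sensilla.json --seed 1 --out annotation.tsv
osnatlas pipeline --seed 1 --out run1/
```

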