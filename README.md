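# bivalchrom

Bivalent chromatin — promoter or enhancer regions carrying both the
activating H3K4me3 and the repressing H3K27me3 histone mark — keeps
developmental genes silent but poised. In normal cells the DNA beneath
bivalent chromatin is nearly unmethylated; in tumors it is frequently
hypermethylated, and the bivalent state itself is often lost.
`bivalchrom` is a toolkit for exploiting and dissecting this signature:

- **Frequently bivalent segments (FBS).** Bivalent (TssBiv/EnhBiv)
  intervals from many ChromHMM 15-state segmentations are pooled,
  merged, and annotated with the number of *distinct* contributing cell
  types; segments supported by more than 80% of inputs form the FBS
  set. Control sets (ESC-conditioned, active-promoter background) and
  gene association via promoter-extended overlap are included.
- **A training-free DNA-methylation cancer score.** For a 450k-style
  beta-value profile, the score is the mean methylation over descriptor
  regions divided by the mean methylation over all covered CpGs:

  $$s = \frac{\tfrac{1}{|R|}\sum_{r \in R} \bar\beta_r}{\bar\beta_{\text{array}}}$$

  where $\bar\beta_r$ is the mean beta over the CpGs of region $r$
  (regions with < 3 covered CpGs dropped, samples with < 3 surviving
  regions discarded). No training step: normal tissue gives $s \ll 1$,
  hypermethylated tumors push $s$ up. Evaluation by Mann–Whitney AUC,
  exhaustive region-subset search, the tumor-purity level at which the
  90% prediction band of the score crosses a detection threshold, and
  rank correlation with ordinal stage/grade. The 14-region descriptor
  set (HOXB cluster, PAX3/6, LBX1, DBX1, TBR1, ZIC2/5, …) ships with
  the package; a scikit-learn-compatible estimator wrapper
  (`BivalentMethylationClassifier`) is provided.
- **Chromatin stability.** The 15 states grouped into 8 categories;
  per category, the fraction of reference (normal) bases that keep
  their category in a paired (cancer) segmentation, contrasted across
  cancer pairs vs related-normal pairs with per-category z-scores and a
  rank-sum test.
- **Methylation profiling.** Per-CpG tumor−control mean beta
  differences, segment aggregation under the ≥3-CpG rule, 300-bin
  length-normalised border profiles, and the stable/lost/new
  bivalency-fate partition with its methylation contrast.
- **Methylation–expression integration.** Per-gene methylation change
  against differential-expression tables: quadrant analysis (Q1 =
  hypermethylated *and* up-regulated, the positive-dependence
  signature), lowly-expressed restriction, fold-change comparison of
  gene sets, and recurrently up/down gene sets across cancers.
- **A seeded synthetic-data generator** producing segmentations, beta
  matrices with purity mixing, purity/stage tables and DE tables with
  known planted structure, so the whole pipeline runs and is tested
  without any external download.

## Worked example

```python
import bivalchrom as bc
from bivalchrom import simulate, classifier, methylation

cfg = bc.SimConfig(seed=1)                 # 20 cell types, 12 planted regions
world = bc.simulate_world(cfg)

# FBS construction: strict "more than 80% of inputs" support rule
merged = bc.count_distinct_merge(world.segmentations)
fbs = bc.build_fbs(merged, n_inputs=cfg.n_celltypes)
print(len(fbs), sorted(fbs.intervals) == sorted(world.truth.planted_regions))
# 12 True

# score purity-mixed tumor and normal samples, no training
beta, purity = simulate.simulate_betas(cfg, world.sites)
scored = classifier.score_samples(beta, fbs.intervals)
print(round(classifier.roc_auc(scored).auc, 3))
# 0.973

# methylation change at the planted regions (bulk, purity-diluted)
track = methylation.group_mean_diff(beta)
summ = methylation.segment_aggregate(track, fbs.intervals)
print(round(sum(s.mean_value for s in summ) / len(summ), 3))
# 0.045
```

The 12 planted regions are recovered exactly; the score separates
tumors from normals with AUC ≈ 0.97 although tumors are purity-mixed;
and the planted +0.07 hypermethylation appears as ≈ +0.045 in bulk
because the average simulated tumor is only ~70% pure.

A command-line interface mirrors the library
(`bivalchrom simulate|fbs|stability|methdiff|profile|fate|classify|integrate`);
run `bivalchrom --help`.

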