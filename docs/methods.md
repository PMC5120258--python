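# Methods

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); printed
descriptor-region coordinates are ingested as half-open intervals.
State mnemonics may carry a numeric prefix (`10_TssBiv`), which is
stripped; matching is case-sensitive afterwards. Merging joins
intervals whose gap is at most `max_gap` (default 0), so book-ended
intervals merge — the default of the standard merging tools. Two
distinct subtraction semantics are used deliberately: `subtract`
discards a whole interval on ≥1 bp overlap (used when building the
active-promoter background, where overlapping *segments* are
discarded), while `difference` clips at base level (used by the
bivalency-fate partition, the only reading consistent with partial
overlaps).

## Frequently bivalent segments

Bivalent promoter and enhancer intervals (`TssBiv`, `EnhBiv`; `BivFlnk`
is intentionally excluded here but included in the stability
category — the flanking state marks the shoulders of bivalent domains,
not the domains themselves) are pooled across segmentations and
merged. A dataset contributes to a merged cluster if any of its
intervals was merged into that cluster (cluster-level attribution,
mirroring distinct-count merging semantics); support is the number of
distinct contributors. The fractional support rule is strict: support
must exceed `f·N` (f = 0.8 over 122 inputs keeps support ≥ 98). The
absolute rule (`support ≥ k`) serves the high-stringency descriptor set
(k = 120) and small-panel controls (k = 7 of 8 ESC). Conditional sets
keep segments passing a rule in one group whose maximal support among
overlapping segments of a second group fails a second rule; a segment
with no overlap counts as support 0 there.

Gene association: the gene body is extended 1,500 nt upstream of the
TSS (strand-aware, clipped at position 0; chromosome ends are not
clipped since lengths are optional), and any ≥1 bp overlap with a
segment associates the pair. Coverage statistics between an FBS set
and a single segmentation are segment-level (≥1 bp overlap counts a
segment), not base-fraction-level.

## Chromatin-category stability

The 15 states collapse onto 8 categories (Bivalent, Promoter,
Transcribed, Enhancer, PolycombRepressed, ZNF, Quiescent,
Heterochromatin). Stability is directional: for each category, the
fraction of *reference* (normal) bases that carry the same category in
the query; reference bases the query does not cover count as changed.
The group comparison reports per-category means, the difference
Δc = mean(normal pairs) − mean(cancer pairs), and a z-score of each Δc
against the mean and SD of all categories' differences. The SD uses
ddof = 1 (sample SD over the 8 category differences): with one
category at Δ = 1 among seven at 0 this gives z = 0.875/√(0.875/7) ≈
2.475. The accompanying rank-sum test compares the focal (Bivalent)
category's stability values in cancer pairs against the pooled
other-category values in cancer pairs, two-sided; scipy's
Mann–Whitney implementation selects the exact null for small tie-free
samples and the tie-corrected normal approximation otherwise.

## Methylation

Group means are unweighted means over non-missing beta values per CpG;
the difference track is mean(tumor) − mean(control), missing wherever
either group has no data. Segment aggregation is an unweighted mean
over covered CpGs (CpG-weighted, not base-weighted — matching array
practice and the covered-CpGs discard rule), and segments with fewer
than 3 covered CpGs are discarded. WGBS-style inputs enter as per-CpG
bedGraph tracks and are treated identically.

Border profiles extend each segment of length L by `extension·L`
(default 100%) on both sides and split the window into 300 equal bins
(100 flank / 100 body / 100 flank). Bin assignment uses exact integer
arithmetic, `(pos − window_start)·n_bins // span`, so a site on a bin
boundary belongs to the right-open bin containing it. Per segment and
bin the mean of covered sites is taken; the profile bin is the mean
over segments with data there — bins without data are missing, never
zero. Windows overhanging the origin are clipped implicitly (no sites
exist at negative coordinates). A length split at 10,000 nt supports
profiling short and long segments separately.

The bivalency-fate partition intersects the merged bivalent bases
(category level: TssBiv, BivFlnk, EnhBiv) of a normal and a cancer
segmentation: stable = both, lost = normal only, new = cancer only.
The three classes are disjoint and satisfy stable+lost = normal
bivalent bases, stable+new = cancer bivalent bases (tested
exhaustively). Fate methylation comparison aggregates each class's
sub-intervals under the ≥3-CpG rule and contrasts lost vs stable with
a two-sided rank-sum test (skipped and flagged below 2 segments per
class).

## Training-free cancer score

The score of a sample is mean(region means)/mean(all covered CpGs).
Regions covering < 3 CpGs with data are dropped per sample; samples
with < 3 surviving regions (or a zero denominator) are discarded with
a reason. The ratio is scale-invariant: multiplying a sample's betas
by a constant leaves the score unchanged, which buffers global
normalisation differences between arrays. Cancer is the positive
class; higher scores predict cancer. AUC follows the Mann–Whitney
convention (ties half credit) and equals the trapezoidal area under
the ROC points.

Subset search enumerates all 2^n − 1 non-empty region subsets
(refused above 20 regions) and rescores samples per subset with the
same filters; for subsets of fewer than 3 regions the min-segments
sample filter is waived (all subset regions with data are required
instead) and flagged, since the filter would otherwise discard every
sample.

Purity crossing fits score = a + b·purity by OLS and takes the lower
bound of the 90% *prediction* interval (not the confidence interval of
the mean — the procedure asks where an individual sample's score
becomes reliably detectable). The detection threshold is the 95th
percentile of the control scores, i.e. the cutoff operating at 95%
specificity; the reported crossing is the smallest purity in (0, 1]
where the lower bound reaches the threshold (bracketed on a grid and
refined by root finding), undefined when it never does. The
sensitivity/specificity wording of such thresholds is often
ambiguous; the quantile and rate are configurable.

Stage/grade correlation maps "Stage I…IV" (sub-stages a/b/c collapsed
to the main stage) and "G1…G4" to 1–4, discards everything else, and
uses Spearman rank correlation by default (the levels are ordinal);
Pearson is available by flag.

## Methylation–expression integration

Per-gene methylation change is the mean over the gene's associated
segments' mean differences (or over the promoter-extended gene window
for window-based analyses). Quadrant analysis restricts to genes
significant at FDR < 0.05 (the field-default cutoff, configurable;
optionally also logCPM(normal) < 0 for the lowly-expressed
restriction) and counts sign quadrants of (Δmeth, log2FC); exact zeros
on either axis are excluded from all quadrants (measure-zero under the
generator). Fold-change group comparisons remove the focal set from
the background and use a two-sided rank-sum test. Recurrence sets
require significance with consistent direction in strictly more than
`min_fraction` of the supplied tables AND in at least `min_datasets`
tables (all supplied tables are counted, whether or not the gene was
testable in each); a gene qualifying in both directions is assigned to
the direction with more supporting datasets, ties excluded.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume.
Defaults are the study conditions: two 400 kb chromosomes, 20 cell
types, 12 planted frequently bivalent regions of 4–12 kb shown as
bivalent by 90% of cell types, 8 decoys at 40% support, cell-type
private bivalent intervals, 300 genes (1–2 per planted region, the
rest background), CpGs every 150 nt inside bivalent regions and every
1,000 nt outside, 100 tumors and 100 controls. Beta values are drawn
from Beta distributions parameterised by mean and concentration
(κ = 50), keeping values in [0, 1] without clipping artifacts; the
bivalent baseline mean is 0.10 and the background is a bimodal
high/low mixture (0.85/0.15 at 60/40), as on real arrays. Tumors add
+0.07 to affected bivalent regions (the effect size the score is
designed to detect) and −0.05 everywhere else (mild global
hypomethylation, bracketing the −0.06/−0.04 losses seen in lymphoma
WGBS); observed tumor signal is p·tumor + (1 − p)·control with
purities drawn from Beta(5, 2). Per-sample heterogeneity enters as a
small jitter on bivalent-region means (SD 0.02) and on the array-wide
level (SD 0.01).

Support is implemented as an exact contributor count
(`round(fraction·N)` randomly chosen cell types), not an independent
Bernoulli per cell type: the planted support is then deterministic and
the recovery guarantee (planted regions at 0.9N all pass the strict
0.8 rule; decoys at 0.4N never do) holds for every seed, which is what
the recovery tests require. Non-bivalent filler states are sampled
from a fixed frequency table (Quies-dominated) so category stability
has realistic composition. Cancer counterparts relabel bivalent
intervals with probability 0.7 where they overlap a hypermethylating
region and 0.2 elsewhere (loss and hypermethylation co-occur, as
observed in tumors), plus occasional new bivalent intervals and a 3%
background label churn; index-matched "related normal" segmentations
apply the same churn with only the basal bivalency turnover, providing
the normal-pair control for stability contrasts. Region effect
heterogeneity (SD 0.02 around +0.07) applies only when a nonzero
effect is planted; a zero effect keeps tumors and controls exactly
exchangeable, which the null-calibration tests rely on.

DE tables are generated per gene from two groups of 30 simulated
replicates (log-scale SD 1.0) — group sizes in the range of real
cohort comparisons — so p-values come from an actual two-group test
and Benjamini–Hochberg FDR behaves realistically rather than being
assigned. FBS genes carry a +0.94 mean log2 fold-change shift; the
dependence knob ρ couples fold change to the gene's methylation
change after within-group standardisation, so ρ = 0 yields exact
independence and the group means stay at their configured values.
logCPM(normal) marks 60% of FBS genes and 30% of background genes as
lowly expressed.

What the generator does *not* emulate: probe-specific biases and
batch effects of real arrays, linkage between neighbouring CpGs,
segmentation errors, copy-number effects on expression, and the
cell-type diversity of real tissue panels. Passing tests therefore
demonstrate correctness of the computations and recovery of planted
structure under idealised noise, not performance on consortium data.

## Problem sizes and numerics

Tests and the acceptance script run the generator at two 200–400 kb
chromosomes, 10–20 cell types and ≤ 400 genes — the scale at which all
planted-structure guarantees are exercised while the suite stays
fast. Interval operations use sorted sweeps checked against per-base
bit-vector oracles (and `bedtools merge`) on small fixtures. Rank
tests use scipy's exact small-sample nulls where tie-free. The purity
crossing is located on a 2001-point grid and refined with Brent's
method to ~1e-10. All randomness flows through seeded numpy
generators; identical configuration and seed give bit-identical
output.

## Known limitations

- The per-cancer descriptor evaluation scores each dataset against its
  own controls; pooled-control evaluation is a one-line change but not
  the default.
- The promoter-only and enhancer-only descriptor variants have no
  published coordinates; they can be rebuilt from segmentation inputs
  but are not packaged, and requesting them raises an explicit error.
- The exact recipe behind the published stability z-score is not
  fully specified; ours (sample SD over the 8 category differences) is
  documented above and matches the worked example it was derived from,
  but is not claimed to reproduce the published value digit for digit.
- Subset enumeration counts 2^14 − 1 = 16,383 non-empty subsets of 14
  regions; published counts of "16,396 subsets" cannot arise from 14
  items and presumably include bookkeeping duplicates.
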