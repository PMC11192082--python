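# Methods

This note records the models behind each stage, the defaults and why they
are what they are, what the synthetic generator does and does not emulate,
and the judgment calls made where the procedure left room.

## Synthetic generative model (`syndata`)

Counts for cell c, gene g are negative binomial with mean

    mu_cg = exp( b_g + f_c . w_g + m_{p(c),g} + s_{b(c),g} )

where `b_g` is a gene baseline (log-normal: N(log 0.3, 1) on the log scale,
giving ~0.5 mean counts/gene/cell and realistic UMI totals of a few hundred
to a few thousand per cell at 1-2k genes), `f_c` is the cell's score on a
shared rank-r factor basis (r = 15, the expected-heterogeneity rank used by
the common-factor integration this emulates), `w_g` its loadings,
`m_{p,g}` the planted marker offset (log(2) x the requested log2FC for the
marker genes of population p), and `s_{b,g} ~ N(0, batch_scale_sd)` a
per-batch per-gene multiplicative distortion — the scaling-type batch
effect that factor-based integration is designed to remove. Dispersion is
a single global NB shape theta = 2 (var = mu + mu^2/theta), the field's
default noise model for UMI counts; the hurdle/zero-inflation structure of
plate data is not modeled.

Design choices worth knowing:

- **Population structure lives in factor space.** Populations are centroids
  in the r-dimensional factor space (expected pairwise distance
  `population_separation`, default 4, against within-population SD 1 per
  dimension). Loadings are small (SD 0.025) so the factor term produces
  diffuse transcriptome-wide covariance rather than marker-scale fold
  changes: at the defaults the factor-induced per-gene log2 shift between
  populations has SD ~0.14, safely under the 0.5 log2FC marker filter.
  Marker recovery statistics against planted truth are therefore
  meaningful; with large loadings every gene would be differentially
  expressed and "precision against planted markers" would be ill-posed.
- **Planted markers are exact and detectable.** Marker genes get their
  factor loadings zeroed (so the planted log2FC is the exact expected
  log2 mean ratio) and draw their baseline from a moderately expressed
  regime (N(log 1, 0.5)), as real curated markers are detectable genes.
  Marker sets of distinct populations are disjoint by construction.
- **The "ideal" embedding is the true factor-score matrix** — what a
  perfect integration would return. `corrupt_embedding` adds per-batch
  rotations/translations for testing integration metrics;
  `pca_embedding` gives the uncorrected view in which batch effects are
  visible.
- **Spots** sum the counts of exactly `cells_per_spot` (default 4) cells
  sampled without replacement within a spot; the majority annotation comes
  from the constituent cells' labels with lexicographic tie-break.
  Ambient RNA, doublet kinetics and segmentation error are not emulated.
- **Cell/nucleus mixtures** rescale each barcode's expected library
  composition so the flagged ribosomal panel carries a given share of the
  library (defaults: 0.40 in whole cells vs 0.05 in nuclei) and the lncRNA
  panel likewise (0.08 in nuclei vs 0.01 in cells). The asymmetry is the
  point: whole cells carry a dominant cytoplasmic ribosomal share and
  little nuclear-retained lncRNA, so their ribo-score x lnc-score product
  is large and negative, while nuclei deviate mildly in both directions
  and sit near zero. That is the empirical configuration under which a
  fixed −0.5 product threshold separates the classes; the mechanism is
  demonstrated on this synthetic family rather than asserted in general.
  These shares were fixed at design time from this sign analysis and were
  not tuned against test outcomes.

A green test on this generator establishes that the pipeline's statistics
behave correctly under NB noise, low-rank population structure,
multiplicative batch effects and the planted-marker model — not that they
are robust to ambient contamination, doublets, batch-specific cell-type
composition shifts, or UMI saturation, none of which are simulated.

## kNN refinement and neighbor purity (`embedkit`)

Neighbor search is exact; below 4096 cells the full pairwise distance
matrix is formed and neighbor order is the lexicographic pair
(distance, cell_id), making results deterministic and bit-identical to a
brute-force oracle even under distance ties. Above that, an exact
tree-based search is used with an 8-rank tie buffer.

Refinement uses k = 25 votes with the cell itself excluded: including self
would bias toward the input label and reduce the effective vote count.
Ties go to the cell's original label when it is among the tied modes
(refinement should be conservative), else to the lexicographically
smallest tied label. Unlabeled cells are refused unless `allow_missing`,
in which case they neither vote nor change.

Purity uses k = 200. Entry (A,B) is the mean percentage of class-A cells'
neighbors labeled B; rows sum to 100 exactly. Under random labels each
entry concentrates on the global label share with the single-draw
hypergeometric SD 100/k * sqrt(k p (1-p) (N-1-k)/(N-2)) as the natural
scale — neighborhoods of same-class cells overlap, so the row mean's own
SE has no closed form and calibration is checked against the single-draw
band.

## State projection (`stateproj`)

Random forest, 500 trees, on the integrated coordinates; prediction is
argmax of the class-probability matrix (ties, which are rare, go to the
lexicographically smallest class and are logged; no confidence threshold
is applied). Cross-validation is stratified — the published procedure
says 10-fold without detail, and without stratification rare states drop
out of folds entirely. Folds are pooled into one confusion matrix before
computing per-class sensitivity, specificity and balanced accuracy, so
the balanced-accuracy identity holds exactly on the reported matrix. The
backend is pluggable behind a `fit`/`predict_proba` score-matrix
contract; all invariants are backend-independent. No resampling for class
imbalance: balanced accuracy per class is the imbalance-aware metric.

## Markers, overlap, scores (`markerkit`)

- **Test**: default two-sided Wilcoxon rank-sum on the log-normalized
  layer, vectorized over genes; all-tied genes get p = 1. The test is a
  pluggable callable so a hurdle-model backend can be slotted in; the
  thresholds and filtering logic, not the test internals, are the
  contribution here.
- **log2FC definition** (left open by the procedure): log2 of the ratio
  of group means of de-logged counts-per-10k, with pseudocount 1 added to
  both means; configurable.
- **Multiple testing**: Bonferroni over all genes in the matrix (the
  family is fixed regardless of post-filters; `min_frac` is applied after
  testing so it cannot shrink the family).
- **Fisher universe**: the intersection of genes tested in both datasets,
  supplied explicitly by the caller — marker tables alone do not define
  it. Default ortholog mapping is case-normalized symbol matching
  (mouse Title-case vs human UPPER); an explicit two-column map overrides.
- **Module score**: 24 equal-occupancy bins of dataset-average
  expression; for each set gene up to 100 control genes sampled without
  replacement from its bin; the control pool is the union of draws. When
  the gene set is the whole panel the control pool saturates to the whole
  panel and the score is exactly zero. The score is *not* invariant to
  adding a constant to one cell's profile unless controls shift with it —
  the documented binned-control behavior, not an idealized one. Note the
  known caveat: a set whose genes monopolize their expression bins is its
  own control and scores near zero.
- **Regulon activity**: raw statistic sum_g w_g x_cg; 100 shared
  gene-label permutations give the per-cell null mean/SD; activity is the
  z-score; SD 0 yields activity 0 with a warning. Normalization is
  exact under gene exchangeability; on structured data a regulon whose
  targets are systematically high- or low-expressed carries a genuine
  nonzero baseline — that is signal, not a bug, and the null-calibration
  guarantee is stated for exchangeable data only. Regulons under 5
  present targets are dropped with a warning.
- **Fold-change correlation**: Pearson over the union of genes
  significant in either contrast, with each gene's fold change taken from
  its own table (tables should be produced unfiltered so non-significant
  genes carry measured, not imputed, values); genes absent from one table
  are dropped with a warning rather than imputed as 0.

## Spatial scores (`spatialscore`)

Signature weights default to the markers' log2 fold changes, restricted
to the top 50 markers by adjusted p — the published description names
"top markers" without counts or weights, so this default is an explicit,
reproducible substitute (both the count and the weight column are
parameters). Expression is counts-per-10k log1p by default; raw-count
mode exists. The bivariate map discretizes each score into rank-quantile
classes (robust to scale differences between the two scores); constant
vectors collapse to class 0 with a warning. Coordinates are abstract
planar x/y; no registration to histology is attempted.

## Cell/nucleus split (`splitcn`)

Scores are the package's own module scores over caller-supplied (or
var-flagged) ribosomal and lncRNA panels; the product is thresholded at
−0.5. A product exactly at the threshold — unassigned by a strict
greater/less rule — is called nucleus and flagged ambiguous, keeping the
"cell" call the stricter one. Intron-inclusive requantification of the
nuclei after the split is out of scope; the partition is the deliverable.

## Orchestration (`pipeline`)

One global seed is expanded per stage as sha256(seed:stage_name) mod 2^31,
so independent stages keep their streams under reordering. The threshold
bundle carries a provenance tag per parameter (published value vs repo
decision) and the manifest dumps it with every run, together with output
checksums and per-stage timing; reruns with the same config and seed are
checksum-identical.

## Known limitations

- The NB count model is a stand-in: the integration methods this emulates
  do not publish a generative count model, so the simulator uses the
  field-standard gamma-Poisson.
- Exact neighbor search only; the approximate path for >50k cells is not
  implemented (all supported analyses here run exact).
- The permutation count (100) bounds the resolution of regulon z-scores;
  extreme tail probabilities are not meaningful at that depth.
- Balanced accuracies reported on real integrated atlases are not
  reproducible here: they depend on the original accessions, which this
  package deliberately does not fetch.
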