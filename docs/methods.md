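# Methods

## Data model

Expression lives in genes × samples tables tagged with a scale:
`log2_intensity` for RMA-normalized microarray data (normalization itself
is upstream of this package) and linear `rpkm` for RNA-seq. Single-cell
RNA-seq enters as cluster *pseudo-samples* (mean RPKM over a cluster's
cells); each pseudo-sample counts as one replicate during selection. The
two platforms are never normalized together — the only cross-platform
operation is the soft intersection of marker sets.

Samples carry a cell type, a brain region, a study and a platform. Brain
regions form a tree; a sample participates in a region's selection run
when its annotated region equals the query or descends from it. Glial
cross-region inclusions (cortex-derived astrocytes used for thalamus,
whole-brain microglia used everywhere) are data, not code: per-sample
`override_regions` lists, with the keyword `all` for whole-brain glia. A
default hierarchy (whole brain → cerebrum {cortex, hippocampus, amygdala,
basal forebrain, striatum}, thalamus, brainstem {midbrain, locus
coeruleus}, cerebellum, spinal cord) is packaged; users supply their own
as YAML/JSON. Mouse→human mapping keeps every pair within a HomoloGene
group; deduplication is left to callers because no collapse rule is
canonical.

## Preprocessing

* **Low-signal filter**: a probeset is kept when its maximum over samples
  reaches the median of *all* matrix entries (we read "all probeset
  signals" as the full entry pool, not per-sample medians). The boundary
  is inclusive. Note the operation is not idempotent for arbitrary
  matrices — removing sub-median rows can raise the global median — but is
  stable in the bimodal expressed/unexpressed regime it presumes; the
  test suite pins that regime.
* **Second-pass quantile normalization** across samples at the probeset
  level, applied before collapsing (order: filter → quantile → collapse).
  Ties within a sample receive the mean of the rank-values they span.
* **Probeset→gene collapse**: the probeset with the largest sample
  variance (ddof = 1) represents the gene; ties break to the
  lexicographically smallest probeset id for determinism.
* **Cell-type summary**: replicate mean within each study, then
  unweighted mean across studies, so a 40-sample study counts no more
  than a 3-sample study.

## Marker selection

Thresholds (all configurable in `MarkerSelectionConfig`):

| parameter | microarray (log2) | RNA-seq (RPKM) |
|---|---|---|
| background B | 6 | 0.1 |
| expression threshold θ | 8 | 2.5 |
| fold requirement | 10× | 10× |
| mean / min silhouette | > 0.5 / > 0 | same |

RPKM comparisons happen after log2(x + 0.1); the pseudocount equals the
RNA-seq background so that "background" maps to log2(0.2). "10 times the
background" is multiplicative: the fold branch of the enrichment
criterion activates when the target summary exceeds B + log₂10 ≈ 9.32 on
the microarray scale; below that, a strict maximum over other cell types
is required instead (a 10-fold gap there would force other types below
background, where values carry no information).

The detectability criterion uses the **median of the target type's
per-sample values** (a per-sample detectability guard), while the
enrichment criterion uses the **cross-study summaries** and the median
over the *other* types' summaries.

Silhouettes are one-dimensional with distance |x_i − x_j|. The mean
silhouette pools all non-target types into one cluster and averages
s(i) = (b−a)/max(a,b) over *all* samples; the minimum silhouette takes,
for each other type separately, the mean width of the *target* samples
only, and keeps the worst. Singleton clusters contribute width 0, as does
the fully degenerate all-equal case. The implementation is vectorized
over genes via per-type pairwise distance block sums; tests verify it
against a literal O(n²) a(i)/b(i) implementation to 1e-12.

Robustness permutations: each of 500 rounds removes
round-half-up(n/3) samples uniformly at random from the region's pool
(unstratified), then — microarray only, to keep large studies from
dominating — subsamples each cell type's surviving studies down to the
smallest per-study count. Summaries, medians and silhouettes are
recomputed on the surviving samples. A cell type absent from a
permutation is excluded from that permutation's denominator rather than
counted as a failure. A gene is selected when its pass rate strictly
exceeds 95% ("more than"), and the uniqueness rule is applied to final
pass rates: a gene clearing the bar for two cell types is dropped from
both. One seeded generator drives all draws; identical seeds give
identical marker sets.

Soft intersection admits: genes selected on both platforms; genes
selected on one platform whose expression in the other platform's
summary is strictly maximal in the target cell type; and genes measured
on only one platform. Provenance records which rule admitted each gene.
Refinement filters (exclusion list with label, inclusion/allow list with
an extra drop list, external-dataset ranking where a gene is removed iff
its mean over target columns is strictly lower than the best other
column) log every removed gene.

Distinct pyramidal-subtype versus pan-pyramidal selection runs are
expressed as two annotation tables, not special-cased logic.

## MGP estimation

Genes are z-scored across bulk samples (correlation-scale PCA) and the
first principal component is computed by SVD each iteration; minority-
sign loadings mark genes whose variation opposes the consensus — the
expected signature of condition-specific regulation rather than
abundance — and all of them are removed per iteration (a one-at-a-time
mode removes only the largest-|loading| minority gene). Standardization
and the SVD are recomputed after each removal. Convergence is guaranteed
because the gene set strictly shrinks. Decisions for cases the procedure
itself does not fix:

* exact sign tie (equal counts): keep the sign group with the larger sum
  of absolute loadings;
* zero loadings: treated as majority (no directional conflict);
* a single surviving gene: the MGP is that standardized gene, with a
  warning;
* final orientation: scores are flipped so loadings are positive, making
  higher scores mean more of the cell type; reported scores are also
  min-max scaled to [0, 1] (raw PC1 scores are kept alongside).

Group comparisons use the two-sided Wilcoxon rank-sum test (exact null
for small tie-free groups, otherwise tie- and continuity-corrected
normal approximation; the reported statistic is the Mann–Whitney U of the
non-reference group, i.e. its rank sum minus the minimum possible), with
optional Benjamini–Hochberg adjustment. The method yields *relative*
profiles; it does not estimate absolute cell proportions.

## Single-cell co-detection validation

Detection is binary (any nonzero value). Spearman ρ between two binary
detection vectors is computed on ranked rows; constant rows are dropped
with a warning. Prevalence matching is multiplicative: candidates for a
marker with prevalence p lie in [0.975p, 1.025p], inclusive; the
candidate pool excludes the marker genes themselves and never/always-
detected genes. When a marker has no candidate — or within-group
uniqueness exhausts its candidates — the window widens in 2.5% steps
(logged) up to ±25%, then errors. The test is one-sided ("greater"):
markers are claimed to be more co-detected than matched random genes. By
default the 1000 null groups' pairwise correlations are pooled into one
null sample (a rank-sum test needs observations, and pooling is the most
direct reading); a per-group-means mode is available. Calibration and
power are checked empirically: under independent detections the p-values
are uniform (KS) with nominal type-I error, and a 20-gene planted module
in 500 cells is detected at p < 0.001 essentially always.

## Synthetic data

`simulate_atlas` plants markers at log2 level 11 in their own type and 6
elsewhere (a 32-fold gap — the 10-fold rule needs ≈3.32, and the margin
absorbs noise), non-markers at a per-gene baseline drawn once from
[4, 9], per-sample noise SD 0.3 and per-gene-per-study batch offsets SD
0.2 — magnitudes typical of RMA-processed purified-cell data. Defaults: 6
cell types × 3 studies × 4 replicates, 1000 genes, 10 markers per type.

`simulate_bulk` draws per-sample proportions from a symmetric Dirichlet
(concentration 1) and mixes profiles on the **linear** scale before
log2-transforming (transcript quantities add in tissue; log intensities
do not), adding Gaussian noise (SD 0.3). Regulated genes swap their
profile between their own cell type and the most abundant *other* type
(by mean proportion) — this guarantees an inverted association for a
marker of any cell type, which the literal "two most abundant types"
reading would not.

`simulate_single_cells` draws detection from a logistic function of the
log2 profile (midpoint 7, steepness 1 — genes near background are rarely
detected, strong markers almost always); planted co-detection modules
share a per-cell latent state, copied per gene with a fidelity f (pairwise
detection correlation ≈ f²).

What the generators do **not** emulate: probe-level effects and real
platform noise spectra, realistic brain composition, mean–variance
relationships of counts, doublets/ambient contamination, or
transcriptome-wide correlation structure. Passing tests therefore show
the algorithms implement their definitions and recover planted structure
under the stated noise model, not that the thresholds are optimal for any
particular real dataset.

## Problem sizes used in verification

The acceptance script and end-to-end tests use: the default 1000-gene
atlas with 500-permutation selection; 50-sample bulk mixtures of 4 cell
types; 100 replicates of regulated-gene pruning (200-gene atlases); 200
seeds for validation calibration (600 genes × 300 cells, 100 null groups)
and 100 replicates for power (400 genes × 500 cells); and a reduced
pipeline (200 genes, 25 permutations, 25 null groups) for the determinism
check. These sizes give stable Monte-Carlo estimates while keeping a full
verification run near one minute.

## Known limitations

* Absolute proportions are out of scope; MGPs are comparable across
  samples, not across cell types.
* Uniqueness is enforced on final pass rates, not per permutation; the
  alternative is stricter and would only shrink sets.
* Silhouettes within a permutation are computed on the study-subsampled
  surviving samples (the subsampling exists precisely to protect the
  silhouette from large studies).
* The prevalence-matched null reuses pool genes across groups, so pooled
  null correlations are not fully independent; the empirical calibration
  check shows the effect is negligible at the sizes used.
* Glial override samples are treated identically to native samples once
  assigned to a region, including during subsampling.
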