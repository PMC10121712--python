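# Methods

`snstates` implements the statistical toolkit used to dissect cell-state
structure in genetically stratified single-nucleus RNA-seq cohorts:
droplet-level quality control, batch/sample mixing entropy, differential
cell-state abundance, per-gene negative-binomial mixed-model differential
expression, gene-signature module scores, cross-cohort label transfer,
and hypergeometric replication statistics. A seeded synthetic-cohort
generator with full ground truth ties the pieces together so that every
stage can be validated by parameter recovery rather than by eye.

## Synthetic cohorts

The generator emulates the statistical structure the downstream models
assume, not the full biology of cortical tissue. A cohort has
`n_subjects` donors (default 10), each contributing `nuclei_per_subject`
nuclei (default 200; the defaults give desk-scale cohorts of 2,000–5,000
nuclei). Each nucleus belongs to a cell type with a configurable number
of transcriptional states. Counts for nucleus *i*, gene *j* are drawn
from a (optionally zero-inflated) negative binomial with

```
log mu_ij = log(base_j) + state effect + group effect + b_subject(i) + d_i
```

where `b_subject ~ N(0, subject_re_sd^2)` is a per-donor random intercept
on the natural-log scale and `d_i ~ N(0, depth_log_sd^2)` a per-nucleus
depth factor. Defaults: per-gene dispersion 0.5 (variance = mu + 0.5 mu²,
mid-range for UMI data), `subject_re_sd = 0.3` (a ±35% donor-level swing,
chosen so that ignoring the random intercept is visibly anti-conservative
while recovery tests remain informative — donor variance in real tissue
is not identifiable from published summaries), `depth_log_sd = 0.25`,
zero inflation 0 (plain NB is the base case; a constant per-gene dropout
mixture is available and mirrors an intercept-only zero model).

Planted effects live on the scales the estimators work on: state/group
expression effects are natural-log mean shifts (so a planted `ln 2`
should be recovered as estimate ≈ 0.693, log2FC ≈ 1), and abundance
effects are additive shifts of the cube-root state proportion, cubed and
renormalized. The truth tables return every nucleus's state, doublet
flag and mitochondrial component, the per-subject planted proportions,
and the planted log2 fold-changes.

Mitochondrial contamination is a two-component Beta model on the
per-nucleus mitochondrial fraction (low component mean 2%, high 25%,
concentration 80), matching the intuition that a filtered dataset should
average ≈2% mitochondrial reads; the high component is the planted
answer for the k = 2 filter. Ambient barcodes are low-UMI multinomial
draws from the pooled expression profile (log-normal depth, default
scale 25 UMI), giving the two-plateau barcode-rank curve that knee
detection expects. Doublets are element-wise sums of two random nuclei
(homotypic or heterotypic as the pairing falls), flagged in metadata;
doublet *detection* is deliberately out of scope — the QC stage consumes
flags.

A single global seed drives per-stage `SeedSequence` substreams
(assignment, counts, mitochondria, metadata, doublets, ambient), so the
same cohort is reproduced bit-identically and stages can be toggled
without perturbing the others.

What the generator does **not** model: gene–gene correlation beyond the
shared donor/depth factors, spliced/unspliced structure, cell-type
specific library sizes, batch effects on expression (batch labels are
assigned but expression-neutral). Passing tests therefore demonstrate
the estimators' statistical correctness under the stated model, not
robustness to every artifact of real tissue.

## Quality control

Filtering is per subject, in the order: barcode-rank threshold,
mitochondrial filter, doublet-flag removal, then one global gene filter.

* **Barcode-rank knee.** Barcodes are sorted by descending UMI; on the
  (log10 rank, log10 UMI) curve the discrete slope over a 5-rank window
  is computed and the threshold sits at the steepest drop (geometric
  mean of the bracketing UMI values). The search is restricted to the
  top half of ranks: deep in the ambient tail, runs of tied integer
  counts make log-log steps arbitrarily steep because log-rank
  increments vanish. If no slope exceeds 2 in magnitude (an ambient-free
  sample has none), a fallback threshold (default 0 = keep all) is
  used; per-subject manual overrides are accepted, replacing the
  interactive threshold picking that the original workflow did by hand.
* **Mitochondrial filter.** An optional hard cap (default 10%) precedes
  a deterministic one-dimensional two-means split of the per-nucleus
  mitochondrial fraction (centroids initialized at min and max); the
  higher-mean group is removed. If the converged centroids differ by
  less than 5 percentage points the split is considered spurious and
  all nuclei are kept — without this guard, k = 2 on a homogeneous
  sample would always manufacture a "high" group.
* **Gene filter.** A gene is kept iff detected (nonzero) in at least 10
  nuclei.

The stage-by-stage report (nuclei retained, mean genes, mean UMI, mean
mitochondrial fraction) makes the cascade auditable; counts are checked
to be non-increasing.

## Mixing entropy

For cluster *i* with category proportions `p_j` (categories = samples or
batches), `H(i) = −Σ p_j log2 p_j`; the overall clustering entropy is
the nucleus-weighted sum `Σ H(i) N_i / N`. Entropies are normalized by
the global maximum `log2 K` where K counts the categories in the whole
dataset — with 14 batches that maximum is 3.81 bits and with 67 samples
6.07 bits — and clusters strictly below half the maximum are flagged
for review (boundary equality is unflagged).

## Differential cell-state abundance

Per subject and cell type, a state's proportion is
`n(state) / n(cell type)`; subjects contributing no more than the
cell-type minimum are excluded entirely (strict `>`; defaults 50 for
astrocytes/microglia, 60 for neurons and oligodendrocytes, 66 for OPCs —
these printed thresholds are configuration values, since the "natural
breaks" that produced them are not reproducible). The cube-root
transform pulls small proportions toward normality while preserving
ranks; the response is then fitted by OLS on the predictor of interest
(binary status or an additive 0/1/2 allele dose) plus covariates (sex,
and age of death or AD status as the contrast requires). OLS is exactly
the Gaussian `glm` estimator, and the reported p-values are the usual
t-statistics. Discovery/replication results are combined by Stouffer's
method: two-sided p-values become z-scores signed by the effect
direction, weighted by √(subjects); a zero effect contributes z = 0 and
exactly opposed effects cancel to z = 0 (combined two-sided p = 1). The
original analysis did not name its meta-analytic method; weighted
Stouffer is the standard choice for effect-signed p-value combination.

## Negative-binomial mixed-model differential expression

For one gene, counts follow an NB with log link:

```
log mu = X beta + offset + b_subject,   b_subject ~ N(0, sigma^2)
```

The subject random intercept is integrated out by a Laplace
approximation: the inner mode over subject intercepts is found by
damped per-subject Newton steps (the NB log-likelihood is strictly
concave in the intercept), and the outer optimization over fixed
effects, log dispersion and log sigma uses L-BFGS-B. Wald p-values come
from the numerical Hessian of the marginal log-likelihood at the
optimum — the common choice for this model class. Per-gene dispersion is
profiled jointly with the fixed effects. Convergence requires the
optimizer to succeed away from the parameter bounds with a positive
definite Hessian block; non-converged genes (all-zero genes, separated
designs) keep a flagged row and are excluded from the BH family.

Numerical choices: relative function tolerance 1e-8, at most 200
iterations, fixed-effect bounds ±30 on the log scale (a bound hit is
flagged, not reported), sigma bounded below at e^-8 where the Laplace
correction cancels exactly against the prior normalization, so the
sigma → 0 limit reproduces a plain NB regression (verified against an
independent NB maximizer to 1e-3).

A log-total-UMI offset is on by default. The upstream workflow argued
depth was handled by its normalization yet fed raw counts to the model;
a raw-count NB without any depth term is not depth-invariant, so the
offset is the default here with a flag to disable. The zero-inflated
variant adds a constant mixture weight for zeros (intercept-only zero
model) and is off by default: plain NB is identifiable and stable at
desk scale, and the ZI path is provided and tested as an option.

Scan modes: each state against all other states of its cell type, each
state pair, or a genotype group against controls, with sex always in
the design and age of death included except where it is confounded with
the contrast (autosomal dominant carriers are decades younger than
sporadic cases). Estimates are natural-log fold-changes;
`log2FC = log2(e^estimate)`. BH correction is applied within each scan
over the genes passing the 10-nuclei presence filter.

Known limitation: with planted effects concentrated in one direction,
the offset absorbs the compositional shift in total UMI and attenuates
estimates — a property of all library-size-normalized DE, visible in the
recovery tests unless planted effects are depth-balanced.

## Module scores and signature statistics

Genes are ranked by dataset-average expression into 24 bins; each
signature gene draws 100 control genes from its bin (signature genes
themselves are excluded from the pools, so a strong planted signal
cannot contaminate its own controls); the score is mean(signature) −
mean(controls) per nucleus. The score is exactly invariant to adding a
constant to the matrix and centred at zero for random sets. Bin and
control-set sizes are the upstream tool's defaults. Score differences
between clusters are tested pairwise with a Gaussian linear model,
optionally with a subject random intercept (statsmodels MixedLM) —
the tests demonstrate that the fixed-only variant is anti-conservative
when donor-level variation exists, which is why the random term is the
default. Signatures are extracted from DE tables with strict cutoffs
(q < 0.05 and |estimate| > 0.25). Published-signature overlap uses the
upper-tail hypergeometric test with BH across the reference panel; the
overlap universe defaults to the post-filter gene set. The APOE/MHC-I
module flags nuclei more than two SDs above mean APOE expression
(computed over the analyzed subset, imputed or not) and sums the six
class-I genes HLA-A/B/C/E/F and B2M.

## Label transfer by over-clustering

Reference and query are restricted to shared genes, z-scored per gene
within each dataset (removing constant per-gene batch offsets), and
embedded jointly by PCA. The embedding is shattered into many fine
clusters (centroid clustering with k = target fineness, the scale of
the original 147-cluster shattering; the embedding is pluggable and an
external integration can be supplied instead). Each fine cluster takes
the modal label of its *reference* members — only reference nuclei
vote — and hands it to its query members with a purity value. Ties
break to the lexicographically smallest label and are flagged. Fine
clusters without reference members take the label of the nearest
labeled centroid (flagged; an "unlabeled" policy is available). A
fineness larger than the number of nuclei is clamped with a warning.

## Replication statistics

Hypergeometric overlaps are computed in log space via log-gamma
combinatorics (scipy's implementation), stable to p ≈ 1e-300; both the
point probability P(X = k) and the upper tail P(X ≥ k) are reported.
For the printed TF-concordance parameters (M = 896, n = 222, N = 190,
k = 122) the point probability is 9.08e-41 and the tail 9.99e-41 — the
two values quoted in different places by the source analysis are the
point and tail of the same test. The regulon replication pipeline
intersects TF lists, tests overall concordance, keeps TFs that are
themselves differentially expressed, tests each regulon's target
overlap in the declared gene universe (the TF is excluded from its own
target sets by default), applies BH at 0.05 and drops regulons with
fewer than three shared targets (the strict ">2" rule). DEG concordance
between cohorts uses Fisher's exact test with a conditional-MLE odds
ratio (solved from the Fisher noncentral hypergeometric mean identity);
tables with a zero margin are reported as OR undefined, p = 1. The GWAS
summarization applies the 5%-of-nuclei state filter, drops negative
one-vs-rest estimates (a state's *under*-expression against the rest is
not evidence the gene acts in that state), converts estimates to log2FC
and reports the maximum absolute value per gene and cell type with
log10 mean expression.

## Problem sizes used in validation

Calibration and recovery runs use 10 subjects × 200 nuclei with 400–500
genes (DE), 500 replicate cohorts of 20 subjects (abundance), 100,000
barcodes (knee detection) and a 5,000-nucleus end-to-end cohort —
desk-scale datasets on which the full pipeline completes in about a
minute while leaving the binomial test intervals tight enough to detect
miscalibration.

## Known limitations

* The Laplace approximation can be slightly anti-conservative for
  between-donor contrasts with very few donors; adaptive quadrature is
  the natural upgrade path.
* Wald p-values are used throughout (no LRT).
* The barcode-rank rule is an automated stand-in for interactive
  threshold selection; per-subject overrides exist for that reason.
* The proportion model treats per-subject proportions as independent
  Gaussian observations after the cube-root transform; compositional
  methods (CLR, Dirichlet regression) are out of scope.
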