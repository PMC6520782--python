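# Methods

This note records the models, the numerical choices, and the reasoning
behind the design decisions that were genuinely open. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Denoising autoencoders

**One-input model.** For a [0,1]-scaled genes × patients matrix, each
patient profile `x` is encoded as `h = σ(Wᵀx̃ + b)` with `W ∈ ℝ^{G×100}`
and decoded as `σ(W h' + b_dec)`, where `h'` is `h` after dropout (training
only). The decode layer owns no weight matrix: it always uses the current
transpose of `W` (tied weights), so the parameter count is `G·100 + 100 +
G`. The encode outputs on the clean inputs, in inference mode, are the
feature activities used downstream; being sigmoid outputs they lie strictly
inside (0, 1).

**Two-input model.** Each source is encoded to 1000 units, the two encodes
are concatenated (2000), and a second encode maps to the 100 shared
features. The printed decode recipe of this architecture is dimensionally
inconsistent if the per-source transposes are applied directly to the
100-dim feature vector; the only shape-consistent tied-weight reading —
adopted here — inserts the transpose of the second-layer matrix first
(100 → 2000), splits the result into its two 1000-unit halves, and applies
each source's first-layer transpose (1000 → genes). Both `W2` and each
`W1` therefore receive gradient from an encode *and* a decode use.

**Corruption.** For every patient column independently, exactly
`round(0.25 · G)` gene positions are sampled without replacement and set to
0; the fraction is exact by construction, not in expectation. Corruption is
resampled every epoch from seeds derived from the training seed; a
fixed-mask variant (corrupt once before training) and a whole-gene-row
variant are available behind flags, since the sampling unit and schedule
admit both readings. The loss target is always the clean input (denoising
semantics).

**Training.** Plain SGD without momentum, learning rate 0.1, batch size 64,
100 epochs, 50% dropout after the feature layer. Dropout is *inverted*
(survivors scaled by 1/(1−p) at train time) so inference needs no
rescaling. Weights are initialized Glorot-uniform from a seeded generator;
biases start at 0. The loss is the mean binary cross-entropy over all
matrix entries; the per-epoch report is the batch-size-weighted mean. For
the two-input model the loss is the sum of the two reconstruction terms.
Gradients are exact: the test suite checks them against central finite
differences at 1e−5 relative tolerance. Cohorts smaller than one batch fall
back to a single batch with a logged warning. Everything is reproducible
from one integer seed (epoch corruption, shuffling and dropout streams are
spawned from it independently).

**Numerical details.** The logistic function is evaluated branch-wise to
avoid overflow and its output clamped to the open interval's nearest
representable neighbours; cross-entropy clamps outputs at 1e−12 (logged)
so perfect reconstructions stay finite.

## Preprocessing

Order: CPM filter → FPKM-UQ → (CNA: drop all-missing genes, mean-impute
gaps) → gene/patient matching → per-gene min-max scaling.

* The low-expression filter **keeps** genes with CPM ≥ 1 in at least 3
  patients — the standard reading; the literal alternative (drop a gene if
  any 3 patients are below 1) would discard nearly everything.
* The FPKM-UQ upper quartile is taken over each sample's *positive* counts
  so zeros cannot drag the quartile toward 0 in sparse data.
* Matching restricts both matrices to the sorted intersection of gene
  identifiers and to patients present in both sources and the clinical
  table (three-way intersection).
* Scaling is per gene (each gene attains 0 and 1 somewhere), so every gene
  contributes comparable dynamic range to the sigmoid autoencoder; genes
  with zero range are dropped and reported. Scaling is idempotent.

## Clustering and association testing

Patients are clustered on the activity matrix by agglomerative hierarchical
clustering, complete linkage, Euclidean distance, and the tree is cut into
k = 2 groups. Complete linkage is outlier-sensitive: a single extreme
patient can claim the top split, leaving a singleton "group" — the
situation a human reading the dendrogram would ignore. The cut therefore
deepens progressively until k clusters each covering at least 5% of
patients exist; patients on smaller outlier branches are assigned to the
nearest group centroid. When the groups are clean this reduces exactly to
the plain k-cut. This is the package's reproducible surrogate for
visual dendrogram inspection; k stays fixed at 2 by default (overridable)
because a visual choice of k is not reproducible.

Cluster membership is crossed with each clinical characteristic; 2×2
tables get the two-sided Fisher exact test (probability-ordering rule) with
the sample odds ratio (a·d)/(b·c) (undefined when b·c = 0), larger tables
get a seeded Monte-Carlo generalization of the exact test plus Pearson's
chi-square without continuity correction (expected counts < 5 are logged).
No multiple-testing correction is applied across characteristics by
default; a Benjamini–Hochberg option exists.

## Survival analysis

The univariate Cox fit maximizes the Breslow partial likelihood by
Newton–Raphson with step halving; convergence at |Δb| < 1e−8 or 50
iterations. The covariate is centred first (the estimate is
shift-invariant; centring stabilizes the exponentials). A constant
covariate returns b = 0, HR = 1 with infinite standard error; a monotone
likelihood (perfect separation) is flagged and |b| capped at 50 — the cap
is deliberately high because feature activities have standard deviations
near 0.01, so genuine finite per-unit estimates of 20–30 occur. Breslow tie
handling suffices because activities are continuous. Wald intervals
`exp(b ± 1.96·se)`.

Risk scores sum all 100 coefficient-weighted activities (no p-value
screening — the coefficients, not their p-values, enter the score). A
joint 100-covariate ridge-penalized fit is available behind a flag as the
alternative reading. Binarization uses the linear-interpolation empirical
quantile at 0.55; ties at the cutoff go to low-risk. KM estimation and the
log-rank test are delegated to `lifelines`; a cohort with no events reports
log-rank p = 1 with a warning rather than NaN.

## Gene trace-back

One-input: `w_g = Σᵢ W[g,i]·Bᵢ` with `B` the Cox coefficient vector.
Two-input: no direct genes × features matrix exists, so each source's
first-layer weights are composed with the matching half of the second-layer
matrix (`W1 · W2_half`, genes × features) before applying `B`; the combined
concatenated score for a shared gene is the sum of its two side scores
(max-|·| available behind a flag). The cutoff 0.01 is applied to |w_g| —
negative weights are equally informative, and single lists per model are
produced. Ranked lists are exported both as one-gene-per-line text and as
(gene, weight) TSV.

## Synthetic data generator

The generator is the package's stand-in for a real paired-omics cohort and
defines the conditions under which the pipeline is validated.

* Latent factors `z ∈ ℝ^{n×L}` (L = 4 by default) are standard normal; the
  first factor is shifted by ±`group_effect`/2 according to a binary
  subgroup label.
* Genes are split into L disjoint blocks; factor j loads only on block j
  with loadings of magnitude 0.4–0.8 (expression) / 0.3–0.6 (copy number)
  and random sign. The non-subgroup factors load at half strength
  (`nuisance_attenuation = 0.5`), emulating cohorts where the subtype axis
  dominates total variance, as the ER/basal axis does in breast tumors.
  The genes of block 1 are the `causal_genes` ground truth for trace-back
  evaluation.
* Expression counts are gamma-Poisson (negative binomial) with dispersion
  0.2 — raw RNA-seq counts are overdispersed, and integer counts make the
  CPM/FPKM-UQ stages meaningful. Copy-number values are the same latent
  signal plus Gaussian noise (sd 0.3), giving genuinely shared cross-omics
  structure. 10% of genes appear in only one source so gene matching is
  exercised.
* Survival is exponential with hazard `h₀·exp(hazard_coef·z₁)`
  (`h₀ = ln 2 / 1500` days). Censoring times are uniform on (0, c_max)
  with c_max calibrated by bisection so the realized censoring fraction
  approximates `censor_rate` (default 0.3). The ER-like label equals the
  subgroup label flipped with probability 0.1.
* Defaults: n = 300 patients, 2000 genes, group_effect = 3,
  hazard_coef = 0.8. Everything is bit-reproducible from the seed.

**What the generator does not emulate**: realistic CNA segmentation
profiles, PAM50-like multi-way subtype structure, tumor-stage confounding,
batch effects, or non-linear gene–gene dependence. Passing tests on this
generator therefore demonstrates that the implementation recovers *linear
block-structured* latent signal through the full stack — not that the
method would do so on any particular real cohort.

## Validation conditions and problem sizes

The test suite validates each operation against independent oracles
(hypergeometric enumeration for Fisher, O(n³) agglomeration for complete
linkage, grid-search partial-likelihood maximization for Cox, elementwise
loops for cross-entropy and trace-back) and runs the pipeline end-to-end at
reduced sizes chosen so the full suite completes in a few minutes on one
CPU: training-descent checks on a 2000-gene × 300-patient bundle at 20
epochs; Cox parameter recovery at n = 500 over 100 replicates; end-to-end
recovery at 400 genes × 300 patients with 100-unit per-source encodes over
20 replicate seeds; null calibration of the log-rank test over 200
replicates.

The end-to-end recovery study uses `group_effect = 8`. The choice is
driven by the clustering method, not the feature extraction: complete
linkage applied directly to the *true* latent factors needs roughly a
6-standard-deviation group separation before a k = 2 cut reaches ARI ≥ 0.8
reliably at n = 300, and the omics generation, [0,1] scaling and
autoencoder compression attenuate the realized feature-space separation
run-to-run, so the planted separation carries ~2× headroom over that
threshold. In runs where the hierarchical cut still fails, k-means on the
same activity matrix recovers the planted groups — the linkage criterion,
not the learned representation, is the binding constraint.

## Known limitations

* The autoencoders are CPU NumPy; they are sized for cohort-scale matrices
  (thousands of genes), not for architecture search or GPU-scale data.
* The Monte-Carlo r×c exact test uses a fixed internal seed; its p-values
  have sampling error ~1/√B (B = 2000 by default).
* The risk score's hazard ratio is per unit of the summed score; its
  magnitude depends on the activity scale and is not comparable across
  feature sets with different coefficient magnitudes.
* With 100 features fitted univariately there is no control of
  multiplicity; this is deliberate — the coefficients, not their p-values,
  feed the risk score — and the optional BH flag exists for users who want
  it.
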