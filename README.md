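# dasurv

Deep-feature extraction from paired tumor gene-expression and copy-number
matrices with **tied-weight denoising autoencoders (DAs)**, followed by the
full downstream association workflow: patient clustering on the learned
feature activities, clinical association testing, Cox-based survival risk
scoring, and trace-back of the risk weights to ranked gene lists.

The package is aimed at computational biologists who want a tested,
reproducible implementation of this multi-omics workflow — including a
synthetic-data generator with *planted* latent structure, so that every
stage can be validated against a known ground truth before being pointed at
a real cohort.

## The model

Each omics matrix (genes × patients) is scaled per gene into [0, 1] and fed
to a denoising autoencoder with tied weights:

```
encode = σ(Wᵀ x̃ + b)          W: genes × 100
decode = σ(W · encode + b')    (decode reuses the transpose of W)
```

where `x̃` is a corrupted copy of the patient profile (25% of gene values
set to 0 at random) and `σ` is the logistic function. Training minimizes the
binary cross-entropy `L(x, decode)` against the **clean** profile with
plain SGD (learning rate 0.1, batch 64, 100 epochs) and 50% inverted
dropout after the encode layer. The 100 encode outputs per patient are the
*activity values* of the deep features.

A two-input variant encodes each source into 1000 units, concatenates, and
encodes again into 100 shared features; the decode path runs the network
backwards through the transposed weights.

Downstream, for each feature *i* a univariate Cox proportional-hazards fit
`h(t) = h₀(t)·exp(bᵢ aᵢ)` supplies a coefficient, patients receive the risk
score `r = Σᵢ bᵢ aᵢ`, and the cohort is split at the 55% quantile of `r`
into high/low-risk groups compared by Kaplan–Meier curves and the log-rank
test. Feature weights are traced back to genes by `w_g = (W B)_g` (for the
two-input model via the composite per-source weight matrix `W1 · W2ₕₐₗf`),
filtered at |w_g| ≥ 0.01, and exported as ranked lists for enrichment
tools.

## Worked example

Simulate a 300-patient, 400-gene cohort whose two planted subgroups are
separated along the first latent factor (which also drives the hazard and
an ER-like label), then run the whole pipeline:

```yaml
# example.yaml
seed: 7
epochs: 100
n_features: 100
hidden1: 100          # scaled-down per-source encode for a quick run
sim: {n_patients: 300, n_genes: 400, group_effect: 8.0, hazard_coef: 1.0, seed: 7}
```

```bash
dasurv all --config example.yaml --outdir run_example
```

The run directory contains the simulated inputs, the three activity
matrices (expression, CNA, concatenated), the clustered heat map with
clinical side bars, per-feature Cox tables, risk profiles, KM plots, ranked
gene lists and `summary.json`. For this configuration the summary reports:

```
preprocess:  360 matched genes x 300 patients
cluster:     ARI vs planted groups 0.987, sizes {1: 162, 2: 138}
er_status:   Fisher p = 2.9e-43, chi-square p = 4.2e-39, OR = 55.3
risk (concatenated): HR 1.087 (95% CI 1.075-1.100), log-rank p = 4.0e-69
training:    mean BCE 1.410 (epoch 1) -> 1.227 (epoch 100)
```

That is: the two-group cut of the concatenated deep features recovers the
planted subgroups almost exactly (adjusted Rand index 0.987), the clusters
are strongly associated with the ER-like label, and the high-risk group
defined by the Cox-weighted score has markedly worse survival — the
qualitative behaviour expected when shared latent structure drives both
omics sources and the hazard. Every stage is also runnable on its own
(`dasurv simulate / preprocess / train / cluster / associate / riskscore /
traceback`); the stages compose through tab-separated files.

## Limitations

The generator plants block-structured linear latent signal; real cohorts
are messier (see `docs/methods.md` for what passing on synthetic data does
and does not demonstrate). Gene-set enrichment of the exported lists is
intentionally out of scope — the ranked files are formatted for external
enrichment tools.
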