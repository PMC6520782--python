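"""Synthetic paired-omics generator with planted latent structure.

Produces a gene-expression count matrix, a log2 copy-number matrix over a
shared gene set, and a clinical table with right-censored overall survival,
all driven by the same patient-level latent factors.  Two patient subgroups
are planted by shifting the first latent factor; the same factor drives the
hazard, so every downstream stage (feature extraction, clustering,
association testing, risk scoring, gene trace-back) has a recoverable
ground truth.

Model
-----
Latent factors ``z`` are standard normal per patient; the first factor gets
an additive shift of ``±group_effect/2`` by subgroup.  Expression counts are
negative-binomial with log-mean ``baseline_g + L[g,:]·z_p`` where the loading
matrix ``L`` is block-sparse: the genes are split into ``n_latent`` disjoint
blocks and each factor loads only on its own block, so the genes driven by
the hazard-linked factor are exactly one block.  The first (subgroup) factor
loads at full strength and the nuisance factors at half strength, emulating
cohorts where the subtype axis dominates total variance (as the ER/basal
axis does in breast tumors).  Copy-number values are a linear function of
the *same* factors plus Gaussian noise, giving shared cross-omics structure.
Survival is exponential with hazard ``h0·exp(hazard_coef·z_1)`` and uniform
censoring calibrated to the requested censoring fraction.  An ER-like binary
label equals the subgroup label flipped with a small probability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "GroundTruth", "SyntheticBundle", "simulate_bundle", "write_bundle"]

# baseline mean-count range (log scale) for expressed genes
_BASE_LOG_LO = np.log(5.0)
_BASE_LOG_HI = np.log(500.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    Parameters
    ----------
    n_patients, n_genes, n_latent
        Dimensions; ``n_latent`` must be smaller than both.
    group_effect
        Separation (in latent-space standard deviations) between the two
        planted subgroups along the first latent factor.
    hazard_coef
        Log-hazard-ratio linking the first latent factor to survival.
    censor_rate
        Target fraction of right-censored patients, in [0, 1].
    er_flip_prob
        Label noise on the ER-like label, in [0, 0.5].
    dispersion
        Negative-binomial dispersion of the counts (var = mu + dispersion*mu^2).
    frac_source_specific
        Fraction of genes present in only one omics source (half of them
        expression-only, half CNA-only), so gene matching is non-trivial.
    nuisance_attenuation
        Loading strength of the non-subgroup latent factors relative to the
        first factor; values below 1 make the subgroup axis the dominant
        source of variance.
    """

    n_patients: int = 300
    n_genes: int = 2000
    n_latent: int = 4
    group_effect: float = 3.0
    hazard_coef: float = 0.8
    censor_rate: float = 0.3
    er_flip_prob: float = 0.1
    seed: int = 0
    dispersion: float = 0.2
    frac_source_specific: float = 0.1
    nuisance_attenuation: float = 0.5
    baseline_hazard: float = np.log(2.0) / 1500.0  # median ~1500 days at z1=0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0 or self.n_latent <= 0:
            raise ValueError("n_patients, n_genes and n_latent must be positive")
        if not (self.n_latent < self.n_genes and self.n_latent < self.n_patients):
            raise ValueError("n_latent must be smaller than n_genes and n_patients")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if not 0.0 <= self.er_flip_prob <= 0.5:
            raise ValueError("er_flip_prob must lie in [0, 0.5]")
        if self.group_effect < 0:
            raise ValueError("group_effect must be non-negative")
        if not 0.0 <= self.frac_source_specific < 1.0:
            raise ValueError("frac_source_specific must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted structure of one simulated bundle."""

    group_label: np.ndarray           # (n_patients,) in {0, 1}
    latent_factors: np.ndarray        # (n_patients, n_latent)
    causal_genes: frozenset[str]      # genes loading on the hazard-linked factor


@dataclass
class SyntheticBundle:
    """Raw simulated inputs, mirroring what a cohort download provides."""

    counts: pd.DataFrame              # genes x patients, non-negative ints
    gene_lengths: pd.Series           # per-gene length in bases
    cna_log2: pd.DataFrame            # genes x patients, real
    clinical: pd.DataFrame            # one row per patient


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _patient_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def _calibrate_censoring(t_event: np.ndarray, rate: float) -> float:
    """Upper bound of the uniform censoring window giving ~`rate` censoring.

    With C ~ U(0, cmax), P(censored) = E[min(T, cmax)] / cmax, which decreases
    monotonically in cmax; solve by bisection on the drawn event times.
    """
    lo, hi = 1e-6, float(t_event.max()) * 50 + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = float(np.minimum(t_event, mid).mean() / mid)
        if p > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_bundle(config: SimConfig) -> tuple[SyntheticBundle, GroundTruth]:
    """Draw one paired-omics cohort with planted subgroups and hazard.

    Fully reproducible: the same ``config`` (including seed) yields a
    bit-identical bundle.
    """
    config.validate()
    n, g, L = config.n_patients, config.n_genes, config.n_latent
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)

    genes = _gene_ids(g)
    patients = _patient_ids(n)

    # --- latent structure ------------------------------------------------
    group = rng.integers(0, 2, size=n)
    z = rng.standard_normal((n, L))
    z[:, 0] += config.group_effect * (group - 0.5)

    # block-sparse loadings: factor j loads only on its own disjoint block;
    # nuisance factors attenuated so the subgroup axis dominates
    block = max(1, g // L)
    load_expr = np.zeros((g, L))
    load_cna = np.zeros((g, L))
    for j in range(L):
        sl = slice(j * block, min((j + 1) * block, g))
        nb = sl.stop - sl.start
        atten = 1.0 if j == 0 else config.nuisance_attenuation
        load_expr[sl, j] = rng.choice([-1.0, 1.0], size=nb) * rng.uniform(0.4, 0.8, size=nb) * atten
        load_cna[sl, j] = rng.choice([-1.0, 1.0], size=nb) * rng.uniform(0.3, 0.6, size=nb) * atten
    causal = frozenset(genes[i] for i in np.flatnonzero(load_expr[:, 0]))

    # --- expression counts (gamma-Poisson = negative binomial) -----------
    baseline = rng.uniform(_BASE_LOG_LO, _BASE_LOG_HI, size=g)
    log_mu = baseline[:, None] + load_expr @ z.T          # genes x patients
    mu = np.exp(np.clip(log_mu, -30, 30))
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    lengths = rng.integers(200, 10001, size=g)

    # --- copy number: same factors, Gaussian noise ------------------------
    cna = load_cna @ z.T + 0.3 * rng.standard_normal((g, n))

    # --- survival ---------------------------------------------------------
    hazard = config.baseline_hazard * np.exp(config.hazard_coef * z[:, 0])
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        cmax = _calibrate_censoring(t_event, config.censor_rate)
        t_cens = rng.uniform(0.0, cmax, size=n)
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_time = t_event
        os_event = np.ones(n, dtype=int)

    # --- clinical table ----------------------------------------------------
    er_flip = rng.random(n) < config.er_flip_prob
    er_group = group ^ er_flip
    er_status = np.where(er_group == 0, "Positive", "Negative")
    age = rng.integers(25, 91, size=n)
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "os_time": np.round(os_time, 1),
            "os_event": os_event,
            "er_status": er_status,
            "pr_status": rng.choice(["Positive", "Negative"], size=n),
            "her2_status": rng.choice(["Positive", "Negative", "Equivocal"], size=n),
            "triple_negative": rng.choice(["Yes", "No"], size=n, p=[0.15, 0.85]),
            "path_T": rng.choice(["T1", "T2", "T3", "T4"], size=n),
            "path_N": rng.choice(["N0", "N1", "N2", "N3"], size=n),
            "path_M": rng.choice(["M0", "M1"], size=n, p=[0.95, 0.05]),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n),
            "subtype": rng.choice(
                ["LumA", "LumB", "Basal", "Her2", "Normal"], size=n
            ),
            "age": age,
            "age_group": np.where(age < 40, "young", "old"),
        }
    )

    # --- source-specific genes ---------------------------------------------
    counts_df = pd.DataFrame(counts, index=genes, columns=patients)
    lengths_s = pd.Series(lengths, index=genes, name="length")
    cna_df = pd.DataFrame(cna, index=genes, columns=patients)
    n_spec = int(round(config.frac_source_specific * g))
    if n_spec:
        spec = rng.permutation(g)[:n_spec]
        expr_only = spec[: n_spec // 2]
        cna_only = spec[n_spec // 2:]
        counts_df = counts_df.drop(index=[genes[i] for i in cna_only])
        lengths_s = lengths_s.drop(index=[genes[i] for i in cna_only])
        cna_df = cna_df.drop(index=[genes[i] for i in expr_only])

    bundle = SyntheticBundle(counts_df, lengths_s, cna_df, clinical)
    truth = GroundTruth(group_label=group, latent_factors=z, causal_genes=causal)
    return bundle, truth


def write_bundle(bundle: SyntheticBundle, truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write bundle + ground truth as tab-separated text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "cna": outdir / "cna_log2.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth_labels": outdir / "truth_labels.tsv",
        "truth_latent": outdir / "truth_latent.tsv",
        "truth_causal": outdir / "truth_causal_genes.txt",
    }
    bundle.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    bundle.gene_lengths.to_frame().to_csv(paths["gene_lengths"], sep="\t", index_label="gene_id")
    bundle.cna_log2.to_csv(paths["cna"], sep="\t", index_label="gene_id", float_format="%.6g")
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    pids = bundle.clinical["patient_id"]
    pd.DataFrame({"patient_id": pids, "group_label": truth.group_label}).to_csv(
        paths["truth_labels"], sep="\t", index=False
    )
    lat = pd.DataFrame(
        truth.latent_factors,
        index=pids,
        columns=[f"z{i + 1}" for i in range(truth.latent_factors.shape[1])],
    )
    lat.to_csv(paths["truth_latent"], sep="\t", index_label="patient_id", float_format="%.6g")
    paths["truth_causal"].write_text("\n".join(sorted(truth.causal_genes)) + "\n")
    return paths


def read_bundle(indir: str | Path) -> SyntheticBundle:
    """Read a bundle previously written by :func:`write_bundle`."""
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="gene_id")
    lengths = pd.read_csv(indir / "gene_lengths.tsv", sep="\t", index_col="gene_id")["length"]
    cna = pd.read_csv(indir / "cna_log2.tsv", sep="\t", index_col="gene_id")
    clinical = pd.read_csv(indir / "clinical.tsv", sep="\t")
    return SyntheticBundle(counts, lengths, cna, clinical)
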