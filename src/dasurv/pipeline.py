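"""End-to-end orchestration: simulate -> preprocess -> train -> analyze.

One global seed deterministically derives per-stage seeds, so the whole run
(and any stage rerun from its inputs) is reproducible.  Every stage writes
its artifacts as tab-separated text under the run directory, and a summary
JSON collects the association table, the risk-score survival contrasts and
the gene-list sizes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as fa
from . import preprocess as pp
from . import survival as sv
from . import trace as tr
from .da import FeatureSet, TrainConfig, train_one_input, train_two_input
from .synthetic import SimConfig, simulate_bundle, write_bundle

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    Defaults: corruption 0.25, SGD learning rate 0.1, batch 64, 100 epochs,
    50% dropout, k = 2 clusters, 55%-quantile risk binarization, gene
    cutoff 0.01, 100 deep features and 1000-unit per-source encodes in the
    two-input model.
    """

    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    noise_factor: float = 0.25
    learning_rate: float = 0.1
    batch_size: int = 64
    epochs: int = 100
    dropout_rate: float = 0.5
    n_features: int = 100
    hidden1: int = 1000
    k: int = 2
    prob: float = 0.55
    cutoff: float = 0.01
    min_cpm: float = 1.0
    min_samples: int = 3
    make_plots: bool = True
    indir: str | None = None        # read bundle from here when simulate=False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg

    def train_config(self, stage_seed: int) -> TrainConfig:
        return TrainConfig(
            noise_factor=self.noise_factor,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            dropout_rate=self.dropout_rate,
            seed=stage_seed,
        )


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Derive per-stage 31-bit seeds from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _write_features(fs: FeatureSet, path: Path) -> None:
    fs.activity.to_csv(path, sep="\t", index_label="patient_id", float_format="%.8g")


def _cox_table(results: list[sv.CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "b": [r.b for r in results],
            "HR": [r.hr for r in results],
            "Lower.95_HR": [r.ci_low for r in results],
            "Upper.95_HR": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
        }
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the machine-readable summary.

    Stages: simulate (optional) -> preprocess -> train three DA models
    (expression, CNA, concatenated) -> cluster patients on the concatenated
    activities -> clinical association tests -> per-feature Cox fits, risk
    scores, 55%-quantile binarization and KM evaluation for each feature set
    -> gene-level trace-back with cutoff filtering and ranked-list export.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "stages": {}}

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.simulate:
        sim = config.sim or SimConfig(seed=seeds[0])
        if config.sim is None:
            log.info("simulate: using default SimConfig with derived seed %d", seeds[0])
        bundle, truth = simulate_bundle(sim)
        write_bundle(bundle, truth, outdir / "input")
        summary["stages"]["simulate"] = {
            "n_patients": sim.n_patients, "n_genes": sim.n_genes, "seed": sim.seed,
        }
    else:
        if not config.indir:
            raise ValueError("simulate=False requires indir")
        from .synthetic import read_bundle

        bundle = read_bundle(config.indir)

    # --- preprocess -------------------------------------------------------
    s_expr, s_cna, clin = pp.preprocess_bundle(
        bundle.counts, bundle.gene_lengths, bundle.cna_log2, bundle.clinical,
        min_cpm=config.min_cpm, min_samples=config.min_samples,
    )
    summary["stages"]["preprocess"] = {
        "n_genes_matched": int(s_expr.values.shape[0]),
        "n_patients": int(s_expr.values.shape[1]),
    }

    # --- train the three models -------------------------------------------
    cfg_e = config.train_config(seeds[1])
    cfg_c = config.train_config(seeds[2])
    cfg_2 = config.train_config(seeds[3])
    model_e, hist_e, feats_e = train_one_input(s_expr, cfg_e, n_features=config.n_features)
    model_c, hist_c, feats_c = train_one_input(s_cna, cfg_c, n_features=config.n_features)
    model_2, hist_2, feats_2 = train_two_input(
        s_expr, s_cna, cfg_2, hidden1=config.hidden1, hidden2=config.n_features
    )
    for tag, fs, hist in (
        ("expression", feats_e, hist_e),
        ("cna", feats_c, hist_c),
        ("concatenated", feats_2, hist_2),
    ):
        _write_features(fs, outdir / f"features_{tag}.tsv")
        summary["stages"][f"train_{tag}"] = {
            "first_epoch_loss": hist[0] if hist else None,
            "final_epoch_loss": hist[-1] if hist else None,
            "epochs": len(hist),
        }

    # --- cluster + associate (concatenated features, per the study design) --
    assign = fa.hier_cluster(feats_2, k=config.k)
    assign.labels.to_csv(outdir / "clusters.tsv", sep="\t", index_label="patient_id")
    assoc = fa.associate_all(assign, clin)
    assoc_df = fa.association_table(assoc)
    assoc_df.to_csv(outdir / "association.tsv", sep="\t", index=False, float_format="%.6g")
    t = clin["os_time"].to_numpy()
    d = clin["os_event"].to_numpy()
    _, lr_stat, lr_p = sv.km_estimate(t, d, assign.labels.to_numpy())
    summary["stages"]["cluster"] = {
        "k": config.k,
        "group_sizes": {str(k_): int(v) for k_, v in assign.sizes().items()},
        "cluster_logrank_p": lr_p,
    }
    summary["stages"]["association"] = {
        r.characteristic: {"fisher_p": r.fisher_p, "chisq_p": r.chisq_p,
                           "odds_ratio": None if np.isnan(r.odds_ratio) else r.odds_ratio}
        for r in assoc
    }
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(truth.group_label, assign.labels.to_numpy())
        summary["stages"]["cluster"]["ari_vs_truth"] = float(ari)
    if config.make_plots:
        fa.heatmap_export(feats_2, assign, clin, outdir)

    # --- risk scoring per feature set ---------------------------------------
    summary["stages"]["risk"] = {}
    profiles = {}
    for tag, fs in (("expression", feats_e), ("cna", feats_c), ("concatenated", feats_2)):
        cox_results = sv.fit_feature_cox(fs, clin)
        _cox_table(cox_results).to_csv(
            outdir / f"cox_features_{tag}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        profile = sv.build_risk_profile(fs, clin, prob=config.prob)
        profiles[tag] = (profile, cox_results)
        pd.DataFrame(
            {"patient_id": profile.scores.index,
             "score": profile.scores.to_numpy(),
             "group": profile.group.to_numpy()}
        ).to_csv(outdir / f"risk_{tag}.tsv", sep="\t", index=False, float_format="%.8g")
        ev = sv.evaluate_risk_groups(profile, clin)
        ev["summary"].to_csv(
            outdir / f"risk_eval_{tag}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        summary["stages"]["risk"][tag] = {
            "HR": ev["score_cox"].hr,
            "Lower.95_HR": ev["score_cox"].ci_low,
            "Upper.95_HR": ev["score_cox"].ci_high,
            "cox_p": ev["score_cox"].p_value,
            "logrank_p": ev["logrank_p"],
            "cutoff": profile.cutoff,
            "n_high": int((profile.group == "high").sum()),
            "n_low": int((profile.group == "low").sum()),
        }
        if config.make_plots:
            _km_plot(profile, clin, outdir / f"km_risk_{tag}.png")

    # --- gene trace-back ----------------------------------------------------
    summary["stages"]["trace"] = {}
    gene_ids = s_expr.gene_ids
    for tag, model, cox_results in (
        ("expression", model_e, profiles["expression"][1]),
        ("cna", model_c, profiles["cna"][1]),
    ):
        B = np.array([r.b for r in cox_results])
        gwv = tr.trace_one_input(model.W, B, gene_ids, tag)
        gl = tr.filter_genes(gwv, cutoff=config.cutoff)
        tr.export_gene_list(gl, outdir / f"genes_{tag}.txt")
        summary["stages"]["trace"][tag] = {"n_genes": len(gl), "cutoff": config.cutoff}
    B2 = np.array([r.b for r in profiles["concatenated"][1]])
    gwv_a, gwv_b = tr.trace_two_input(
        model_2.W1_a, model_2.W1_b, model_2.W2, B2, gene_ids, gene_ids
    )
    gwv_cc = tr.combine_two_sided(gwv_a, gwv_b)
    gl_cc = tr.filter_genes(gwv_cc, cutoff=config.cutoff)
    tr.export_gene_list(gl_cc, outdir / "genes_concatenated.txt")
    summary["stages"]["trace"]["concatenated"] = {
        "n_genes": len(gl_cc), "cutoff": config.cutoff,
    }

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _km_plot(profile: sv.RiskProfile, clinical: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    clin = clin.loc[profile.scores.index]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for grp, color in (("high", "tab:red"), ("low", "tab:blue")):
        sel = (profile.group == grp).to_numpy()
        if sel.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(clin["os_time"][sel], clin["os_event"][sel], label=f"{grp} risk")
        kmf.plot_survival_function(ax=ax, color=color)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("overall survival")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
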