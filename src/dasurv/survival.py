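"""Survival analysis: KM curves, per-feature Cox fits, risk scores.

The proportional-hazards model h(t) = h0(t) * exp(b*x) is fitted per deep
feature by maximizing the Breslow partial likelihood with Newton-Raphson
(the single-covariate score and information have closed forms, so the fit
is a few scalar iterations).  The per-feature coefficients b_i weight the
activity values into a patient-level risk score r = sum_i b_i * a_i, which
is binarized at an empirical quantile (55% by default) into high- and
low-risk groups; group survival is compared with Kaplan-Meier curves and
the log-rank test (via lifelines).

Ties are handled with the Breslow approximation; activities are continuous
so ties are rare.  The Wald confidence interval is exp(b +/- 1.96*se).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .da import FeatureSet

__all__ = [
    "CoxResult",
    "RiskProfile",
    "km_estimate",
    "cox_univariate",
    "fit_feature_cox",
    "risk_score",
    "binarize_risk",
    "build_risk_profile",
    "evaluate_risk_groups",
]

log = logging.getLogger(__name__)

_B_CAP = 50.0      # |b| beyond this flags a monotone partial likelihood
                   # (activities have tiny scale, so finite MLEs can be large)
_TOL = 1e-8
_MAX_ITER = 50


@dataclass
class CoxResult:
    """Univariate proportional-hazards fit for one covariate."""

    feature_id: str
    b: float                 # log hazard ratio
    se: float
    hr: float                # exp(b)
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    converged: bool = True
    flagged: bool = False    # monotone likelihood / degenerate covariate


@dataclass
class RiskProfile:
    """Cox-coefficient-weighted risk scores and their binarization."""

    coefficients: pd.Series   # feature_id -> b
    scores: pd.Series         # patient_id -> r
    cutoff: float
    group: pd.Series          # patient_id -> {"high", "low"}
    prob: float


def _breslow_parts(b, x, order_first, events_idx, x_sorted):
    """Score/information pieces at coefficient b.

    ``x_sorted`` is the covariate sorted by ascending time; ``order_first``
    maps each sorted position to the first position sharing its time (so
    tied events share a risk set); ``events_idx`` are sorted positions of
    events.
    """
    eta = np.clip(b * x_sorted, -500, 500)
    w = np.exp(eta)
    # suffix sums: risk set of position i is [first(t_i):]
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * x_sorted)[::-1])[::-1]
    s2 = np.cumsum((w * x_sorted ** 2)[::-1])[::-1]
    j = order_first[events_idx]
    r0, r1, r2 = s0[j], s1[j], s2[j]
    ll = float(np.sum(b * x_sorted[events_idx] - np.log(r0)))
    mean = r1 / r0
    score = float(np.sum(x_sorted[events_idx] - mean))
    info = float(np.sum(r2 / r0 - mean ** 2))
    return ll, score, info


def cox_univariate(
    covariate: np.ndarray | pd.Series,
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    feature_id: str = "x",
) -> CoxResult:
    """Newton-Raphson maximum partial likelihood for a single covariate.

    Breslow tie handling; convergence when the step falls below 1e-8 or
    after 50 iterations.  A constant covariate carries no information and
    returns b = 0, HR = 1 with an infinite standard error; a monotone
    likelihood (perfect separation) is flagged and |b| capped.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if not (len(x) == len(t) == len(d)):
        raise ValueError("covariate, times and events must have equal length")
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events: partial likelihood is undefined")

    xm = x - x.mean()          # b is shift-invariant; centering stabilizes exp
    order = np.argsort(t, kind="stable")
    t_sorted, x_sorted, d_sorted = t[order], xm[order], d[order]
    # first sorted position sharing each time value (tied risk sets)
    first = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        first[i] = first[i - 1] if t_sorted[i] == t_sorted[i - 1] else i
    events_idx = np.flatnonzero(d_sorted == 1)

    if np.ptp(xm) == 0:
        return CoxResult(feature_id, 0.0, np.inf, 1.0, 0.0, np.inf, 1.0,
                         n_events, converged=True, flagged=True)

    b = 0.0
    converged = False
    flagged = False
    ll, score, info = _breslow_parts(b, xm, first, events_idx, x_sorted)
    for _ in range(_MAX_ITER):
        if info <= 0:
            flagged = True
            break
        step = score / info
        # step-halving line search on the partial log-likelihood
        for _ in range(30):
            ll_new, score_new, info_new = _breslow_parts(
                b + step, xm, first, events_idx, x_sorted
            )
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        b += step
        ll, score, info = ll_new, score_new, info_new
        if abs(b) > _B_CAP:
            b = np.sign(b) * _B_CAP
            ll, score, info = _breslow_parts(b, xm, first, events_idx, x_sorted)
            flagged = True
            log.warning("cox_univariate[%s]: monotone likelihood, |b| capped", feature_id)
            break
        if abs(step) < _TOL:
            converged = True
            break

    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    hr = float(np.exp(b))
    if np.isfinite(se):
        ci_low, ci_high = float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))
        p = float(2 * norm.sf(abs(b) / se))
    else:
        ci_low, ci_high, p = 0.0, np.inf, 1.0
    return CoxResult(feature_id, float(b), float(se), hr, ci_low, ci_high, p,
                     n_events, converged, flagged)


def fit_feature_cox(
    features: FeatureSet | pd.DataFrame,
    clinical: pd.DataFrame,
    joint: bool = False,
    ridge: float = 0.1,
) -> list[CoxResult]:
    """Cox coefficient per deep feature.

    Default: one univariate fit per feature column (coefficients are the
    marginal log hazard ratios).  With ``joint=True`` a single multivariate
    ridge-penalized fit (via lifelines) supplies all coefficients at once;
    the penalty stabilizes the many-covariate fit.
    """
    activity = features.activity if isinstance(features, FeatureSet) else features
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    clin = clin.loc[activity.index]
    t = clin["os_time"].to_numpy(dtype=float)
    d = clin["os_event"].to_numpy(dtype=int)
    if joint:
        from lifelines import CoxPHFitter

        df = activity.copy()
        df["os_time"], df["os_event"] = t, d
        cph = CoxPHFitter(penalizer=ridge, l1_ratio=0.0)
        cph.fit(df, duration_col="os_time", event_col="os_event")
        out = []
        for fid in activity.columns:
            b = float(cph.params_[fid])
            se = float(cph.standard_errors_[fid])
            out.append(CoxResult(
                fid, b, se, float(np.exp(b)),
                float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)),
                float(2 * norm.sf(abs(b) / se)) if se > 0 else 1.0,
                int(d.sum()),
            ))
        return out
    return [
        cox_univariate(activity[fid].to_numpy(), t, d, feature_id=str(fid))
        for fid in activity.columns
    ]


def risk_score(
    features: FeatureSet | pd.DataFrame,
    cox_results: list[CoxResult] | pd.Series | np.ndarray,
) -> pd.Series:
    """Per-patient risk score r = sum_i b_i * a_i."""
    activity = features.activity if isinstance(features, FeatureSet) else features
    if isinstance(cox_results, list):
        coef = pd.Series({r.feature_id: r.b for r in cox_results})
        coef = coef.reindex(activity.columns)
        if coef.isna().any():
            raise ValueError("cox_results do not cover every feature column")
    else:
        coef = pd.Series(np.asarray(cox_results, dtype=float), index=activity.columns) \
            if not isinstance(cox_results, pd.Series) else cox_results.reindex(activity.columns)
        if len(coef) != activity.shape[1] or coef.isna().any():
            raise ValueError("one coefficient per feature column is required")
    scores = activity.to_numpy(dtype=float) @ coef.to_numpy(dtype=float)
    return pd.Series(scores, index=activity.index, name="risk_score")


def binarize_risk(scores: pd.Series, prob: float = 0.55) -> tuple[float, pd.Series]:
    """Split patients at the empirical `prob` quantile of their scores.

    Linear-interpolation quantile; score > cutoff is high-risk, ties at the
    cutoff go to low-risk.  All-identical scores are an error.
    """
    if not 0 < prob < 1:
        raise ValueError("prob must lie in (0, 1)")
    vals = np.asarray(scores, dtype=float)
    if np.unique(vals).size < 2:
        raise ValueError("risk scores are all identical; cannot binarize")
    cutoff = float(np.quantile(vals, prob))
    group = pd.Series(
        np.where(vals > cutoff, "high", "low"), index=scores.index, name="risk_group"
    )
    return cutoff, group


def build_risk_profile(
    features: FeatureSet,
    clinical: pd.DataFrame,
    prob: float = 0.55,
    joint: bool = False,
) -> RiskProfile:
    """Fit per-feature Cox models, score patients, binarize at `prob`."""
    results = fit_feature_cox(features, clinical, joint=joint)
    coef = pd.Series({r.feature_id: r.b for r in results})
    scores = risk_score(features, results)
    cutoff, group = binarize_risk(scores, prob)
    return RiskProfile(coef, scores, cutoff, group, prob)


def km_estimate(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
) -> tuple[dict, float, float]:
    """Kaplan-Meier survival curve per group plus the log-rank test.

    Returns ({group: survival Series indexed by time}, statistic, p).  With
    no events anywhere the log-rank test is undefined; it is reported as
    statistic 0, p = 1 with a warning.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    groups = pd.unique(g)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    curves: dict = {}
    for grp in groups:
        sel = g == grp
        if sel.sum() == 0:
            raise ValueError(f"group {grp!r} has no patients")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], d[sel], label=str(grp))
        curves[grp] = kmf.survival_function_.iloc[:, 0]
    if d.sum() == 0:
        log.warning("km_estimate: no events; log-rank test undefined, p set to 1")
        return curves, 0.0, 1.0
    if len(groups) == 2:
        a, b = groups
        res = logrank_test(t[g == a], t[g == b], d[g == a], d[g == b])
    else:
        res = multivariate_logrank_test(t, g, d)
    stat, p = float(res.test_statistic), float(res.p_value)
    if not np.isfinite(stat):
        log.warning("km_estimate: degenerate log-rank; reporting p = 1")
        stat, p = 0.0, 1.0
    return curves, stat, p


def evaluate_risk_groups(
    profile: RiskProfile, clinical: pd.DataFrame
) -> dict:
    """Survival contrast of the high/low-risk split plus the score's own HR.

    Produces a summary with the per-group KM curves, the log-rank statistic
    and p, and a univariate Cox fit of the continuous risk score (HR with
    95% CI and Wald p).
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    clin = clin.loc[profile.scores.index]
    t = clin["os_time"].to_numpy(dtype=float)
    d = clin["os_event"].to_numpy(dtype=int)
    curves, stat, p = km_estimate(t, d, profile.group.to_numpy())
    cox = cox_univariate(profile.scores.to_numpy(), t, d, feature_id="risk_score")
    return {
        "km_curves": curves,
        "logrank_statistic": stat,
        "logrank_p": p,
        "score_cox": cox,
        "summary": pd.DataFrame(
            [{
                "risk_score": "continuous",
                "HR": cox.hr,
                "Lower.95_HR": cox.ci_low,
                "Upper.95_HR": cox.ci_high,
                "p_value": cox.p_value,
                "logrank_p_high_vs_low": p,
                "n_high": int((profile.group == "high").sum()),
                "n_low": int((profile.group == "low").sum()),
            }]
        ),
    }
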