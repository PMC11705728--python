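"""TRIUNE integrated risk score and its subgroup analyses.

TRIUNE (inTegrated covaRIates and foUr-way iNtEraction score) is the
linear predictor of the fitted four-way interaction Cox model: the
weighted sum of all clinical covariates, the exposure and probe main
effects, and every configured interaction product, with weights taken
from the fitted model. The clinical comparator score is the linear
predictor of a covariates-only Cox model. Patients are grouped by score
quartiles (Group 1 = lowest risk) for Kaplan-Meier comparison, marginal
group hazard ratios, and clinical-factor-stratified forest analyses.

Note: scoring the same samples the weights were estimated on is an
in-sample analysis and inherits its optimism; use ``compute_triune``
with a fit from an independent cohort for honest out-of-sample scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .cox import Z95, CoxFit, fit_cox
from .terms import DEFAULT_COVARIATES, ModelSpec, build_design, encode_covariates

__all__ = [
    "compute_triune",
    "clinical_score",
    "quartile_groups",
    "risk_scores",
    "KMCurve",
    "km_curve",
    "group_hazard_ratios",
    "stratified_forest",
    "conditional_effect_surface",
]


def compute_triune(
    fit: CoxFit, cohort: pd.DataFrame, beta: pd.DataFrame, spec: ModelSpec
) -> pd.Series:
    """Per-sample integrated score = the fitted model's linear predictor.

    Exactly ``sum_i alpha_i * covariate_i + sum beta_S * prod(term S)``
    over the fitted term scheme; no intercept or baseline-hazard term.
    """
    design = build_design(cohort, beta, spec)
    lp = fit.linear_predictor(design)
    return pd.Series(lp, index=cohort.index, name="triune")


def clinical_score(
    cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES, strata: str = "histology"
) -> tuple[pd.Series, CoxFit]:
    """Covariates-only Cox linear predictor (the clinical comparator)."""
    design = encode_covariates(cohort, covariates)
    fit = fit_cox(
        cohort["time"].to_numpy(),
        cohort["event"].to_numpy(),
        design,
        strata=cohort[strata].to_numpy() if strata else None,
    )
    return pd.Series(fit.linear_predictor(design), index=cohort.index, name="clinical_score"), fit


def quartile_groups(scores) -> np.ndarray:
    """Quartile group labels 1-4 (1 = lowest quarter of the score).

    Cutoffs are the empirical 25/50/75 percentiles; values equal to a
    cutoff go to the lower group, so the grouping is deterministic under
    ties and groups are equal-sized when n % 4 == 0 and scores are
    distinct.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 4:
        raise ValueError("need at least 4 samples for quartile groups")
    if np.all(s == s[0]):
        raise ValueError("all scores identical; quartile groups undefined")
    q1, q2, q3 = np.quantile(s, [0.25, 0.5, 0.75])
    return (1 + (s > q1).astype(int) + (s > q2).astype(int) + (s > q3).astype(int))


def risk_scores(
    fit: CoxFit,
    cohort: pd.DataFrame,
    beta: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """TRIUNE and clinical scores with their quartile groups."""
    triune = compute_triune(fit, cohort, beta, spec)
    clin, _ = clinical_score(cohort, spec.covariates, spec.strata)
    return pd.DataFrame(
        {
            "triune": triune,
            "clinical_score": clin,
            "group": quartile_groups(triune.to_numpy()),
            "clinical_group": quartile_groups(clin.to_numpy()),
        },
        index=cohort.index,
    )


@dataclass
class KMCurve:
    """Product-limit estimate with at-risk counts and median survival."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: Optional[float]
    median_ci: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier curve with Brookmeyer-Crowley-style median CI.

    The median is the smallest time with S(t) <= 0.5 (absent when the
    curve never reaches 0.5); its CI comes from where the log-log
    confidence band crosses 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_.iloc[:, 0]
    grid = sf.index.to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    )
    if events.sum() == 0:
        median, ci = None, (None, None)
    else:
        med = kmf.median_survival_time_
        median = None if np.isinf(med) else float(med)
        ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
        ci = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)
    return KMCurve(times=grid, survival=sf.to_numpy(), at_risk=at_risk, median=median, median_ci=ci)


def group_hazard_ratios(
    cohort: pd.DataFrame, groups, *, adjust_covariates=None, strata: str | None = None
) -> pd.DataFrame:
    """Cox hazard ratios of Groups 2-4 versus Group 1.

    Marginal (covariate-free) by default; pass ``adjust_covariates`` for
    an adjusted variant. Groups with zero events get an ``unstable``
    flag on their row.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels[0] != 1:
        raise ValueError("Group 1 (reference) must be present")
    ev = cohort["event"].to_numpy()
    if ev[groups == 1].sum() < 1:
        raise ValueError("reference Group 1 has no events")
    design = pd.DataFrame(index=cohort.index)
    for g in levels[1:]:
        design[f"group_{g}"] = (groups == g).astype(float)
    if adjust_covariates:
        design = pd.concat([design, encode_covariates(cohort, adjust_covariates)], axis=1)
    fit = fit_cox(
        cohort["time"].to_numpy(),
        cohort["event"].to_numpy(),
        design,
        strata=cohort[strata].to_numpy() if strata else None,
    )
    rows = []
    for g in levels[1:]:
        i = fit._idx(f"group_{g}")
        b, se = float(fit.beta[i]), float(fit.se[i])
        rows.append(
            {
                "group": int(g),
                "n": int((groups == g).sum()),
                "events": int(ev[groups == g].sum()),
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - Z95 * se)),
                "ci_high": float(np.exp(b + Z95 * se)),
                "p": float(fit.p[i]),
                "unstable": bool(ev[groups == g].sum() == 0),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def stratified_forest(
    cohort: pd.DataFrame,
    scores,
    strata_factors,
    *,
    min_n: int = 10,
    min_events: int = 3,
) -> pd.DataFrame:
    """Per-stratum hazard ratio of the score (per 1 SD) on survival.

    ``strata_factors`` maps a factor name to a cohort column (or an
    aligned array of labels); within each level a univariate Cox model
    of the standardized score is fitted. Strata below ``min_n`` samples
    or ``min_events`` events are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    if sd == 0:
        raise ValueError("score is constant")
    z = scores / sd  # per-1-SD unit
    rows = []
    for factor, labels in strata_factors.items():
        lab = cohort[labels].to_numpy() if isinstance(labels, str) else np.asarray(labels)
        for level in pd.unique(lab):
            mask = lab == level
            n = int(mask.sum())
            events = int(cohort["event"].to_numpy()[mask].sum())
            if n < min_n or events < min_events:
                warnings.warn(
                    f"skipping stratum {factor}={level!r}: n={n}, events={events}"
                )
                continue
            design = pd.DataFrame({"score_sd": z[mask]}, index=cohort.index[mask])
            fit = fit_cox(
                cohort["time"].to_numpy()[mask],
                cohort["event"].to_numpy()[mask],
                design,
            )
            b, se = float(fit.beta[0]), float(fit.se[0])
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "n": n,
                    "events": events,
                    "hr_per_sd": float(np.exp(b)),
                    "ci_low": float(np.exp(b - Z95 * se)),
                    "ci_high": float(np.exp(b + Z95 * se)),
                    "p": float(fit.p[0]),
                }
            )
    return pd.DataFrame(rows)


def conditional_effect_surface(
    fit: CoxFit,
    spec: ModelSpec,
    exposure_grid,
    g1_grid,
    g2_levels: dict,
) -> pd.DataFrame:
    """Model-implied conditional effect of the scanned probe X.

    For the order-4 scheme with variables (E, G1, G2, X), the log hazard
    ratio of X per 1 percentage point at covariate values (E, g1, g2) is
    the sum of every fitted X-bearing term's coefficient times the
    product of its other variables:

        beta_X + beta_EX*E + beta_G1X*g1 + beta_G2X*g2 + beta_EG1X*E*g1
        [+ beta_EG2X*E*g2] + beta_G1G2X*g1*g2 + beta_EG1G2X*E*g1*g2

    (the bracketed term is absent under the ``as_printed`` scheme).
    ``g2_levels`` maps a subgroup label (e.g. "low"/"high", split at the
    G2 median) to the percent-scale G2 value the surface is evaluated
    at. Grids are on the scales used in fitting (pack-years; percent
    methylation).
    """
    if spec.order < 2:
        raise ValueError("spec must contain interaction terms")
    variables = spec.variables
    x_var = variables[-1]
    rows = []
    for label, g2_val in g2_levels.items():
        for e_val in np.asarray(exposure_grid, dtype=float):
            for g1_val in np.asarray(g1_grid, dtype=float):
                values = {variables[0]: e_val, variables[1]: g1_val}
                if spec.order >= 4:
                    values[variables[2]] = float(g2_val)
                log_hr = 0.0
                for term in fit.terms:
                    parts = tuple(term.split(":"))
                    if x_var not in parts or not set(parts) <= set(variables):
                        continue
                    contrib = fit.coef(term)
                    for v in parts:
                        if v != x_var:
                            contrib *= values[v]
                    log_hr += contrib
                rows.append(
                    {
                        "g2_subgroup": label,
                        "exposure": e_val,
                        "g1": g1_val,
                        "log_hr": log_hr,
                        "hr": float(np.exp(log_hr)),
                    }
                )
    return pd.DataFrame(rows)
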