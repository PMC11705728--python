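"""Epigenome-wide hill-climbing scan for high-order gene-smoking
interactions under the two-phase discovery/validation design.

``scan_order_k`` fits, for every candidate probe X, the stratified Cox
model whose linear predictor contains the clinical covariates plus the
full interaction hierarchy over {exposure, fixed probes, X}; the Wald
test of the single highest-order product term is recorded and
Benjamini-Hochberg adjusted across candidates. ``two_phase_decide``
re-tests discovery hits (FDR-q <= 0.05) in an independent validation
cohort at P <= 0.05 with a matching effect direction, then refits
passers on the pooled cohort. ``hill_climb`` escalates the interaction
order greedily, appending the best validated probe at each order.

Candidate fits that do not converge are recorded with a missing p-value
and excluded from the multiplicity correction (their count is kept in
the table metadata).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cox import Z95, CoxFit, SingularDesignError, SurvivalData, fit_cox
from .stats import bh_adjust
from .terms import (
    DEFAULT_COVARIATES,
    ModelSpec,
    build_design,
    encode_covariates,
    expand_terms,
    term_name,
)

__all__ = ["scan_order_k", "two_phase_decide", "hill_climb", "fit_interaction_model"]


def fit_interaction_model(
    cohort: pd.DataFrame,
    beta: pd.DataFrame,
    exposure: str,
    probes,
    *,
    covariates=DEFAULT_COVARIATES,
    strata: str = "histology",
    scheme: str = "full_factorial",
    ties: str = "efron",
    start=None,
    survival_data: SurvivalData | None = None,
    check_design: bool = True,
) -> tuple[CoxFit, ModelSpec]:
    """Convenience wrapper: build the factorial design and fit it."""
    spec = ModelSpec(
        exposure=exposure,
        probes=tuple(probes),
        covariates=tuple(covariates),
        strata=strata,
        scheme=scheme,
        ties=ties,
    )
    design = build_design(cohort, beta, spec)
    sd = survival_data or SurvivalData(
        cohort["time"].to_numpy(), cohort["event"].to_numpy(), cohort[strata].to_numpy()
    )
    fit = fit_cox(
        None,
        None,
        design,
        ties=ties,
        start=start,
        survival_data=sd,
        check_design=check_design,
    )
    return fit, spec


def _scan_matrices(cohort, beta, exposure, fixed_probes, covariates, scheme):
    """Precompute the per-candidate design layout.

    Returns (column names, fixed column block, list of subset index
    tuples for the X-bearing products, insertion positions of those
    products in the canonical column order).
    """
    spec = ModelSpec(
        exposure=exposure,
        probes=tuple(fixed_probes) + ("__X__",),
        covariates=tuple(covariates),
        scheme=scheme,
    )
    cov_block = encode_covariates(cohort, covariates)
    base_vars = {exposure: cohort[exposure].to_numpy(dtype=float)}
    for p in fixed_probes:
        if p not in beta.index:
            raise KeyError(f"fixed probe {p!r} missing from beta matrix")
        base_vars[p] = beta.loc[p].reindex(cohort.index).to_numpy(dtype=float) * 100.0
    terms = expand_terms(spec)
    names = list(cov_block.columns) + [term_name(t) for t in terms]
    n = len(cohort)
    n_cov = cov_block.shape[1]
    fixed_cols = {}
    x_slots = []  # (column position, tuple of non-X variable names)
    for j, t in enumerate(terms):
        pos = n_cov + j
        if "__X__" in t:
            others = tuple(v for v in t if v != "__X__")
            x_slots.append((pos, others))
        else:
            col = np.ones(n)
            for v in t:
                col = col * base_vars[v]
            fixed_cols[pos] = col
    X0 = np.zeros((n, n_cov + len(terms)))
    X0[:, :n_cov] = cov_block.to_numpy(dtype=float)
    for pos, col in fixed_cols.items():
        X0[:, pos] = col
    # partial products for X-bearing terms (product over non-X variables)
    partials = {}
    for _, others in x_slots:
        if others not in partials:
            col = np.ones(n)
            for v in others:
                col = col * base_vars[v]
            partials[others] = col
    top_term = term_name(tuple(spec.variables))
    return names, X0, x_slots, partials, top_term


def scan_order_k(
    cohort: pd.DataFrame,
    beta: pd.DataFrame,
    exposure: str,
    fixed_probes,
    *,
    candidates=None,
    covariates=DEFAULT_COVARIATES,
    strata: str = "histology",
    scheme: str = "full_factorial",
    ties: str = "efron",
    warm_start: bool = True,
) -> pd.DataFrame:
    """Scan all candidate probes for the order-k slot.

    k = len(fixed_probes) + 2 (exposure, fixed probes, candidate). For
    each candidate the highest-order product term's Wald estimate, SE,
    HR with 95% CI, and p-value are recorded; q is the BH adjustment
    over converged candidate fits. Rows are ordered by ascending p (rank
    1 = strongest signal). Table metadata lives in ``DataFrame.attrs``.
    """
    fixed_probes = tuple(fixed_probes)
    if candidates is None:
        candidates = [p for p in beta.index if p not in fixed_probes]
    else:
        candidates = [p for p in candidates if p not in fixed_probes]
    if len(candidates) == 0:
        raise ValueError("empty candidate probe set")
    expo = cohort[exposure].to_numpy(dtype=float)
    if np.all(expo == expo[0]):
        raise ValueError(f"exposure {exposure!r} is constant")

    names, X0, x_slots, partials, top_term = _scan_matrices(
        cohort, beta, exposure, fixed_probes, covariates, scheme
    )
    sd = SurvivalData(
        cohort["time"].to_numpy(), cohort["event"].to_numpy(), cohort[strata].to_numpy()
    )
    top_idx = names.index(top_term)

    start = None
    if warm_start:
        # fit the reduced model (X-terms zeroed out) once for a warm start
        x_positions = [pos for pos, _ in x_slots]
        keep = [j for j in range(len(names)) if j not in x_positions]
        reduced = pd.DataFrame(X0[:, keep], columns=[names[j] for j in keep], index=cohort.index)
        try:
            base_fit = fit_cox(None, None, reduced, survival_data=sd, ties=ties)
            start = np.zeros(len(names))
            start[keep] = base_fit.beta
        except (SingularDesignError, np.linalg.LinAlgError):
            start = None

    beta_vals = beta.to_numpy(dtype=float)
    beta_pos = {p: i for i, p in enumerate(beta.index)}
    col_order = list(cohort.index)
    if list(beta.columns) != col_order:
        beta_vals = beta.reindex(columns=cohort.index).to_numpy(dtype=float)

    rows = []
    n_failed = 0
    X = X0.copy()
    for probe in candidates:
        x = beta_vals[beta_pos[probe]] * 100.0
        for pos, others in x_slots:
            X[:, pos] = partials[others] * x
        design = pd.DataFrame(X, columns=names, index=cohort.index)
        rec = {"probe": probe}
        try:
            fit = fit_cox(
                None,
                None,
                design,
                ties=ties,
                survival_data=sd,
                start=start,
                check_design=False,
            )
            ok = fit.converged and "pinv_covariance" not in fit.flags
        except (SingularDesignError, np.linalg.LinAlgError, ValueError):
            ok = False
            fit = None
        if fit is not None:
            i = top_idx
            b, se = float(fit.beta[i]), float(fit.se[i])
            rec.update(
                beta=b,
                se=se,
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * se)),
                ci_high=float(np.exp(b + Z95 * se)),
                p=float(fit.p[i]) if ok and se > 0 else np.nan,
                converged=ok,
            )
        else:
            rec.update(
                beta=np.nan, se=np.nan, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                p=np.nan, converged=False,
            )
        if not rec["converged"]:
            n_failed += 1
        rows.append(rec)

    table = pd.DataFrame(rows).set_index("probe")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values("p", kind="stable", na_position="last")
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs.update(
        k=len(fixed_probes) + 2,
        exposure=exposure,
        fixed_probes=list(fixed_probes),
        scheme=scheme,
        n_tested=int(table["converged"].sum()),
        n_failed=n_failed,
        top_term_template=top_term,
    )
    return table


def _combined_cohort(cohort_disc: pd.DataFrame, cohort_valid: pd.DataFrame):
    """Pool the phases; the phase indicator is folded into the center
    block (each validation center becomes its own combined-level)."""
    a = cohort_disc.copy()
    b = cohort_valid.copy()
    a["center"] = "disc_" + a["center"].astype(str)
    b["center"] = "valid_" + b["center"].astype(str)
    return pd.concat([a, b], axis=0)


def two_phase_decide(
    discovery: pd.DataFrame,
    cohort_valid: pd.DataFrame,
    beta_valid: pd.DataFrame,
    *,
    cohort_disc: pd.DataFrame | None = None,
    beta_disc: pd.DataFrame | None = None,
    q_threshold: float = 0.05,
    p_threshold: float = 0.05,
    covariates=DEFAULT_COVARIATES,
    strata: str = "histology",
    scheme: str = "full_factorial",
    ties: str = "efron",
) -> pd.DataFrame:
    """Apply the two-phase rule to a discovery scan table.

    pass <=> q_disc <= 0.05 AND p_valid <= 0.05 AND sign(beta_disc) ==
    sign(beta_valid). Probes absent from the validation beta matrix are
    recorded as untestable (never passed). When both phase cohorts are
    supplied, passers are refit on the pooled data with the phase folded
    into the center covariate block.
    """
    exposure = discovery.attrs["exposure"]
    fixed = tuple(discovery.attrs["fixed_probes"])
    hits = discovery[discovery["q"] <= q_threshold]
    rows = []
    for probe, hit in hits.iterrows():
        rec = {
            "probe": probe,
            "beta_disc": hit["beta"],
            "p_disc": hit["p"],
            "q_disc": hit["q"],
            "beta_valid": np.nan,
            "p_valid": np.nan,
            "direction_consistent": False,
            "untestable": False,
            "passed": False,
            "beta_comb": np.nan,
            "hr_comb": np.nan,
            "ci_low_comb": np.nan,
            "ci_high_comb": np.nan,
            "p_comb": np.nan,
        }
        if probe not in beta_valid.index:
            rec["untestable"] = True
            rows.append(rec)
            continue
        try:
            fit_v, spec_v = fit_interaction_model(
                cohort_valid,
                beta_valid,
                exposure,
                fixed + (probe,),
                covariates=covariates,
                strata=strata,
                scheme=scheme,
                ties=ties,
            )
            top = term_name(spec_v.variables)
            i = fit_v._idx(top)
            rec["beta_valid"] = float(fit_v.beta[i])
            rec["p_valid"] = float(fit_v.p[i])
        except (SingularDesignError, np.linalg.LinAlgError, ValueError):
            rec["untestable"] = True
            rows.append(rec)
            continue
        rec["direction_consistent"] = bool(
            np.sign(rec["beta_disc"]) == np.sign(rec["beta_valid"])
        )
        rec["passed"] = bool(
            rec["p_valid"] <= p_threshold and rec["direction_consistent"]
        )
        if rec["passed"] and cohort_disc is not None and beta_disc is not None:
            shared = [p for p in beta_disc.index if p in beta_valid.index]
            comb_cohort = _combined_cohort(cohort_disc, cohort_valid)
            if comb_cohort.index.duplicated().any():
                raise ValueError("sample ids overlap between phases")
            comb_beta = pd.concat(
                [beta_disc.loc[shared], beta_valid.loc[shared]], axis=1
            )
            fit_c, spec_c = fit_interaction_model(
                comb_cohort,
                comb_beta,
                exposure,
                fixed + (probe,),
                covariates=covariates,
                strata=strata,
                scheme=scheme,
                ties=ties,
            )
            top = term_name(spec_c.variables)
            i = fit_c._idx(top)
            b, se = float(fit_c.beta[i]), float(fit_c.se[i])
            rec.update(
                beta_comb=b,
                hr_comb=float(np.exp(b)),
                ci_low_comb=float(np.exp(b - Z95 * se)),
                ci_high_comb=float(np.exp(b + Z95 * se)),
                p_comb=float(fit_c.p[i]),
            )
        rows.append(rec)
    cols = [
        "probe", "beta_disc", "p_disc", "q_disc", "beta_valid", "p_valid",
        "direction_consistent", "untestable", "passed",
        "beta_comb", "hr_comb", "ci_low_comb", "ci_high_comb", "p_comb",
    ]
    out = pd.DataFrame(rows, columns=cols).set_index("probe")
    out.attrs.update(discovery.attrs)
    out.attrs.update(q_threshold=q_threshold, p_threshold=p_threshold)
    return out


def hill_climb(
    cohort_disc: pd.DataFrame,
    beta_disc: pd.DataFrame,
    cohort_valid: pd.DataFrame,
    beta_valid: pd.DataFrame,
    exposure: str,
    *,
    max_order: int = 4,
    initial_winners=(),
    covariates=DEFAULT_COVARIATES,
    strata: str = "histology",
    scheme: str = "full_factorial",
    ties: str = "efron",
    q_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> dict:
    """Greedy order escalation from two-way to ``max_order``-way.

    Starting from ``initial_winners`` (probes fixed from prior studies),
    each round scans every remaining probe for the next interaction
    slot, applies the two-phase rule, and appends the passer with the
    smallest discovery p. Stops early when no probe passes. Returns the
    winner list plus the per-order scan tables and decisions as an audit
    trail.
    """
    if max_order < 2:
        raise ValueError("max_order must be >= 2")
    winners = list(initial_winners)
    audit = {"winners": winners, "orders": {}}
    for k in range(len(winners) + 2, max_order + 1):
        scan = scan_order_k(
            cohort_disc,
            beta_disc,
            exposure,
            winners,
            covariates=covariates,
            strata=strata,
            scheme=scheme,
            ties=ties,
        )
        decisions = two_phase_decide(
            scan,
            cohort_valid,
            beta_valid,
            cohort_disc=cohort_disc,
            beta_disc=beta_disc,
            q_threshold=q_threshold,
            p_threshold=p_threshold,
            covariates=covariates,
            strata=strata,
            scheme=scheme,
            ties=ties,
        )
        audit["orders"][k] = {"scan": scan, "decisions": decisions}
        passers = decisions[decisions["passed"]]
        if len(passers) == 0:
            break
        winner = passers["p_disc"].idxmin()  # tie-break: smallest discovery p
        winners.append(winner)
    audit["winners"] = winners
    return audit
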