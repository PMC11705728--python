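"""Methylation-expression cis-regulation and the gene-level interaction.

A probe is a cis-regulation (eQTM) candidate for a gene when it lies
within a 1 kb window of the gene-body interval and its methylation is
significantly (P <= 0.05) associated with the gene's expression in a
covariate-adjusted linear model. Candidate gene triples are then
re-tested for the four-way gene-smoking interaction at the expression
level with the same factorial Cox machinery, using standardized
expression values in place of percent-scale methylation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cox import CoxFit, fit_cox
from .stats import bh_adjust
from .terms import DEFAULT_COVARIATES, ModelSpec, encode_covariates, expand_terms, term_name

__all__ = [
    "methylation_expression_correlation",
    "cis_candidates",
    "expression_level_interaction",
]


def methylation_expression_correlation(
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    cohort: pd.DataFrame,
    *,
    probes=None,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Covariate-adjusted linear association of probe methylation with
    gene expression, one row per (probe, gene) pair.

    Fits ``expression ~ methylation + covariates`` by OLS on the shared
    samples; reports the methylation slope (per unit beta on the [0,1]
    scale), its t-test p-value, the partial correlation implied by the
    t statistic, and BH q-values over all tested pairs. By default only
    the probes involved in the integrated score are tested against all
    genes (pass ``probes``); covariates may be empty for a plain
    correlation.
    """
    shared = [s for s in cohort.index if s in beta.columns and s in expr.columns]
    if probes is None:
        probes = list(beta.index)
    k_cov = 0
    if covariates:
        cov = encode_covariates(cohort.loc[shared], covariates)
        k_cov = cov.shape[1]
    if len(shared) < k_cov + 3:
        raise ValueError("not enough shared samples for the adjusted model")
    rows = []
    for probe in probes:
        m = beta.loc[probe, shared].to_numpy(dtype=float)
        for gene in expr.index:
            y = expr.loc[gene, shared].to_numpy(dtype=float)
            X = pd.DataFrame({"meth": m}, index=shared)
            if covariates:
                X = pd.concat([X, cov], axis=1)
            X = sm.add_constant(X)
            mask = ~(np.isnan(y) | np.isnan(m))
            res = sm.OLS(y[mask], X[mask]).fit()
            if res.df_resid <= 0:
                raise ValueError(f"zero residual degrees of freedom for {probe}/{gene}")
            t = float(res.tvalues["meth"])
            rows.append(
                {
                    "probe": probe,
                    "gene": gene,
                    "estimate": float(res.params["meth"]),
                    "t": t,
                    "p": float(res.pvalues["meth"]),
                    "partial_r": t / np.sqrt(t**2 + res.df_resid),
                    "n": int(res.nobs),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def cis_candidates(
    probe_annotation: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    correlations: pd.DataFrame,
    *,
    window: int = 1000,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag cis-regulation candidates among correlation results.

    Distance is 0 when the probe position falls inside the gene-body
    interval (coordinates 1-based inclusive), otherwise the bp gap to
    the nearest interval end; genes on other chromosomes are not cis.
    The candidate flag is ``distance <= window AND p <= p_threshold``
    (both boundaries inclusive). Strand is ignored. Probes on
    chromosomes absent from the gene annotation are skipped with a
    warning.
    """
    genes = gene_annotation.set_index("gene") if "gene" in gene_annotation.columns else gene_annotation
    rows = []
    for _, rec in correlations.iterrows():
        probe, gene = rec["probe"], rec["gene"]
        if probe not in probe_annotation.index or gene not in genes.index:
            continue
        pa = probe_annotation.loc[probe]
        ga = genes.loc[gene]
        if isinstance(ga, pd.DataFrame):
            ga = ga.iloc[0]
        if pa["chrom"] not in set(np.atleast_1d(gene_annotation["chrom"].unique())):
            warnings.warn(f"probe {probe} chromosome {pa['chrom']} absent from gene annotation")
            continue
        if pa["chrom"] != ga["chrom"]:
            dist = np.inf
        else:
            pos = int(pa["position"])
            start, end = int(ga["start"]), int(ga["end"])
            if start <= pos <= end:
                dist = 0
            else:
                dist = start - pos if pos < start else pos - end
        rows.append(
            {
                "probe": probe,
                "gene": gene,
                "distance": dist,
                "estimate": rec.get("estimate", np.nan),
                "p": rec["p"],
                "q": rec.get("q", np.nan),
                "cis": bool(dist <= window and rec["p"] <= p_threshold),
            }
        )
    return pd.DataFrame(rows)


def expression_level_interaction(
    cohort: pd.DataFrame,
    expr: pd.DataFrame,
    genes,
    exposure: str,
    *,
    covariates=DEFAULT_COVARIATES,
    strata: str = "histology",
    scheme: str = "full_factorial",
) -> tuple[CoxFit, dict]:
    """Re-test the four-way interaction with gene expression levels.

    The factorial Cox model is built exactly as for methylation but the
    interacting variables are the (already standardized) expression
    values of the three genes; the highest-order term's Wald test is
    reported against the 0.05 threshold.
    """
    genes = tuple(genes)
    if len(genes) != 3:
        raise ValueError("need exactly three genes")
    spec = ModelSpec(
        exposure=exposure,
        probes=genes,
        covariates=tuple(covariates),
        strata=strata,
        scheme=scheme,
    )
    shared = [s for s in cohort.index if s in expr.columns]
    sub = cohort.loc[shared]
    parts = [encode_covariates(sub, covariates)]
    base = {exposure: sub[exposure].astype(float)}
    for g in genes:
        if g not in expr.index:
            raise KeyError(f"gene {g!r} missing from expression matrix")
        base[g] = expr.loc[g, shared].astype(float)  # standardized scale, no x100
    block = {}
    for term in expand_terms(spec):
        prod = np.ones(len(sub))
        for v in term:
            prod = prod * np.asarray(base[v], dtype=float)
        block[term_name(term)] = prod
    parts.append(pd.DataFrame(block, index=sub.index))
    design = pd.concat(parts, axis=1)
    fit = fit_cox(
        sub["time"].to_numpy(),
        sub["event"].to_numpy(),
        design,
        strata=sub[strata].to_numpy(),
    )
    top = term_name(spec.variables)
    i = fit._idx(top)
    report = {
        "term": top,
        "estimate": float(fit.beta[i]),
        "hr": float(np.exp(fit.beta[i])),
        "p": float(fit.p[i]),
        "significant": bool(fit.p[i] <= 0.05),
        "n": fit.n,
    }
    return fit, report
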