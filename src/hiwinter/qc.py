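"""Probe-, sample- and gene-level quality control.

Probe exclusion rules, applied in a fixed attribution order (a probe is
removed if ANY rule fires; the report records the first failing rule):

a. ``detection``        - detection p > 0.05 in strictly more than 5% of samples
b. ``low_cv``           - coefficient of variation (sd/mean) < 5%
c. ``constant_state``   - methylated (all betas >= 0.9) or unmethylated
                          (all <= 0.1) in every sample; thresholds configurable
d. ``snp_flag``         - common SNP in the probe sequence or 10-bp flanks
                          (annotation flag)
e. ``cross_reactive``   - cross-reactive/cross-hybridizing probe (annotation
                          flag or user blacklist)
f. ``not_in_all_centers`` - fails any of the data-driven rules (a-c) within
                          at least one study center

Samples are removed when more than 5% of their probes fail detection
(``sample_detection``) or the pack-year field is missing
(``missing_packyear``).

The CV is computed as sd/mean on the [0, 1] beta scale with sample sd
(ddof=1); probes with mean 0 are handled by the constant-state rule.
Missing betas are ignored in the CV and constant-state checks; a probe
entirely missing within a center fails rule (f).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "PROBE_RULES",
    "SAMPLE_RULES",
    "filter_probes",
    "filter_samples",
    "normalize_batches",
    "filter_expression",
]

PROBE_RULES = (
    "detection",
    "low_cv",
    "constant_state",
    "snp_flag",
    "cross_reactive",
    "not_in_all_centers",
)
SAMPLE_RULES = ("sample_detection", "missing_packyear")


@dataclass
class QCReport:
    """Per-item pass/fail table plus per-rule removal counts."""

    table: pd.DataFrame  # index = item id; columns: pass, first_fail_rule
    counts: dict

    @property
    def n_retained(self) -> int:
        return int(self.table["pass"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.table["pass"]).sum())


def _rule_abc(values: np.ndarray, cv_threshold, hi, lo):
    """Data-driven rules (b) low CV and (c) constant state on one block.

    Returns (fail_b, fail_c, all_missing) boolean arrays over probes.
    ``values`` is probes x samples with NaN for missing.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
        mn = np.nanmin(values, axis=1)
        mx = np.nanmax(values, axis=1)
    n_obs = (~np.isnan(values)).sum(axis=1)
    all_missing = n_obs == 0
    cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
    fail_b = (mean > 0) & (cv < cv_threshold) & ~all_missing & (n_obs > 1)
    fail_c = (~all_missing) & ((mn >= hi) | (mx <= lo))
    return fail_b, fail_c, all_missing


def filter_probes(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    center_labels=None,
    *,
    detection_p_threshold: float = 0.05,
    detection_sample_frac: float = 0.05,
    cv_threshold: float = 0.05,
    hi_threshold: float = 0.9,
    lo_threshold: float = 0.1,
    cross_reactive_blacklist=None,
):
    """Apply probe rules (a)-(f); return (filtered beta, QCReport).

    ``annotation`` needs boolean/0-1 columns ``snp_flag`` and
    ``cross_reactive`` indexed by probe id; ``center_labels`` assigns each
    sample (beta column) to a study center for rule (f).
    """
    if beta.index.duplicated().any() or beta.columns.duplicated().any():
        raise ValueError("duplicated probe or sample ids in beta matrix")
    vals = beta.to_numpy(dtype=float)
    n_probes, n_samples = vals.shape

    fail = {r: np.zeros(n_probes, dtype=bool) for r in PROBE_RULES}

    if detection_p is not None:
        if detection_p.shape != beta.shape:
            raise ValueError(
                f"detection_p shape {detection_p.shape} does not match beta {beta.shape}"
            )
        det = detection_p.reindex(index=beta.index, columns=beta.columns).to_numpy(float)
        frac = (det > detection_p_threshold).mean(axis=1)
        fail["detection"] = frac > detection_sample_frac  # strictly more than 5%

    fail_b, fail_c, all_missing = _rule_abc(vals, cv_threshold, hi_threshold, lo_threshold)
    fail["low_cv"] = fail_b
    fail["constant_state"] = fail_c | all_missing

    if annotation is not None:
        for col, rule in (("snp_flag", "snp_flag"), ("cross_reactive", "cross_reactive")):
            if col not in annotation.columns:
                raise KeyError(f"annotation missing required column {col!r}")
        ann = annotation.reindex(beta.index)
        fail["snp_flag"] = ann["snp_flag"].fillna(0).astype(bool).to_numpy()
        fail["cross_reactive"] = ann["cross_reactive"].fillna(0).astype(bool).to_numpy()
    if cross_reactive_blacklist is not None:
        black = beta.index.isin(list(cross_reactive_blacklist))
        fail["cross_reactive"] = fail["cross_reactive"] | black

    if center_labels is not None:
        centers = pd.Series(np.asarray(center_labels), index=beta.columns)
        for center in centers.unique():
            cols = centers.index[centers == center]
            sub = beta[cols].to_numpy(float)
            fb, fc, miss = _rule_abc(sub, cv_threshold, hi_threshold, lo_threshold)
            fa = np.zeros(n_probes, dtype=bool)
            if detection_p is not None:
                dsub = detection_p[cols].to_numpy(float)
                fa = (dsub > detection_p_threshold).mean(axis=1) > detection_sample_frac
            fail["not_in_all_centers"] |= fa | fb | fc | miss

    any_fail = np.zeros(n_probes, dtype=bool)
    first_rule = np.full(n_probes, "", dtype=object)
    for rule in PROBE_RULES:  # fixed a->f attribution order
        newly = fail[rule] & ~any_fail
        first_rule[newly] = rule
        any_fail |= fail[rule]

    table = pd.DataFrame(
        {"pass": ~any_fail, "first_fail_rule": first_rule}, index=beta.index
    )
    counts = {rule: int((first_rule == rule).sum()) for rule in PROBE_RULES}
    report = QCReport(table=table, counts=counts)
    return beta.loc[~any_fail], report


def filter_samples(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame | None,
    phenotypes: pd.DataFrame,
    *,
    detection_p_threshold: float = 0.05,
    undetectable_frac: float = 0.05,
    packyear_col: str = "pack_years",
):
    """Drop samples with > 5% undetectable probes or missing pack-years.

    Returns (retained sample ids in input order, QCReport).
    """
    if not beta.columns.equals(pd.Index(phenotypes.index)):
        if set(beta.columns) != set(phenotypes.index):
            raise ValueError("sample ids differ between beta matrix and phenotypes")
        phenotypes = phenotypes.reindex(beta.columns)
    n_samples = beta.shape[1]
    fail = {r: np.zeros(n_samples, dtype=bool) for r in SAMPLE_RULES}
    if detection_p is not None:
        det = detection_p.reindex(index=beta.index, columns=beta.columns).to_numpy(float)
        frac = (det > detection_p_threshold).mean(axis=0)
        fail["sample_detection"] = frac > undetectable_frac  # strict
    if packyear_col not in phenotypes.columns:
        raise KeyError(f"phenotype table lacks {packyear_col!r}")
    fail["missing_packyear"] = phenotypes[packyear_col].isna().to_numpy()

    any_fail = np.zeros(n_samples, dtype=bool)
    first_rule = np.full(n_samples, "", dtype=object)
    for rule in SAMPLE_RULES:
        newly = fail[rule] & ~any_fail
        first_rule[newly] = rule
        any_fail |= fail[rule]
    table = pd.DataFrame(
        {"pass": ~any_fail, "first_fail_rule": first_rule}, index=beta.columns
    )
    counts = {rule: int((first_rule == rule).sum()) for rule in SAMPLE_RULES}
    retained = beta.columns[~any_fail]
    return retained, QCReport(table=table, counts=counts)


def normalize_batches(beta: pd.DataFrame, batch_labels) -> pd.DataFrame:
    """Location-scale batch alignment to the pooled per-probe reference.

    For every probe, each batch's mean/sd is mapped onto the pooled
    mean/sd; output is clipped to [0, 1]. This is a deliberately simple
    stand-in for array-specific normalization pipelines (quantile
    normalization, type I/II correction, empirical-Bayes batch removal),
    which are out of scope here.
    """
    batches = pd.Series(np.asarray(batch_labels), index=beta.columns)
    sizes = batches.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    vals = beta.to_numpy(dtype=float)
    pooled_mean = np.nanmean(vals, axis=1, keepdims=True)
    pooled_sd = np.nanstd(vals, axis=1, keepdims=True)
    out = np.empty_like(vals)
    for batch in sizes.index:
        cols = np.flatnonzero((batches == batch).to_numpy())
        sub = vals[:, cols]
        m = np.nanmean(sub, axis=1, keepdims=True)
        s = np.nanstd(sub, axis=1, keepdims=True)
        scale = np.where(s > 0, np.where(pooled_sd > 0, pooled_sd, s) / np.where(s > 0, s, 1.0), 1.0)
        out[:, cols] = (sub - m) * scale + pooled_mean
    out = np.clip(out, 0.0, 1.0)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def filter_expression(
    expr: pd.DataFrame,
    missing_threshold: float = 0.80,
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Gene-level expression QC: drop genes missing in > 80% of samples,
    optionally log2(x+1)-transform raw values, standardize per gene.

    Genes constant after filtering cannot be standardized and are dropped
    with a warning.
    """
    vals = expr.to_numpy(dtype=float)
    miss = np.isnan(vals).mean(axis=1)
    keep = miss <= missing_threshold
    vals = vals[keep]
    index = expr.index[keep]
    if log2_transform:
        if np.nanmin(vals) < 0:
            raise ValueError("negative raw values are incompatible with log2(x+1)")
        vals = np.log2(vals + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, keepdims=True)
    # relative tolerance: summation rounding leaves ~1e-16 residual spread
    # on constant rows
    tiny = 1e-12 * (np.abs(mean[:, 0]) + 1.0)
    const = (sd[:, 0] <= tiny) | np.isnan(sd[:, 0])
    if const.any():
        warnings.warn(
            f"dropping {int(const.sum())} constant gene(s) after filtering: "
            f"{index[const][:5].tolist()}"
        )
    vals = (vals - mean) / np.where(sd > 0, sd, 1.0)
    return pd.DataFrame(vals[~const], index=index[~const], columns=expr.columns)
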