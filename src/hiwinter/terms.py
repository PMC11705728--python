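"""Factorial term expansion and design-matrix construction.

A model is described by a :class:`ModelSpec`: one continuous environmental
exposure (pack-years of smoking), an ordered set of methylation probes, the
clinical adjustment covariates, and a stratification factor (histology).
The ``k`` interacting variables (exposure + probes) are expanded into
product terms; methylation enters every product on the 0-100 percent scale
so that hazard ratios are interpretable per 1 percentage point.

Two expansion schemes are supported:

``full_factorial``
    every product over a nonempty subset of the k variables
    (``2**k - 1`` terms), i.e. the full interaction hierarchy.
``as_printed``
    the 14-term variant of the four-way integrated-score formula, which
    omits the exposure x probe2 x probe3 triple. Only defined for k = 4;
    kept so that results can be reproduced under either reading of the
    published formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

#: percent-scale multiplier applied to beta values before forming products
PERCENT = 100.0

DEFAULT_COVARIATES = ("age", "sex", "smoking_status", "stage", "center")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a stratified Cox interaction model.

    Parameters
    ----------
    exposure:
        Name of the continuous environmental variable (cohort column).
    probes:
        Ordered probe ids entering the interaction. ``k = len(probes) + 1``.
    covariates:
        Clinical adjustment variables; categorical ones are reference-coded.
    strata:
        Cohort column used as stratification factor for the baseline hazard.
    scheme:
        ``"full_factorial"`` or ``"as_printed"`` (see module docstring).
    ties:
        Partial-likelihood tie handling, ``"efron"`` (default) or ``"breslow"``.
    """

    exposure: str = "pack_years"
    probes: tuple = ()
    covariates: tuple = DEFAULT_COVARIATES
    strata: str = "histology"
    scheme: str = "full_factorial"
    ties: str = "efron"

    def __post_init__(self):
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("duplicate probe ids in ModelSpec.probes")
        if self.exposure in self.probes:
            raise ValueError("exposure must not be among the probes")
        if self.order < 2 and self.probes:
            raise ValueError("interaction order must be >= 2")
        if self.scheme not in ("full_factorial", "as_printed"):
            raise ValueError(f"unknown term scheme {self.scheme!r}")
        if self.scheme == "as_printed" and self.order != 4:
            raise ValueError("scheme 'as_printed' is only defined for order 4")

    @property
    def order(self) -> int:
        """Number of interacting variables k."""
        return len(self.probes) + 1

    @property
    def variables(self) -> tuple:
        """Interacting variables in canonical order (exposure first)."""
        return (self.exposure,) + tuple(self.probes)


# index subset omitted by the printed four-way score formula:
# exposure (1) x probe2 (3) x probe3 (4), zero-based (0, 2, 3)
_AS_PRINTED_OMITTED = (0, 2, 3)


def expand_terms(spec: ModelSpec) -> list:
    """Expand a spec into its ordered interaction-hierarchy term list.

    Returns a list of tuples of variable names; singletons are main
    effects. Ordering is deterministic: ascending interaction order,
    and within an order by position of the variables in
    ``spec.variables`` (exposure first, then probes as given).
    """
    variables = spec.variables
    k = len(variables)
    if k < 2:
        raise ValueError("need at least two interacting variables")
    terms = []
    for order in range(1, k + 1):
        for idx in combinations(range(k), order):
            if spec.scheme == "as_printed" and idx == _AS_PRINTED_OMITTED:
                continue
            terms.append(tuple(variables[i] for i in idx))
    return terms


def term_name(term) -> str:
    return ":".join(term) if isinstance(term, tuple) else str(term)


def encode_covariates(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Reference-code clinical covariates into numeric design columns.

    sex -> sex_M (ref F); smoking_status -> smoking_ever, smoking_current
    (ref never); stage -> stage_II (ref I); center -> one indicator per
    non-reference center (reference = first label in sorted order).
    Continuous columns (age, pack_years, ...) pass through unchanged.
    """
    cols = {}
    for cov in covariates:
        if cov not in cohort.columns:
            raise KeyError(f"covariate {cov!r} missing from cohort")
        col = cohort[cov]
        if cov == "sex":
            cols["sex_M"] = (col.astype(str) == "M").astype(float)
        elif cov == "smoking_status":
            s = col.astype(str)
            bad = set(s.unique()) - {"never", "ever", "current"}
            if bad:
                raise ValueError(f"unknown smoking_status levels {sorted(bad)}")
            # reference = never when present, else the first observed level
            observed = [lev for lev in ("never", "ever", "current") if (s == lev).any()]
            for lev in observed[1:]:
                cols[f"smoking_{lev}"] = (s == lev).astype(float)
        elif cov == "stage":
            cols["stage_II"] = (col.astype(str) == "II").astype(float)
        elif cov == "center":
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols[f"center_{lev}"] = (col.astype(str) == lev).astype(float)
        else:
            cols[cov] = pd.to_numeric(col, errors="raise").astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def interaction_columns(
    cohort: pd.DataFrame, beta: pd.DataFrame, spec: ModelSpec
) -> pd.DataFrame:
    """Raw columns for the k interacting variables, aligned to the cohort.

    Probes are taken from ``beta`` (probe x sample, values in [0, 1]) and
    multiplied by 100 so coefficients are per 1% methylation.
    """
    if spec.exposure not in cohort.columns:
        raise KeyError(f"exposure {spec.exposure!r} missing from cohort")
    cols = {spec.exposure: cohort[spec.exposure].astype(float)}
    for probe in spec.probes:
        if probe not in beta.index:
            raise KeyError(f"probe {probe!r} missing from beta matrix")
        vals = beta.loc[probe].reindex(cohort.index)
        if vals.isna().any():
            missing = vals.index[vals.isna()][:3].tolist()
            raise ValueError(f"probe {probe!r} missing beta values for samples {missing}")
        cols[probe] = vals.astype(float) * PERCENT
    return pd.DataFrame(cols, index=cohort.index)


def build_design(
    cohort: pd.DataFrame, beta: pd.DataFrame | None, spec: ModelSpec
) -> pd.DataFrame:
    """Full numeric design matrix: covariate block + factorial term block.

    Column order is deterministic: encoded covariates first (in spec
    order), then the interaction-hierarchy terms from
    :func:`expand_terms` named ``"a:b:c"``.
    """
    parts = [encode_covariates(cohort, spec.covariates)]
    if spec.probes:
        base = interaction_columns(cohort, beta if beta is not None else pd.DataFrame(), spec)
        term_block = {}
        for term in expand_terms(spec):
            prod = np.ones(len(cohort))
            for var in term:
                prod = prod * base[var].to_numpy()
            term_block[term_name(term)] = prod
        parts.append(pd.DataFrame(term_block, index=cohort.index))
    design = pd.concat(parts, axis=1)
    if design.columns.duplicated().any():
        dup = design.columns[design.columns.duplicated()].tolist()
        raise ValueError(f"duplicate design columns {dup}")
    return design
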