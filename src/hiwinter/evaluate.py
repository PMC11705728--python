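"""Discrimination of nested prognostic models: time-dependent ROC/AUC,
AUC contrasts, and Harrell's concordance index.

The time-dependent AUC is the cumulative/dynamic estimator with inverse
probability of censoring weighting (IPCW): at horizon tau, cases are
samples with an observed event by tau, controls are samples still at
risk beyond tau, and samples censored before tau are weighted out via
the Kaplan-Meier estimate of the censoring distribution G. With no
censoring before the horizon every weight is 1 and the estimator
reduces exactly to the Mann-Whitney AUC of the binary event-by-horizon
label.

AUC contrasts between two models on the same samples use DeLong's test
for correlated ROC curves whenever the horizon reduction is uncensored,
and otherwise a Wald test on the AUC difference using the paired
influence-function variance of the weighted two-sample U-statistic
(weights treated as fixed). The method used is labelled in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.stats import norm

from .cox import Z95
from .terms import DEFAULT_COVARIATES, ModelSpec, build_design, encode_covariates
from .cox import fit_cox

__all__ = [
    "TimedAUC",
    "ModelContrast",
    "ModelComparison",
    "timed_auc",
    "compare_auc",
    "c_index",
    "nested_models",
]


def _censoring_km(times, events):
    """Step function of the censoring survival G (KM with roles swapped).

    Returns (sorted unique times, G at those times). Ties between
    events and censorings at the same time follow the convention that
    events precede censorings, so G(t-) uses strictly earlier censoring
    times only.
    """
    times = np.asarray(times, dtype=float)
    cens = 1 - np.asarray(events)
    order = np.argsort(times, kind="stable")
    t = times[order]
    c = cens[order]
    uniq, start = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - start
    n_cens = np.add.reduceat(c, start)
    # events at t are removed from the risk set before censorings at t
    n_events = np.add.reduceat(1 - c, start)
    factors = 1.0 - n_cens / np.maximum(at_risk - n_events, 1)
    G = np.cumprod(factors)
    return uniq, G


def _G_at(uniq, G, t, left: bool):
    """Evaluate the censoring KM at t (left=True gives the left limit)."""
    side = "left" if left else "right"
    idx = np.searchsorted(uniq, t, side=side) - 1
    out = np.where(idx >= 0, G[np.clip(idx, 0, None)], 1.0)
    return out


@dataclass
class TimedAUC:
    horizon: float
    auc: float
    se: float
    ci: tuple
    n_cases: int
    n_controls: int
    estimator: str = "ipcw"
    #: per-sample pieces reused by compare_auc (not part of the public repr)
    _parts: dict = field(default_factory=dict, repr=False)


def _ipcw_parts(scores, times, events, horizon):
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if not (times > 0).all():
        raise ValueError("survival times must be > 0")
    if horizon <= 0 or horizon >= times.max():
        raise ValueError("horizon must lie within the follow-up range")
    case = (events == 1) & (times <= horizon)
    ctrl = times > horizon
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("need at least one case and one control at the horizon")
    uniq, G = _censoring_km(times, events)
    w_case = 1.0 / _G_at(uniq, G, times[case], left=True)
    g_tau = _G_at(uniq, G, np.array([horizon]), left=False)[0]
    if g_tau <= 0:
        raise ValueError("censoring survival is zero at the horizon")
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / g_tau)
    return scores, case, ctrl, w_case, w_ctrl


def _weighted_auc(s_case, s_ctrl, w_case, w_ctrl):
    """Weighted concordance of case scores over control scores plus the
    per-sample conditional means used for the variance."""
    diff = s_case[:, None] - s_ctrl[None, :]
    psi = (diff > 0) + 0.5 * (diff == 0)
    p = w_case / w_case.sum()
    q = w_ctrl / w_ctrl.sum()
    auc = float(p @ psi @ q)
    P = psi @ q  # per-case mean over controls
    Q = p @ psi  # per-control mean over cases
    var = float(np.sum(p**2 * (P - auc) ** 2) + np.sum(q**2 * (Q - auc) ** 2))
    return auc, np.sqrt(var), P, Q, p, q


def timed_auc(scores, times, events, horizon) -> TimedAUC:
    """Cumulative/dynamic IPCW AUC at one horizon.

    cases: events by the horizon, weighted 1/G(T-); controls: at risk
    beyond the horizon, weighted 1/G(horizon). The CI is a normal Wald
    interval from the weighted U-statistic projection variance,
    truncated to [0, 1].
    """
    scores, case, ctrl, w_case, w_ctrl = _ipcw_parts(scores, times, events, horizon)
    auc, se, P, Q, p, q = _weighted_auc(scores[case], scores[ctrl], w_case, w_ctrl)
    ci = (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))
    return TimedAUC(
        horizon=float(horizon),
        auc=auc,
        se=se,
        ci=ci,
        n_cases=int(case.sum()),
        n_controls=int(ctrl.sum()),
        estimator="ipcw",
        _parts={"case": case, "ctrl": ctrl, "P": P, "Q": Q, "p": p, "q": q},
    )


def _delong(scores_a, scores_b, labels):
    """Exact DeLong test for two correlated ROC curves on binary labels."""
    pos = labels == 1
    neg = ~pos
    m, n = int(pos.sum()), int(neg.sum())
    stats = []
    for s in (scores_a, scores_b):
        diff = s[pos][:, None] - s[neg][None, :]
        psi = (diff > 0) + 0.5 * (diff == 0)
        stats.append((float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)))
    (auc_a, V10_a, V01_a), (auc_b, V10_b, V01_b) = stats
    S10 = np.cov(np.vstack([V10_a, V10_b]), ddof=1)
    S01 = np.cov(np.vstack([V01_a, V01_b]), ddof=1)
    var = (S10[0, 0] + S10[1, 1] - 2 * S10[0, 1]) / m + (
        S01[0, 0] + S01[1, 1] - 2 * S01[0, 1]
    ) / n
    delta = auc_b - auc_a
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2 * norm.sf(abs(delta) / np.sqrt(var)))
    return auc_a, auc_b, delta, p, np.sqrt(max(var, 0.0))


@dataclass
class ModelContrast:
    horizon: float
    auc_small: float
    auc_big: float
    delta: float
    rel_increase_pct: float
    p: float
    se: float
    method: str  # "delong" (uncensored reduction) or "ipcw_wald"


def compare_auc(scores_small, scores_big, times, events, horizon) -> ModelContrast:
    """Paired contrast of two models' time-dependent AUCs at one horizon.

    With no censoring before the horizon this is exactly DeLong's test
    on the binary event-by-horizon label; under censoring it is a Wald
    test on the IPCW AUC difference with the joint influence variance.
    Also reports the relative AUC increase 100*(big-small)/small.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    sa = np.asarray(scores_small, dtype=float)
    sb = np.asarray(scores_big, dtype=float)
    if sa.shape != sb.shape or sa.shape != times.shape:
        raise ValueError("both score vectors must cover the same samples")
    censored_early = ((events == 0) & (times <= horizon)).any()
    if not censored_early:
        labels = ((times <= horizon) & (events == 1)).astype(int)
        auc_a, auc_b, delta, p, se = _delong(sa, sb, labels)
        method = "delong"
    else:
        ta = timed_auc(sa, times, events, horizon)
        tb = timed_auc(sb, times, events, horizon)
        auc_a, auc_b = ta.auc, tb.auc
        delta = auc_b - auc_a
        dP = tb._parts["P"] - ta._parts["P"]
        dQ = tb._parts["Q"] - ta._parts["Q"]
        p_w, q_w = ta._parts["p"], ta._parts["q"]
        var = float(np.sum(p_w**2 * (dP - delta) ** 2) + np.sum(q_w**2 * (dQ - delta) ** 2))
        se = np.sqrt(max(var, 0.0))
        if se == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            p = float(2 * norm.sf(abs(delta) / se))
        method = "ipcw_wald"
    rel = 100.0 * delta / auc_a if auc_a != 0 else np.nan
    return ModelContrast(
        horizon=float(horizon),
        auc_small=auc_a,
        auc_big=auc_b,
        delta=delta,
        rel_increase_pct=rel,
        p=p,
        se=se,
        method=method,
    )


def c_index(scores, times, events, *, symmetric: bool = False) -> float:
    """Harrell's concordance index for right-censored data.

    Orderable pairs: the sample with the shorter observed time had the
    event (time ties are orderable only when exactly one member is an
    event, which is then the shorter survivor). Concordant when the
    shorter survivor has the higher score; score ties get half credit.
    With ``symmetric=True`` the reported value is max(c, 1-c).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    ej = e[None, :]
    # pair (i, j): i is the established shorter survivor
    orderable = ((ti < tj) & ei) | ((ti == tj) & ei & ~ej)
    n_pairs = int(orderable.sum())
    if n_pairs == 0:
        raise ValueError("no orderable pairs under censoring")
    si, sj = s[:, None], s[None, :]
    conc = (orderable & (si > sj)).sum() + 0.5 * (orderable & (si == sj)).sum()
    c = float(conc / n_pairs)
    return max(c, 1.0 - c) if symmetric else c


@dataclass
class ModelComparison:
    labels: tuple
    aucs: pd.DataFrame  # rows: model label; columns: horizon
    c_indices: dict
    contrasts: list  # (label_small, label_big, ModelContrast)

    def summary(self) -> pd.DataFrame:
        rows = []
        for a, b, ct in self.contrasts:
            rows.append(
                {
                    "small": a,
                    "big": b,
                    "horizon": ct.horizon,
                    "auc_small": ct.auc_small,
                    "auc_big": ct.auc_big,
                    "delta": ct.delta,
                    "rel_increase_pct": ct.rel_increase_pct,
                    "p": ct.p,
                    "method": ct.method,
                }
            )
        return pd.DataFrame(rows)


def nested_models(
    cohort: pd.DataFrame,
    beta: pd.DataFrame,
    probes,
    exposure: str,
    *,
    horizons=(3.0, 5.0),
    covariates=DEFAULT_COVARIATES,
    strata: str = "histology",
    scheme: str = "full_factorial",
) -> ModelComparison:
    """Fit and compare the three nested prognostic models.

    (a) clinical covariates only; (b) covariates plus all elements of
    the three-way interaction (exposure x probe1 x probe2); (c)
    covariates plus all elements of the four-way interaction. Each model
    is fitted on the cohort, samples are scored with its linear
    predictor, and discrimination is evaluated in-sample by IPCW AUC at
    the requested horizons and Harrell's C.
    """
    probes = tuple(probes)
    if len(probes) != 3:
        raise ValueError("need exactly three probes (two fixed + scanned)")
    t = cohort["time"].to_numpy()
    e = cohort["event"].to_numpy()
    st = cohort[strata].to_numpy()

    def lp_for(probe_subset):
        if probe_subset is None:
            design = encode_covariates(cohort, covariates)
        else:
            spec = ModelSpec(
                exposure=exposure,
                probes=probe_subset,
                covariates=tuple(covariates),
                strata=strata,
                scheme=scheme if len(probe_subset) == 3 else "full_factorial",
            )
            design = build_design(cohort, beta, spec)
        fit = fit_cox(t, e, design, strata=st)
        return fit.linear_predictor(design)

    labels = ("covariates", "three_way", "four_way")
    scores = {
        "covariates": lp_for(None),
        "three_way": lp_for(probes[:2]),
        "four_way": lp_for(probes),
    }
    auc_rows = {}
    for lab in labels:
        auc_rows[lab] = {h: timed_auc(scores[lab], t, e, h).auc for h in horizons}
    aucs = pd.DataFrame(auc_rows).T
    aucs.index.name = "model"
    cidx = {lab: c_index(scores[lab], t, e) for lab in labels}
    contrasts = []
    for a, b in (("covariates", "three_way"), ("three_way", "four_way"), ("covariates", "four_way")):
        for h in horizons:
            contrasts.append((a, b, compare_auc(scores[a], scores[b], t, e, h)))
    return ModelComparison(labels=labels, aucs=aucs, c_indices=cidx, contrasts=contrasts)
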