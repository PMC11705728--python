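"""Time-dependent AUC, AUC contrasts, concordance index, nested models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from hiwinter.evaluate import c_index, compare_auc, nested_models, timed_auc
from hiwinter.synthetic import discovery_config, simulate_bundle

PLANTED = ("cg05293407", "cg00060500", "cg16658473")


def delong_oracle(scores_a, scores_b, labels):
    """Independent DeLong implementation (naive loops over structural
    components) for the correlated-ROC contrast."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    m, n = len(pos), len(neg)

    def components(s):
        v10 = np.array([np.mean((s[i] > s[neg]) + 0.5 * (s[i] == s[neg])) for i in pos])
        v01 = np.array([np.mean((s[pos] > s[j]) + 0.5 * (s[pos] == s[j])) for j in neg])
        return v10.mean(), v10, v01

    auc_a, v10a, v01a = components(np.asarray(scores_a))
    auc_b, v10b, v01b = components(np.asarray(scores_b))
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    z = (auc_b - auc_a) / np.sqrt(var)
    return auc_b - auc_a, 2 * norm.sf(abs(z))


class TestTimedAUC:
    def test_no_censoring_equals_mann_whitney(self, rng):
        n = 150
        score = rng.normal(size=n)
        time = rng.exponential(np.exp(-score))
        event = np.ones(n, dtype=int)
        tau = float(np.quantile(time, 0.5))
        labels = (time <= tau).astype(int)
        from sklearn.metrics import roc_auc_score

        expected = roc_auc_score(labels, score)
        assert timed_auc(score, time, event, tau).auc == pytest.approx(expected, abs=1e-12)

    def test_identical_scores_give_half(self, rng):
        time = rng.exponential(1.0, 50)
        auc = timed_auc(np.ones(50), time, np.ones(50, dtype=int), float(np.median(time)))
        assert auc.auc == pytest.approx(0.5)

    def test_six_sample_worked_fixture(self):
        """Hand-derived weighted concordance: censoring KM gives case
        weights 6/5 and 8/5 and control weights 8/5; the weighted AUC is
        exactly 5/7."""
        t = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0])
        e = np.array([0, 1, 0, 1, 1, 0])
        s = np.array([2.1, 3.0, 1.0, 0.8, 0.5, 1.5])
        r = timed_auc(s, t, e, 2.5)
        assert r.auc == pytest.approx(5 / 7, abs=1e-10)
        assert r.n_cases == 2 and r.n_controls == 2
        assert r.ci[0] <= r.auc <= r.ci[1]

    def test_matches_scikit_survival_estimator(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc

        n = 200
        score = rng.normal(size=n)
        T = rng.exponential(np.exp(-0.8 * score))
        C = rng.exponential(2.0, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
        y = np.array(
            [(bool(a), float(b)) for a, b in zip(event, time)],
            dtype=[("e", bool), ("t", float)],
        )
        for tau in (0.5, 1.0, 1.5):
            mine = timed_auc(score, time, event, tau).auc
            ref, _ = cumulative_dynamic_auc(y, y, score, [tau])
            assert mine == pytest.approx(ref[0], abs=1e-10)

    def test_invariant_to_monotone_score_transform(self, rng):
        n = 120
        score = rng.normal(size=n)
        T = rng.exponential(np.exp(-score))
        C = rng.exponential(2.0, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        tau = float(np.quantile(time, 0.4))
        a1 = timed_auc(score, time, event, tau).auc
        a2 = timed_auc(np.exp(3 * score) + 7, time, event, tau).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_degenerate_horizons_rejected(self, rng):
        time = rng.exponential(1.0, 30)
        event = np.ones(30, dtype=int)
        s = rng.normal(size=30)
        with pytest.raises(ValueError):
            timed_auc(s, time, event, float(time.max()) + 1)
        with pytest.raises(ValueError):
            timed_auc(s, time, event, float(time.min()) / 2)


class TestCompareAUC:
    def test_identical_scores_give_zero_delta_p_one(self, rng):
        time = rng.exponential(1.0, 60)
        event = np.ones(60, dtype=int)
        s = rng.normal(size=60)
        ct = compare_auc(s, s.copy(), time, event, float(np.median(time)))
        assert ct.delta == 0.0
        assert ct.p == 1.0

    def test_uncensored_reduction_matches_independent_delong(self, rng):
        n = 150
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        time = rng.exponential(np.exp(-x))
        event = np.ones(n, dtype=int)
        tau = float(np.quantile(time, 0.5))
        sa = x + 2.0 * noise
        sb = x + 0.5 * noise
        ct = compare_auc(sa, sb, time, event, tau)
        assert ct.method == "delong"
        labels = (time <= tau).astype(int)
        d_delta, d_p = delong_oracle(sa, sb, labels)
        assert ct.delta == pytest.approx(d_delta, abs=1e-12)
        assert ct.p == pytest.approx(d_p, abs=1e-8)

    def test_censored_contrast_labelled_and_relative_increase(self, rng):
        n = 300
        x = rng.normal(size=n)
        T = rng.exponential(np.exp(-x))
        C = rng.exponential(1.5, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        tau = float(np.quantile(time, 0.5))
        sa = x + rng.normal(size=n)
        ct = compare_auc(sa, x, time, event, tau)
        assert ct.method == "ipcw_wald"
        assert ct.rel_increase_pct == pytest.approx(
            100.0 * (ct.auc_big - ct.auc_small) / ct.auc_small
        )


class TestCIndex:
    def test_perfectly_anti_ranked_scores(self):
        assert c_index([3.0, 2.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1]) == 1.0

    def test_hand_enumerated_three_pairs(self):
        """times (1,2,3) all events, scores (2,3,1): pairs (1,2) discordant,
        (1,3) and (2,3) concordant -> 2/3."""
        assert c_index([2.0, 3.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1]) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        s = rng.normal(size=n)
        t = rng.exponential(1.0, n)
        e = rng.binomial(1, 0.6, n)
        e[np.argmin(t)] = 1
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shorter = (t[i] < t[j] and e[i]) or (t[i] == t[j] and e[i] and not e[j])
                if shorter:
                    den += 1
                    num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert c_index(s, t, e) == pytest.approx(num / den, abs=1e-15)

    def test_matches_lifelines_concordance(self, rng):
        from lifelines.utils import concordance_index

        n = 80
        s = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * s))
        e = rng.binomial(1, 0.7, n)
        e[np.argmin(t)] = 1
        # lifelines concordance is for predicted survival times (higher =
        # longer survival), so negate the risk score
        assert c_index(s, t, e) == pytest.approx(concordance_index(t, -s, e), abs=1e-12)

    def test_score_and_negation_sum_to_one(self, rng):
        n = 40
        s = rng.normal(size=n)
        t = rng.exponential(1.0, n)
        e = rng.binomial(1, 0.7, n)
        e[np.argmin(t)] = 1
        assert c_index(s, t, e) + c_index(-s, t, e) == pytest.approx(1.0)

    def test_symmetric_convention_flag(self):
        c = c_index([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 1, 1])
        assert c == 0.0
        assert c_index([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 1, 1], symmetric=True) == 1.0

    def test_no_orderable_pairs_rejected(self):
        with pytest.raises(ValueError, match="orderable"):
            c_index([1.0, 2.0], [3.0, 3.0], [1, 1])


class TestNestedModels:
    def test_planted_four_way_orders_the_three_models(self):
        """With a planted four-way effect the full interaction model
        discriminates best at both horizons, and C-indices follow."""
        cfg = discovery_config(
            seed=51, n_probes=6, n_per_center=300, centers=("A", "B"),
            planted_coefficients={"E:G1:G2:X": -3e-5},
        )
        bundle = simulate_bundle(cfg, with_expression=False)
        comp = nested_models(bundle.cohort, bundle.beta, PLANTED, "pack_years")
        aucs = comp.aucs
        for h in (3.0, 5.0):
            assert aucs.loc["four_way", h] >= aucs.loc["three_way", h]
            assert aucs.loc["three_way", h] >= aucs.loc["covariates", h] - 0.02
        assert comp.c_indices["four_way"] > comp.c_indices["covariates"]
        summary = comp.summary()
        assert len(summary) == 6  # 3 contrasts x 2 horizons
        assert set(summary["method"]) <= {"delong", "ipcw_wald"}

    def test_fully_null_data_keeps_aucs_near_half(self):
        """Zero covariate effects and no planted terms: every model's
        in-sample AUC stays near chance (small optimism from fitting 21
        coefficients is expected)."""
        cfg = discovery_config(
            seed=52, n_probes=6, n_per_center=300, centers=("A", "B"),
            covariate_effects={},
        )
        bundle = simulate_bundle(cfg, with_expression=False)
        comp = nested_models(
            bundle.cohort, bundle.beta, cfg.planted_probe_ids, "pack_years",
            horizons=(3.0,),
        )
        assert (comp.aucs[3.0] - 0.5).abs().max() < 0.12
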