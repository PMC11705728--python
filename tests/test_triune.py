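"""Integrated risk score, quartile subgroups, KM curves, group hazard
ratios, forest analysis and the conditional effect surface."""

import numpy as np
import pandas as pd
import pytest

from hiwinter.cox import CoxFit, fit_cox
from hiwinter.scan import fit_interaction_model
from hiwinter.synthetic import discovery_config, simulate_bundle
from hiwinter.terms import ModelSpec, build_design, encode_covariates, expand_terms, term_name
from hiwinter.triune import (
    clinical_score,
    compute_triune,
    conditional_effect_surface,
    group_hazard_ratios,
    km_curve,
    quartile_groups,
    risk_scores,
    stratified_forest,
)

PLANTED = ("cg05293407", "cg00060500", "cg16658473")


@pytest.fixture(scope="module")
def planted_fit():
    cfg = discovery_config(
        seed=41, n_probes=6, n_per_center=300, centers=("A", "B"),
        planted_coefficients={"E:G1:G2:X": -3e-5},
    )
    bundle = simulate_bundle(cfg, with_expression=False)
    fit, spec = fit_interaction_model(
        bundle.cohort, bundle.beta, "pack_years", PLANTED
    )
    return cfg, bundle, fit, spec


class TestComputeTriune:
    def test_score_equals_hand_computed_weighted_sum(self, planted_fit):
        """The integrated score is the exact weighted sum of covariates
        and factorial products; re-derive it independently for a few
        samples from the fitted coefficients."""
        _, bundle, fit, spec = planted_fit
        scores = compute_triune(fit, bundle.cohort, bundle.beta, spec)
        coefs = dict(zip(fit.terms, fit.beta))
        for sample in bundle.cohort.index[:5]:
            row = bundle.cohort.loc[sample]
            vals = {
                "age": row["age"],
                "sex_M": float(row["sex"] == "M"),
                "smoking_ever": float(row["smoking_status"] == "ever"),
                "smoking_current": float(row["smoking_status"] == "current"),
                "stage_II": float(row["stage"] == "II"),
                "center_B": float(row["center"] == "B"),
                "pack_years": row["pack_years"],
            }
            for p in PLANTED:
                vals[p] = bundle.beta.loc[p, sample] * 100.0
            expected = 0.0
            for term, coef in coefs.items():
                prod = 1.0
                for part in term.split(":"):
                    prod *= vals[part]
                expected += coef * prod
            assert scores[sample] == pytest.approx(expected, rel=1e-12)

    def test_zero_coefficients_give_zero_scores(self, planted_fit):
        _, bundle, fit, spec = planted_fit
        null_fit = CoxFit(
            terms=fit.terms, beta=np.zeros_like(fit.beta), se=fit.se,
            cov=fit.cov, loglik=0.0, n=fit.n, n_events=fit.n_events,
            converged=True, n_iter=0, ties="efron",
        )
        scores = compute_triune(null_fit, bundle.cohort, bundle.beta, spec)
        assert (scores == 0).all()

    def test_missing_term_input_named_in_error(self, planted_fit):
        _, bundle, fit, spec = planted_fit
        with pytest.raises((KeyError, ValueError), match="cg05293407"):
            compute_triune(fit, bundle.cohort, bundle.beta.drop(index=[PLANTED[0]]), spec)


class TestQuartileGroups:
    def test_eight_distinct_scores_split_evenly(self):
        groups = quartile_groups(np.arange(1.0, 9.0))
        assert np.bincount(groups)[1:].tolist() == [2, 2, 2, 2]

    def test_992_distinct_scores_give_groups_of_248(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(992) / 7.0
        groups = quartile_groups(scores)
        assert np.bincount(groups)[1:].tolist() == [248, 248, 248, 248]

    def test_boundary_ties_go_to_lower_group_deterministically(self):
        g1 = quartile_groups([1.0, 1.0, 1.0, 2.0])
        g2 = quartile_groups([1.0, 1.0, 1.0, 2.0])
        assert g1.tolist() == g2.tolist()
        assert g1[:3].tolist() == [1, 1, 1]  # ties at the cutoff stay low
        assert g1[3] == 4

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            quartile_groups([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="at least 4"):
            quartile_groups([1.0, 2.0, 3.0])


class TestKMCurve:
    def test_hand_worked_product_limit(self):
        """times (1+, 2, 3, 4) with events at 2, 3, 4: S = 1, 2/3, 1/3, 0
        and the median (first time S <= 0.5) is 3."""
        curve = km_curve([1.0, 2.0, 3.0, 4.0], [0, 1, 1, 1])
        sf = dict(zip(curve.times, curve.survival))
        assert sf[1.0] == pytest.approx(1.0)
        assert sf[2.0] == pytest.approx(2 / 3)
        assert sf[3.0] == pytest.approx(1 / 3)
        assert sf[4.0] == pytest.approx(0.0)
        assert curve.median == pytest.approx(3.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(2.0, 200)
        curve = km_curve(t, np.ones_like(t))
        for q in (0.25, 0.5, 0.75):
            tq = np.quantile(t, q)
            idx = np.searchsorted(curve.times, tq, side="right") - 1
            assert curve.survival[idx] == pytest.approx((t > tq).mean(), abs=1e-12)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.allclose(curve.survival, 1.0)
        assert curve.median is None


class TestGroupHazardRatios:
    def test_twenty_sample_fixture_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        t = rng.exponential(1.0, 20)
        e = rng.binomial(1, 0.8, 20)
        e[0] = 1
        groups = np.repeat([1, 2, 3, 4], 5)
        table = group_hazard_ratios(
            pd.DataFrame({"time": t, "event": e}), groups
        )
        df = pd.DataFrame(
            {
                "T": t, "E": e,
                "g2": (groups == 2).astype(float),
                "g3": (groups == 3).astype(float),
                "g4": (groups == 4).astype(float),
            }
        )
        cph = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(
            np.log(table["hr"].to_numpy()), cph.params_.to_numpy(), atol=1e-5
        )

    def test_monotone_risk_groups_under_planted_score(self, planted_fit):
        """Quartiles of a real risk score order the marginal hazards."""
        _, bundle, fit, spec = planted_fit
        scores = compute_triune(fit, bundle.cohort, bundle.beta, spec)
        groups = quartile_groups(scores.to_numpy())
        table = group_hazard_ratios(bundle.cohort, groups)
        hrs = table["hr"].to_numpy()
        assert hrs[2] > hrs[1] > hrs[0] > 1.0

    def test_zero_event_reference_rejected(self):
        cohort = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [0, 0, 1, 1]}
        )
        with pytest.raises(ValueError, match="Group 1"):
            group_hazard_ratios(cohort, np.array([1, 1, 2, 2]))


class TestStratifiedForest:
    def test_single_level_factor_equals_unstratified_fit(self, planted_fit):
        _, bundle, fit, spec = planted_fit
        scores = compute_triune(fit, bundle.cohort, bundle.beta, spec).to_numpy()
        forest = stratified_forest(
            bundle.cohort, scores, {"all": np.repeat("everyone", len(bundle.cohort))}
        )
        assert len(forest) == 1
        direct = fit_cox(
            bundle.cohort["time"].to_numpy(),
            bundle.cohort["event"].to_numpy(),
            pd.DataFrame({"score_sd": scores / scores.std()}, index=bundle.cohort.index),
        )
        assert forest["hr_per_sd"].iloc[0] == pytest.approx(
            float(np.exp(direct.beta[0])), rel=1e-9
        )

    def test_homogeneous_planted_effect_across_strata(self, planted_fit):
        """The score's log-HR agrees across histology strata within 3 SE
        when the planted effect does not differ by stratum."""
        _, bundle, fit, spec = planted_fit
        scores = compute_triune(fit, bundle.cohort, bundle.beta, spec).to_numpy()
        forest = stratified_forest(bundle.cohort, scores, {"histology": "histology"})
        assert len(forest) == 2
        b = np.log(forest["hr_per_sd"].to_numpy())
        se = (np.log(forest["ci_high"]) - np.log(forest["ci_low"])).to_numpy() / (2 * 1.96)
        assert abs(b[0] - b[1]) <= 3 * np.hypot(se[0], se[1])

    def test_small_strata_skipped_with_warning(self, planted_fit):
        _, bundle, fit, spec = planted_fit
        scores = compute_triune(fit, bundle.cohort, bundle.beta, spec).to_numpy()
        labels = np.array(["big"] * (len(bundle.cohort) - 4) + ["tiny"] * 4)
        with pytest.warns(UserWarning, match="tiny"):
            forest = stratified_forest(bundle.cohort, scores, {"f": labels})
        assert set(forest["level"]) == {"big"}


class TestConditionalEffectSurface:
    def _synthetic_fit(self, coefs: dict) -> tuple:
        spec = ModelSpec(probes=("g1", "g2", "x"), covariates=("age",))
        terms = ["age"] + [term_name(t) for t in expand_terms(spec)]
        beta = np.array([coefs.get(t, 0.0) for t in terms])
        fit = CoxFit(
            terms=terms, beta=beta, se=np.ones_like(beta),
            cov=np.eye(len(beta)), loglik=0.0, n=10, n_events=5,
            converged=True, n_iter=1, ties="efron",
        )
        return fit, spec

    def test_no_interactions_give_flat_surface(self):
        fit, spec = self._synthetic_fit({"x": -0.002})
        surf = conditional_effect_surface(
            fit, spec, exposure_grid=[0, 20, 40], g1_grid=[30, 50, 70],
            g2_levels={"low": 40.0, "high": 60.0},
        )
        assert np.allclose(surf["hr"], np.exp(-0.002))

    def test_surface_matches_closed_form_at_grid_points(self):
        """Nine grid points against an explicit evaluation of
        b4 + b14*E + b24*g1 + b34*g2 + b124*E*g1 + b134*E*g2 +
        b234*g1*g2 + b1234*E*g1*g2."""
        coefs = {
            "x": 1e-3, "pack_years:x": -2e-5, "g1:x": 3e-5, "g2:x": -4e-5,
            "pack_years:g1:x": 5e-7, "pack_years:g2:x": -6e-7,
            "g1:g2:x": 7e-7, "pack_years:g1:g2:x": -8e-9,
        }
        fit, spec = self._synthetic_fit(coefs)
        g2v = 55.0
        surf = conditional_effect_surface(
            fit, spec, exposure_grid=[0.0, 25.0, 60.0], g1_grid=[35.0, 50.0, 65.0],
            g2_levels={"high": g2v},
        )
        for _, row in surf.iterrows():
            E, g1 = row["exposure"], row["g1"]
            expected = (
                coefs["x"] + coefs["pack_years:x"] * E + coefs["g1:x"] * g1
                + coefs["g2:x"] * g2v + coefs["pack_years:g1:x"] * E * g1
                + coefs["pack_years:g2:x"] * E * g2v + coefs["g1:g2:x"] * g1 * g2v
                + coefs["pack_years:g1:g2:x"] * E * g1 * g2v
            )
            assert row["log_hr"] == pytest.approx(expected, abs=1e-12)

    def test_pure_four_way_tilts_opposite_across_g2_levels(self):
        """With only beta_1234 < 0, the surface decreases in E*g1 for
        positive g2 and increases for negative g2 (centered planting)."""
        fit, spec = self._synthetic_fit({"pack_years:g1:g2:x": -1e-8})
        surf = conditional_effect_surface(
            fit, spec, exposure_grid=[10.0, 50.0], g1_grid=[40.0],
            g2_levels={"neg": -20.0, "pos": 20.0},
        )
        neg = surf[surf["g2_subgroup"] == "neg"].sort_values("exposure")["log_hr"].to_numpy()
        pos = surf[surf["g2_subgroup"] == "pos"].sort_values("exposure")["log_hr"].to_numpy()
        assert neg[1] > neg[0]
        assert pos[1] < pos[0]


class TestRiskScores:
    def test_risk_table_has_consistent_groups(self, planted_fit):
        _, bundle, fit, spec = planted_fit
        table = risk_scores(fit, bundle.cohort, bundle.beta, spec)
        assert set(table.columns) == {"triune", "clinical_score", "group", "clinical_group"}
        assert set(table["group"]) == {1, 2, 3, 4}
        assert len(table) == len(bundle.cohort)

    def test_triune_groups_separate_survival_better_than_clinical(self, planted_fit):
        """With a planted interaction the integrated score stratifies
        risk more sharply than the covariates-only score (log-rank on
        extreme groups)."""
        from lifelines.statistics import logrank_test

        _, bundle, fit, spec = planted_fit
        table = risk_scores(fit, bundle.cohort, bundle.beta, spec)

        def extreme_logrank(groups):
            m1 = (groups == 1).to_numpy()
            m4 = (groups == 4).to_numpy()
            t, e = bundle.cohort["time"], bundle.cohort["event"]
            return logrank_test(t[m1], t[m4], e[m1], e[m4]).test_statistic

        assert extreme_logrank(table["group"]) > extreme_logrank(table["clinical_group"])
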