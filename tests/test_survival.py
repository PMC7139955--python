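import numpy as np
import pandas as pd
import pytest

from immunosig import SimulationConfig, simulate_cohort
from immunosig.survival import (
    build_model,
    fit_cox,
    kaplan_meier,
    kaplan_meier_curve,
)

from _oracles import cox_mle_1d


class TestCoxOracle:
    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_four_subject_fixture_matches_direct_maximization(self, toy_survival, ties):
        res = fit_cox(toy_survival, ["group"], ties=ties)
        oracle = cox_mle_1d(
            toy_survival["group"].to_numpy() - toy_survival["group"].mean(),
            toy_survival["time"].to_numpy(),
            toy_survival["event"].to_numpy(),
            ties,
        )
        assert res.terms["group"].beta == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_fixtures_with_ties(self, ties, seed):
        """<= 8 subjects, tied event times included, both ties methods."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        data = pd.DataFrame(
            {
                "time": rng.integers(1, 4, size=n).astype(float),  # forces ties
                "event": rng.integers(0, 2, size=n),
                "x": rng.normal(size=n).round(2),
            }
        )
        if data["event"].sum() == 0:
            data.loc[data.index[0], "event"] = 1
        if data["x"].nunique() < 2:
            data.loc[data.index[0], "x"] += 1.0
        try:
            res = fit_cox(data, ["x"], ties=ties)
        except RuntimeError:
            pytest.skip("separated fixture")
        xc = data["x"].to_numpy() - data["x"].mean()
        oracle = cox_mle_1d(
            xc, data["time"].to_numpy(), data["event"].to_numpy(), ties
        )
        assert res.terms["x"].beta == pytest.approx(oracle, abs=1e-6)

    def test_breslow_equals_efron_when_event_times_distinct(self):
        rng = np.random.default_rng(1)
        n = 30
        data = pd.DataFrame(
            {
                "time": rng.permutation(np.arange(1, n + 1)).astype(float),
                "event": rng.integers(0, 2, size=n),
                "x": rng.normal(size=n),
            }
        )
        b = fit_cox(data, ["x"], ties="breslow").terms["x"].beta
        e = fit_cox(data, ["x"], ties="efron").terms["x"].beta
        assert b == pytest.approx(e, abs=1e-10)

    def test_matches_lifelines_multivariable(self, default_cohort):
        """Independent cross-check: Efron fit against lifelines on a
        multivariable synthetic-cohort model."""
        lifelines = pytest.importorskip("lifelines")
        tab = default_cohort.clinical
        res = fit_cox(tab, ["Z_TCT:M2TAM", "age", "stage"], ties="efron")
        df = tab[["time", "event", "Z_TCT:M2TAM", "age"]].copy()
        df["stage3"] = (tab["stage"] == "3").astype(float)
        df["stage4"] = (tab["stage"] == "4").astype(float)
        cph = lifelines.CoxPHFitter()
        cph.fit(df, "time", "event")
        assert res.terms["Z_TCT:M2TAM"].beta == pytest.approx(
            cph.params_["Z_TCT:M2TAM"], abs=1e-5
        )
        assert res.terms["age"].beta == pytest.approx(cph.params_["age"], abs=1e-5)
        assert res.terms["stage[4]"].beta == pytest.approx(
            cph.params_["stage4"], abs=1e-5
        )
        assert res.terms["Z_TCT:M2TAM"].se == pytest.approx(
            cph.standard_errors_["Z_TCT:M2TAM"], abs=1e-5
        )


class TestCoxInvariances:
    def test_covariate_shift_leaves_beta_unchanged(self, default_cohort):
        tab = default_cohort.clinical.copy()
        b1 = fit_cox(tab, ["age"]).terms["age"].beta
        tab["age"] = tab["age"] + 100.0
        b2 = fit_cox(tab, ["age"]).terms["age"].beta
        assert b1 == pytest.approx(b2, rel=1e-8)

    def test_covariate_scaling_scales_beta_inversely(self, default_cohort):
        tab = default_cohort.clinical.copy()
        b1 = fit_cox(tab, ["age"]).terms["age"].beta
        tab["age"] = tab["age"] * 10.0
        b2 = fit_cox(tab, ["age"]).terms["age"].beta
        assert b2 == pytest.approx(b1 / 10.0, rel=1e-8)

    def test_hr_and_ci_consistency(self, default_cohort):
        res = fit_cox(default_cohort.clinical, ["Z_TCT:M2TAM", "age"])
        for t in res.terms.values():
            assert t.ci_low < t.hr < t.ci_high
            assert t.hr == pytest.approx(np.exp(t.beta))
            assert 0 < t.p <= 1

    def test_errors(self, toy_survival):
        no_events = toy_survival.assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            fit_cox(no_events, ["group"])
        const = toy_survival.assign(group=1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_cox(const, ["group"])

    def test_complete_separation_detected(self):
        # events happen strictly ordered by the covariate -> monotone likelihood
        data = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 1, 1, 1],
                "x": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            }
        )
        with pytest.raises(RuntimeError, match="separation|diverging"):
            fit_cox(data, ["x"])


class TestBuildModel:
    def test_strong_cytoreduction_effect_retained(self):
        cfg = SimulationConfig(
            seed=21,
            samples_per_type=150,
            covariate_betas={
                "age": 0.015,
                "stage[3]": 0.3,
                "stage[4]": 0.6,
                "cytoreduction[Optimal]": np.log(0.4),
                "cytoreduction[Unknown]": 0.0,
            },
        )
        cohort = simulate_cohort(cfg)
        model = build_model(cohort.clinical, "TCT:M2TAM")
        assert not model.cytoreduction_dropped
        assert model.cytoreduction_p <= 0.10
        hr = model.final.terms["cytoreduction[Optimal]"].hr
        assert 0.28 <= hr <= 0.57  # true HR 0.4

    def test_drop_decision_consistent_with_joint_p(self):
        """The cytoreduction block is excluded exactly when its joint
        Wald p exceeds 0.10, on cohorts either side of the rule."""
        for seed, cyto_beta in [(22, 0.0), (23, np.log(0.4))]:
            cfg = SimulationConfig(
                seed=seed,
                samples_per_type=120,
                covariate_betas={
                    "age": 0.015,
                    "stage[3]": 0.3,
                    "stage[4]": 0.6,
                    "cytoreduction[Optimal]": cyto_beta,
                    "cytoreduction[Unknown]": 0.0,
                },
            )
            cohort = simulate_cohort(cfg)
            model = build_model(cohort.clinical, "TCT:M2TAM")
            assert model.cytoreduction_dropped == (model.cytoreduction_p > 0.10)
            if model.cytoreduction_dropped:
                assert "cytoreduction" not in {
                    t.block for t in model.final.terms.values()
                }
                assert any("not included" in n for n in model.final.notes)

    def test_missing_signature_rejected(self, default_cohort):
        with pytest.raises(KeyError):
            build_model(default_cohort.clinical, "NOPE")

    def test_signature_hr_reported_on_standardized_scale(self, default_cohort):
        model = build_model(default_cohort.clinical, "TCT:M2TAM")
        t = model.final.terms["Z_TCT:M2TAM"]
        # generating HR is 0.6 per standardized unit
        assert 0.45 <= t.hr <= 0.8


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # times 1+ (censored), 2 (event), 3+ (censored)
        c = kaplan_meier_curve(
            np.array([1.0, 2.0, 3.0]), np.array([0, 1, 0]), group="g"
        )
        assert list(c.times) == [2.0]
        assert c.at_risk[0] == 2
        assert c.survival[0] == pytest.approx(0.5)
        assert c.survival_at(1.9) == 1.0
        assert c.survival_at(10.0) == pytest.approx(0.5)

    def test_no_events_flat_at_one(self):
        c = kaplan_meier_curve(np.array([1.0, 2.0]), np.array([0, 0]))
        assert len(c.times) == 0
        assert c.survival_at(5.0) == 1.0

    def test_all_events_steps_by_one_over_n(self):
        n = 5
        c = kaplan_meier_curve(np.arange(1.0, n + 1), np.ones(n))
        np.testing.assert_allclose(c.survival, 1 - np.arange(1, n + 1) / n)

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(2.0, size=40)
        c = kaplan_meier_curve(t, np.ones(40))
        for q in [0.5, 1.0, 2.0, 4.0]:
            assert c.survival_at(q) == pytest.approx((t > q).mean())

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t = rng.exponential(2.0, size=60)
        e = rng.integers(0, 2, size=60)
        e[0] = 1
        c = kaplan_meier_curve(t, e)
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(t, e)
        for tt in c.times:
            assert c.survival_at(tt) == pytest.approx(
                float(kmf.survival_function_at_times(tt).iloc[0]), abs=1e-10
            )

    def test_two_group_curves_and_hr(self, default_cohort):
        tab = default_cohort.clinical
        z = tab["Z_TCT:M2TAM"]
        groups = pd.Series(
            np.where(z > z.median(), "High", "Low"), index=tab.index
        )
        curves, fit = kaplan_meier(tab, groups)
        assert set(curves) == {"High", "Low"}
        # protective signature: High group has better survival
        assert fit.terms["group[High]"].hr < 1.0
        for c in curves.values():
            assert np.all(np.diff(c.survival) <= 1e-12)
            assert np.all((c.survival >= 0) & (c.survival <= 1))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kaplan_meier_curve(np.array([]), np.array([]))
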