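import numpy as np
import pandas as pd
import pytest

from curecorrect import (Cohort, CureParams, LifeTable, MixtureCureModel,
                         breast_scenario, build_life_table, generate_cohort)
from curecorrect.estimation import fit, initial_values


def single_cell_table(d, l, s_exp, t0=0.0, t1=1.0, x=0.0):
    return LifeTable(pd.DataFrame({
        "stratum": ["s"], "t_start": [t0], "t_end": [t1],
        "n": [l], "d": [d], "w": [0.0], "l": [l],
        "s_obs": [1 - d / l], "s_exp": [s_exp],
        "mean_age": [60.0], "x": [x],
    }))


class TestIndividualLoglik:
    def test_single_censored_record_value(self, pop):
        # ln RS(5) + alpha * ln S*(5|60) with Breast truths and alpha=1.2
        coh = Cohort(pd.DataFrame({"age": [60.0], "time": [5.0], "event": [0]}))
        m = MixtureCureModel(coh, pop=pop, variant="corrected")
        p = CureParams.from_pi60(0.7, beta=-0.15, lambda_=0.1, gamma_=1.1,
                                 delta=0.0, alpha=1.2)
        assert m.loglike(m.working_from_params(p)) == pytest.approx(
            -0.1681, abs=2e-4)

    def test_censored_contribution_has_no_hazard_term(self, pop):
        coh = Cohort(pd.DataFrame({"age": [60.0], "time": [5.0], "event": [0]}))
        m = MixtureCureModel(coh, pop=pop)
        p = CureParams.from_pi60(0.7, lambda_=0.1, gamma_=1.1, alpha=1.0)
        expected = (np.log(0.7 + 0.3 * np.exp(-0.1 * 5 ** 1.1))
                    + np.log(pop.survival(60.0, 5.0)))
        assert m.loglike(m.working_from_params(p)) == pytest.approx(
            expected, rel=1e-10)

    def test_corrected_at_alpha_one_equals_conventional(self, pop):
        rng = np.random.default_rng(0)
        coh = generate_cohort(breast_scenario(alpha=1.0, n=300), rng)
        mc = MixtureCureModel(coh, pop=pop, variant="corrected")
        mv = MixtureCureModel(coh, pop=pop, variant="conventional",
                              keep_constant_terms=True)
        for pi60 in (0.3, 0.7):
            p = CureParams.from_pi60(pi60, beta=-0.2, lambda_=0.2,
                                     gamma_=0.9, delta=0.1, alpha=1.0)
            assert mc.loglike(mc.working_from_params(p)) == pytest.approx(
                mv.loglike(mv.working_from_params(p)), rel=1e-12)

    def test_event_at_time_zero_uses_floor(self, pop):
        coh = Cohort(pd.DataFrame({"age": [60.0], "time": [0.0], "event": [1]}))
        m = MixtureCureModel(coh, pop=pop)
        p = CureParams.from_pi60(0.7, lambda_=0.1, gamma_=1.1, alpha=1.0)
        assert np.isfinite(m.loglike(m.working_from_params(p)))


class TestGroupedLoglik:
    def test_binomial_cell_value(self):
        # d=2, l=10, predicted p=0.8 -> 2 ln 0.2 + 8 ln 0.8
        lt = single_cell_table(d=2.0, l=10.0, s_exp=0.8)
        m = MixtureCureModel(lt, variant="corrected")
        # lambda tiny => model interval RS ratio ~ 1, so p = s_exp^alpha = 0.8
        p = CureParams.from_pi60(0.5, lambda_=1e-10, gamma_=1.0, alpha=1.0)
        assert m.loglike(m.working_from_params(p)) == pytest.approx(
            2 * np.log(0.2) + 8 * np.log(0.8), abs=1e-6)

    def test_exact_dialect_nests_conventional_at_alpha_one(self, pop):
        coh = generate_cohort(breast_scenario(alpha=1.0, n=2000, seed=4))
        lt = build_life_table(coh, pop=pop)
        mc = MixtureCureModel(lt, variant="corrected", dialect="exact")
        mv = MixtureCureModel(lt, variant="conventional", dialect="exact")
        p = CureParams.from_pi60(0.6, beta=-0.1, lambda_=0.15, gamma_=1.0,
                                 delta=0.0, alpha=1.0)
        assert mc.loglike(mc.working_from_params(p)) == pytest.approx(
            mv.loglike(mv.working_from_params(p)), rel=1e-12)

    def test_dialects_agree_to_first_order(self):
        # |r * s^alpha - (r + alpha ln s)| small near survival 1
        a = np.linspace(0.5, 2.0, 7)[None, None, :]
        for s_min, bound in ((0.95, 0.01), (0.98, 0.003)):
            r = np.linspace(s_min, 1.0, 21)[:, None, None]
            s = np.linspace(s_min, 1.0, 21)[None, :, None]
            exact = r * s ** a
            printed = r + a * np.log(s)
            assert np.max(np.abs(exact - printed)) <= bound

    def test_missing_expected_survival_raises(self):
        lt = single_cell_table(d=2.0, l=10.0, s_exp=np.nan)
        with pytest.raises(ValueError, match="s_exp"):
            MixtureCureModel(lt)


class TestInitialValues:
    def test_plateau_sets_cure_fraction(self, flat_pop):
        # 30 deaths in year one, 70 survivors censored at the end: RS
        # plateau 0.7 and no late deaths
        df = pd.DataFrame({
            "age": 60.0,
            "time": np.r_[np.full(30, 0.5), np.full(70, 5.0)],
            "event": np.r_[np.ones(30), np.zeros(70)]})
        lt = build_life_table(Cohort(df), age_breaks=(40, 75),
                              max_followup=5.0, pop=flat_pop)
        init = initial_values(lt)
        assert init.pi60 == pytest.approx(0.7, abs=1e-6)

    def test_extreme_plateau_clamped(self, flat_pop):
        df = pd.DataFrame({
            "age": 60.0,
            "time": np.r_[np.full(1, 0.5), np.full(99, 5.0)],
            "event": np.r_[np.ones(1), np.zeros(99)]})
        lt = build_life_table(Cohort(df), age_breaks=(40, 75),
                              max_followup=5.0, pop=flat_pop)
        assert initial_values(lt).pi60 == pytest.approx(0.95)

    def test_no_deaths_is_degenerate(self, flat_pop):
        df = pd.DataFrame({"age": 60.0, "time": 5.0, "event": 0},
                          index=range(20))
        lt = build_life_table(Cohort(df), age_breaks=(40, 75),
                              max_followup=5.0, pop=flat_pop)
        with pytest.raises(ValueError, match="no deaths"):
            initial_values(lt)

    @pytest.mark.parametrize("preset_alpha", [0.8, 1.2, 2.0])
    def test_finite_for_scenario_presets(self, pop, preset_alpha):
        coh = generate_cohort(breast_scenario(alpha=preset_alpha, n=2000,
                                              seed=8))
        lt = build_life_table(coh, pop=pop)
        init = initial_values(lt)
        assert np.isfinite([init.beta0, init.lambda_, init.gamma_]).all()


class TestFit:
    def test_grouped_fit_recovers_truth(self, pop):
        cfg = breast_scenario(alpha=1.2, n=20_000, seed=12)
        lt = build_life_table(generate_cohort(cfg), pop=pop)
        res = fit(lt, pop=pop, variant="corrected")
        assert res.converged
        ci = res.conf_int()
        assert abs(ci.loc["alpha", "estimate"] - 1.2) < 3 * ci.loc["alpha", "se"]
        assert abs(ci.loc["pi_60", "estimate"] - 0.7) < 3 * ci.loc["pi_60", "se"]
        assert (ci["lower"] < ci["estimate"]).all()
        assert (ci["estimate"] < ci["upper"]).all()

    def test_individual_and_grouped_agree(self, pop):
        cfg = breast_scenario(alpha=1.5, n=10_000, seed=3)
        coh = generate_cohort(cfg)
        lt = build_life_table(coh, pop=pop)
        r_grp = fit(lt, pop=pop)
        r_ind = fit(coh, pop=pop)
        a_g = r_grp.conf_int().loc["alpha"]
        a_i = r_ind.conf_int().loc["alpha"]
        tol = 3 * max(a_g["se"], a_i["se"])
        assert abs(a_g["estimate"] - a_i["estimate"]) <= tol

    def test_summary_mentions_key_fields(self, pop):
        cfg = breast_scenario(alpha=1.0, n=3000, seed=6)
        res = fit(build_life_table(generate_cohort(cfg), pop=pop), pop=pop)
        text = res.summary()
        for token in ("alpha", "pi_60", "log-likelihood", "converged"):
            assert token in text

    def test_no_cure_variant_fits(self, pop):
        # no-cure comparison variant: pi = 0, alpha kept free
        from curecorrect import lung_scenario
        cfg = lung_scenario(alpha=1.5, n=5000, seed=9, pi60=0.02)
        lt = build_life_table(generate_cohort(cfg), pop=pop)
        m = MixtureCureModel(lt, variant="corrected_no_cure")
        res = m.fit()
        assert res.converged
        ci = res.conf_int()
        assert "pi_60" not in ci.index and "beta" not in ci.index
        assert {"alpha", "lambda", "gamma", "delta"} <= set(ci.index)
        # nesting: equals the full corrected model with the cured
        # component switched off (beta0 -> -inf)
        full = MixtureCureModel(lt, variant="corrected")
        p = res.params
        w_full = np.array([-40.0, 0.0, np.log(p.lambda_), np.log(p.gamma_),
                           p.delta, np.log(p.alpha)])
        assert full.loglike(w_full) == pytest.approx(res.llf, rel=1e-9)

    def test_identity_link_fit(self, pop):
        cfg = breast_scenario(alpha=1.2, n=10_000, seed=14)
        lt = build_life_table(generate_cohort(cfg), pop=pop)
        res = fit(lt, pop=pop, link="identity")
        assert res.converged
        # identity-link pi60 comparable with the logistic truth
        assert res.conf_int().loc["pi_60", "estimate"] == pytest.approx(
            0.7, abs=0.1)

    def test_result_serializes(self, pop):
        import json
        cfg = breast_scenario(alpha=1.0, n=2000, seed=2)
        res = fit(build_life_table(generate_cohort(cfg), pop=pop), pop=pop)
        payload = json.dumps(res.to_dict())
        assert "loglik" in payload
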