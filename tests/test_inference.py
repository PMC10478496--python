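"""Grouping, gamma pinning, MCMC fitting, DIC and the selection rule."""

import dataclasses

import numpy as np
import pytest

from microhab.data_model import (
    HabitatCategory,
    ObservationGroup,
    Parity,
    RANDOM_GROUP,
    Sex,
    SiteObservation,
)
from microhab.inference import (
    DICResult,
    MCMCConfig,
    ModelScheme,
    NINE_SCHEMES,
    PriorSpec,
    assign_groups,
    compute_dic,
    determine_gamma_mode,
    fit_all_models,
    fit_zoib,
    fit_zoib_values,
    posterior_summary,
    scheme_complexity,
    select_model,
)
from microhab.synthetic import (
    HabitatScenario,
    generate_habitat_dataset,
    preset_scenario,
)
from microhab.zoib import GammaMode, ZOIBParams

C = HabitatCategory


def obs(site_id, group, value, category=C.GRASS):
    return SiteObservation(site_id, group, {category: value})


LIZ_F_OVI = ObservationGroup("lizard", Sex.FEMALE, Parity.OVIPAROUS)
LIZ_M_VIV = ObservationGroup("lizard", Sex.MALE, Parity.VIVIPAROUS)


class TestSchemes:
    def test_exactly_nine_schemes_without_null_variable(self):
        assert len(NINE_SCHEMES) == 9
        assert ModelScheme("null", "shared") in NINE_SCHEMES
        with pytest.raises(ValueError):
            ModelScheme("null", "variable")

    def test_complexity_ordering(self):
        order = [
            ModelScheme("null"),
            ModelScheme("lizard", "shared"),
            ModelScheme("lizard", "variable"),
            ModelScheme("sex", "shared"),
            ModelScheme("parity_sex", "shared"),
            ModelScheme("parity_sex", "variable"),
        ]
        keys = [scheme_complexity(s) for s in order]
        assert keys == sorted(keys)
        # sex and parity are equal-complexity
        assert scheme_complexity(ModelScheme("sex", "shared")) == scheme_complexity(
            ModelScheme("parity", "shared")
        )


class TestAssignGroups:
    def test_null_pools_everything(self):
        observations = [obs("a", RANDOM_GROUP, 0.1), obs("b", LIZ_F_OVI, 0.2)]
        a = assign_groups(observations, ModelScheme("null"))
        assert a.mean_names == ["all"]
        assert np.all(a.mean_idx == 0)

    def test_parity_sex_parameterises_empty_groups(self):
        observations = [
            obs("a", RANDOM_GROUP, 0.1),
            obs("b", LIZ_F_OVI, 0.2),
            obs("c", LIZ_M_VIV, 0.3),
        ]
        a = assign_groups(observations, ModelScheme("parity_sex", "shared"))
        assert len(a.mean_names) == 5  # all five groups exist
        assert len(set(a.mean_idx)) == 3  # only three are populated

    def test_variable_precision_always_splits_random_vs_lizard(self):
        observations = [obs("a", RANDOM_GROUP, 0.1), obs("b", LIZ_F_OVI, 0.2)]
        a = assign_groups(observations, ModelScheme("lizard", "variable"))
        assert a.phi_names == ["random", "lizard"]
        assert list(a.phi_idx) == [0, 1]
        # under the lizard grouping, mean and precision groups coincide
        assert list(a.mean_idx) == list(a.phi_idx)
        a_sex = assign_groups(observations, ModelScheme("sex", "variable"))
        assert a_sex.phi_names == ["random", "lizard"]


class TestGammaMode:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.0, 0.2, 0.4], GammaMode.FIXED_ZERO),
            ([0.2, 1.0], GammaMode.FIXED_ONE),
            ([0.0, 0.5, 1.0], GammaMode.FREE),
        ],
    )
    def test_modes(self, values, expected):
        assert determine_gamma_mode(values) == expected

    def test_no_atoms_warns_and_fixes_zero(self):
        with pytest.warns(UserWarning, match="no atoms"):
            assert determine_gamma_mode([0.2, 0.5]) == GammaMode.FIXED_ZERO

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            determine_gamma_mode([])


class TestSelectModel:
    def test_simpler_model_within_two_preferred(self):
        table = {
            ModelScheme("null"): 100.0,
            ModelScheme("lizard", "shared"): 99.0,
            ModelScheme("sex", "shared"): 140.0,
        }
        result = select_model(table)
        assert result.chosen == ModelScheme("null")
        assert result.rationale == "simpler_within_2"

    def test_exactly_two_apart_is_not_within(self):
        # "differing by less than two" is strict
        table = {ModelScheme("null"): 101.0, ModelScheme("lizard", "shared"): 99.0}
        assert select_model(table).chosen == ModelScheme("lizard", "shared")

    def test_order_invariance(self):
        table = {
            ModelScheme("lizard", "shared"): 72.1,
            ModelScheme("parity", "shared"): 73.5,
            ModelScheme("parity_sex", "shared"): 72.9,
            ModelScheme("null"): 111.1,
        }
        forward = select_model(dict(table))
        backward = select_model(dict(reversed(list(table.items()))))
        assert forward.chosen == backward.chosen == ModelScheme("lizard", "shared")

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_model({})

    def test_accepts_dic_results(self):
        table = {
            ModelScheme("null"): DICResult(d_bar=101.0, d_hat=100.0),
            ModelScheme("lizard", "shared"): DICResult(d_bar=120.0, d_hat=119.0),
        }
        assert select_model(table).chosen == ModelScheme("null")


class TestDICResult:
    def test_identities(self):
        # two draws with deviances 10 and 14 average to 12; with a plug-in
        # deviance of 11 this gives pD = 1 and DIC = 13
        r = DICResult(d_bar=12.0, d_hat=11.0)
        assert r.p_d == 1.0
        assert r.dic == 13.0

    def test_constant_shift_moves_dic_not_pd(self):
        r = DICResult(d_bar=12.0, d_hat=11.0)
        shifted = DICResult(d_bar=12.0 + 5.0, d_hat=11.0 + 5.0)
        assert shifted.p_d == r.p_d
        assert shifted.dic == r.dic + 5.0


class TestFitZoib:
    def test_determinism(self, zoib_fixture_values, single_group_assignment, fast_mcmc):
        y, _ = zoib_fixture_values
        assign = single_group_assignment(len(y))
        scheme = ModelScheme("null")
        f1 = fit_zoib_values(y, assign, scheme, config=fast_mcmc)
        f2 = fit_zoib_values(y, assign, scheme, config=fast_mcmc)
        assert np.array_equal(f1.alpha_logit, f2.alpha_logit)
        assert np.array_equal(f1.deviance_draws, f2.deviance_draws)

    def test_retained_draw_count(self, zoib_fixture_values, single_group_assignment):
        y, _ = zoib_fixture_values
        config = MCMCConfig(chains=3, iterations=2000, burn_in=500, thin=5, seed=0)
        fit = fit_zoib_values(y, single_group_assignment(len(y)),
                              ModelScheme("null"), config=config)
        assert fit.n_retained == config.n_retained == 3 * 1500 // 5

    def test_all_zero_data_concentrates_alpha_near_one(self, single_group_assignment,
                                                       fast_mcmc):
        y = np.zeros(100)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_zoib_values(
                y, single_group_assignment(100), ModelScheme("null"),
                config=fast_mcmc, gamma_mode=GammaMode.FIXED_ZERO,
            )
        assert fit.natural_draws("alpha").mean() > 0.95

    def test_gamma_mode_data_conflicts_rejected(self, single_group_assignment):
        y = np.array([0.0, 0.5, 1.0])
        with pytest.raises(ValueError, match="ones are present"):
            fit_zoib_values(y, single_group_assignment(3), ModelScheme("null"),
                            gamma_mode=GammaMode.FIXED_ZERO)

    def test_empty_groups_keep_their_prior(self, fast_mcmc):
        # only random and oviparous-female sites: the three unpopulated groups'
        # alpha draws should be prior draws (sd ~ sqrt(1000) on the logit scale)
        observations = [obs(f"r{i}", RANDOM_GROUP, v) for i, v in
                        enumerate([0.0, 0.2, 0.4, 0.6, 0.3] * 6)]
        observations += [obs(f"l{i}", LIZ_F_OVI, v) for i, v in
                         enumerate([0.0, 0.1, 0.5, 0.7, 0.2] * 6)]
        fit = fit_zoib(observations, C.GRASS, ModelScheme("parity_sex", "shared"),
                       config=fast_mcmc)
        names = fit.group_names
        empty = [names.index("viviparous_male"), names.index("viviparous_female")]
        populated = [names.index("random"), names.index("oviparous_female")]
        draws = fit.alpha_logit.reshape(-1, len(names))
        for j in empty:
            assert draws[:, j].std() > 10.0  # ~ prior sd 31.6
        for j in populated:
            assert draws[:, j].std() < 3.0

    @pytest.mark.parametrize("scheme", NINE_SCHEMES, ids=str)
    def test_parameter_recovery_across_all_schemes(self, scheme, fast_mcmc):
        """Posterior means land within 0.08 of the generating alpha and mu
        for data simulated from the scheme itself (n=150 per group)."""
        groups = scheme.mean_groups
        mus = np.linspace(0.35, 0.7, len(groups))
        params = {
            g: ZOIBParams(alpha=0.3, gamma=0.0, mu=float(mus[j]), phi=10.0,
                          gamma_fixed=GammaMode.FIXED_ZERO)
            for j, g in enumerate(groups)
        }
        scenario = HabitatScenario(
            scheme=scheme,
            params={C.GRASS: params},
            n_per_group={g: 150 for g in groups},
            seed=1234,
        )
        observations = generate_habitat_dataset(scenario)
        fit = fit_zoib(observations, C.GRASS, scheme, config=fast_mcmc)
        alpha = fit.natural_draws("alpha").reshape(-1, len(groups)).mean(axis=0)
        mu = fit.natural_draws("mu").reshape(-1, len(groups)).mean(axis=0)
        for j, g in enumerate(groups):
            assert abs(alpha[j] - 0.3) < 0.08, (g, alpha[j])
            assert abs(mu[j] - mus[j]) < 0.08, (g, mu[j])


class TestComputeDic:
    def test_identities_and_recompute(self, grass_observations, fast_mcmc):
        fit = fit_zoib(grass_observations, C.GRASS, ModelScheme("lizard", "shared"),
                       config=fast_mcmc)
        dic = compute_dic(fit)
        assert dic.dic == dic.d_bar + dic.p_d
        assert dic.p_d == dic.d_bar - dic.d_hat
        # recomputing the plug-in deviance from the observations agrees
        dic2 = compute_dic(fit, grass_observations, C.GRASS)
        assert dic2.d_hat == pytest.approx(dic.d_hat)

    def test_requires_deviance_draws(self, grass_observations, fast_mcmc):
        fit = fit_zoib(grass_observations, C.GRASS, ModelScheme("null"),
                       config=fast_mcmc)
        fit.deviance_draws = np.empty((0,))
        with pytest.raises(ValueError, match="deviance"):
            compute_dic(fit)


class TestFitAllModels:
    def test_nine_entries_and_shared_gamma_mode(self, grass_observations):
        config = MCMCConfig(chains=2, iterations=1500, burn_in=500, seed=5)
        comp = fit_all_models(grass_observations, C.GRASS, config=config,
                              keep_fits=True)
        assert set(comp.dic_table) == set(NINE_SCHEMES)
        assert all(f.gamma_mode == comp.gamma_mode for f in comp.fits.values())

    def test_strong_group_difference_beats_null(self, fast_mcmc):
        """With mu 0.70 vs 0.55 at n=200/group the lizard model should beat
        the null decisively in nearly every replicate."""
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            observations = generate_habitat_dataset(
                preset_scenario("grass-lizard", seed=500 + rep)
            )
            config = dataclasses.replace(fast_mcmc, seed=rep)
            dic = {
                s: compute_dic(fit_zoib(observations, C.GRASS, s, config=config))
                for s in (ModelScheme("null"), ModelScheme("lizard", "shared"))
            }
            if dic[ModelScheme("null")].dic - dic[ModelScheme("lizard", "shared")].dic > 10:
                wins += 1
        assert wins >= 9

    def test_null_data_prefers_null_or_close(self):
        """Data generated with no group structure: the null model should sit
        within 2 DIC of the best model in most replicates."""
        config = MCMCConfig(chains=2, iterations=1500, burn_in=500, seed=0)
        null_params = ZOIBParams(alpha=0.3, gamma=0.0, mu=0.5, phi=8.0,
                                 gamma_fixed=GammaMode.FIXED_ZERO)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            scenario = HabitatScenario(
                scheme=ModelScheme("lizard", "shared"),
                params={C.GRASS: {"random": null_params, "lizard": null_params}},
                n_per_group={"random": 150, "lizard": 150},
                seed=900 + rep,
            )
            observations = generate_habitat_dataset(scenario)
            comp = fit_all_models(observations, C.GRASS,
                                  config=dataclasses.replace(config, seed=rep),
                                  keep_fits=False)
            dics = comp.dic_values()
            if dics[ModelScheme("null")] - min(dics.values()) < 2.0:
                hits += 1
        assert hits >= 8


class TestPosteriorSummary:
    def test_natural_scale_mean_is_not_backtransformed_mean(
        self, single_group_assignment
    ):
        """By Jensen's inequality E[expit(x)] != expit(E[x]) on a skewed
        posterior; the summary must average the back-transformed draws."""
        from scipy.special import expit

        y = np.concatenate([np.zeros(3), np.full(2, 0.4)])  # tiny, skewed
        config = MCMCConfig(chains=2, iterations=4000, burn_in=1000, seed=2)
        fit = fit_zoib_values(y, single_group_assignment(5), ModelScheme("null"),
                              config=config, gamma_mode=GammaMode.FIXED_ZERO)
        summary = posterior_summary(fit)
        row = summary[(summary.parameter == "alpha") & (summary.group == "all")]
        natural_mean = float(row["mean"].iloc[0])
        wrong = float(expit(fit.alpha_logit.mean()))
        assert natural_mean == pytest.approx(
            float(expit(fit.alpha_logit).mean()), rel=1e-12
        )
        assert abs(natural_mean - wrong) > 1e-4

    def test_interval_covers_truth_in_most_replicates(self, single_group_assignment):
        """95% equal-tailed intervals for alpha and mu cover the generating
        values in nearly all of 20 replicates (n=50 each)."""
        from microhab.zoib import zoib_sample

        truth = ZOIBParams(alpha=0.3, gamma=0.0, mu=0.6, phi=8.0,
                           gamma_fixed=GammaMode.FIXED_ZERO)
        config = MCMCConfig(chains=2, iterations=3000, burn_in=1000, seed=0)
        covered = 0
        for rep in range(20):
            y = zoib_sample(50, truth, seed=3000 + rep)
            fit = fit_zoib_values(
                y, single_group_assignment(50), ModelScheme("null"),
                config=dataclasses.replace(config, seed=rep),
                gamma_mode=GammaMode.FIXED_ZERO,
            )
            summary = posterior_summary(fit).set_index(["parameter", "group"])
            ok = (
                summary.loc[("alpha", "all"), "q2.5"] <= truth.alpha
                <= summary.loc[("alpha", "all"), "q97.5"]
                and summary.loc[("mu", "all"), "q2.5"] <= truth.mu
                <= summary.loc[("mu", "all"), "q97.5"]
            )
            covered += ok
        assert covered >= 17


class TestPriorSpec:
    def test_variance_vs_precision_reading(self):
        assert PriorSpec().sd("alpha") == pytest.approx(np.sqrt(1000))
        assert PriorSpec(interpret_as="precision").sd("alpha") == pytest.approx(
            np.sqrt(1 / 1000)
        )

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(v_mu=0.0)
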