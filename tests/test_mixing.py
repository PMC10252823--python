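"""Mixing-model inference, MCMC diagnostics and posterior summaries."""

import numpy as np
import pytest
from scipy import stats

from isoweb.errors import ConfigError, InputError
from isoweb.mixing import (DietMixingModel, McmcSettings, fit_mixing_model,
                           gelman_rubin, geweke, summarize_posterior)

WELL_SEPARATED_MU = np.array([[-29.0, 1.0], [-21.0, 4.5],
                              [-9.5, 8.0], [-15.0, 11.5]])
WELL_SEPARATED_SD = np.full((4, 2), 0.7)


class TestMcmcSettings:
    def test_published_profile_is_default(self):
        s = McmcSettings()
        assert (s.iterations, s.burn_in, s.thin) == (300_000, 200_000, 100)

    @pytest.mark.parametrize("kwargs", [
        {"burn_in": 300_000},                        # burn_in >= iterations
        {"thin": 0},
        {"chains": 1},
        {"iterations": 30_000, "burn_in": 25_000, "thin": 100},  # <500 draws
    ])
    def test_invalid_settings_raise(self, kwargs):
        with pytest.raises(ConfigError):
            McmcSettings(**kwargs)


class TestDietMixingModel:
    def test_single_source_trivial(self):
        m = DietMixingModel().fit(np.zeros((5, 2)), [[-20.0, 3.0]],
                                  [[0.5, 0.5]])
        assert np.allclose(m.draws_, 1.0)
        assert m.medians_[0] == 1.0

    def test_recovery_with_separated_sources(self):
        # truth p = (0.6, 0.2, 0.1, 0.1), n = 20 consumers
        rng = np.random.default_rng(0)
        p_true = np.array([0.6, 0.2, 0.1, 0.1])
        x = p_true @ WELL_SEPARATED_MU + 0.5 * rng.standard_normal((20, 2))
        m = DietMixingModel(settings=McmcSettings.desk(seed=1)).fit(
            x, WELL_SEPARATED_MU, WELL_SEPARATED_SD)
        assert np.all(np.abs(m.medians_ - p_true) <= 0.10)
        assert np.all(m.rhat_ < 1.1)

    def test_draws_stay_on_simplex(self):
        rng = np.random.default_rng(1)
        x = np.array([0.25, 0.25, 0.25, 0.25]) @ WELL_SEPARATED_MU \
            + rng.standard_normal((10, 2))
        m = DietMixingModel(settings=McmcSettings.desk(seed=2)).fit(
            x, WELL_SEPARATED_MU, WELL_SEPARATED_SD)
        assert np.all(m.draws_ >= 0)
        assert np.allclose(m.draws_.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((m.ci95_[:, 0] <= m.medians_)
                      & (m.medians_ <= m.ci95_[:, 1]))

    def test_prior_recovery_when_likelihood_uninformative(self):
        # identical source means with zero variance make the likelihood
        # independent of p; marginals must then match Beta(1, K-1)
        mu = np.tile([-20.0, 3.0], (4, 1))
        sd = np.zeros((4, 2))
        rng = np.random.default_rng(30)
        x = mu[0] + rng.standard_normal((8, 2))
        m = DietMixingModel(settings=McmcSettings.desk(seed=3),
                            tdf_sd=(0.0, 0.0)).fit(x, mu, sd)
        q = np.quantile(m.draws_[:, 0], [0.25, 0.5, 0.75])
        expected = stats.beta(1, 3).ppf([0.25, 0.5, 0.75])
        assert np.allclose(q, expected, atol=0.05)

    def test_chain_count_invariance(self):
        rng = np.random.default_rng(4)
        p_true = np.array([0.5, 0.3, 0.1, 0.1])
        x = p_true @ WELL_SEPARATED_MU + rng.standard_normal((15, 2))
        med = []
        for chains in (3, 6):
            s = McmcSettings(chains=chains, iterations=30_000,
                             burn_in=10_000, thin=20, seed=5)
            m = DietMixingModel(settings=s).fit(
                x, WELL_SEPARATED_MU, WELL_SEPARATED_SD)
            med.append(m.medians_)
        assert np.allclose(med[0], med[1], atol=0.02)

    def test_acceptance_rate_in_target_band(self):
        rng = np.random.default_rng(6)
        x = np.array([0.4, 0.3, 0.2, 0.1]) @ WELL_SEPARATED_MU \
            + rng.standard_normal((12, 2))
        m = DietMixingModel(settings=McmcSettings.desk(seed=7)).fit(
            x, WELL_SEPARATED_MU, WELL_SEPARATED_SD)
        assert 0.15 < m.acceptance_ < 0.45

    def test_input_validation(self):
        with pytest.raises(InputError):
            DietMixingModel().fit(np.zeros((1, 2)), WELL_SEPARATED_MU,
                                  WELL_SEPARATED_SD)
        with pytest.raises(InputError):
            DietMixingModel().fit(np.zeros((5, 3)), WELL_SEPARATED_MU,
                                  WELL_SEPARATED_SD)

    def test_functional_wrapper_matches_estimator(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        x = np.array([0.4, 0.3, 0.2, 0.1]) @ WELL_SEPARATED_MU \
            + rng.standard_normal((10, 2))
        consumers = pd.DataFrame(x, columns=["d13c_corr", "d15n_corr"])
        sources = pd.DataFrame({
            "source": list("abcd"),
            "mu13": WELL_SEPARATED_MU[:, 0],
            "mu15": WELL_SEPARATED_MU[:, 1],
            "sd13": WELL_SEPARATED_SD[:, 0],
            "sd15": WELL_SEPARATED_SD[:, 1]})
        res = fit_mixing_model(consumers, sources,
                               settings=McmcSettings.desk(seed=9),
                               group=("A", "rainy", "fish"))
        m = DietMixingModel(settings=McmcSettings.desk(seed=9)).fit(
            x, WELL_SEPARATED_MU, WELL_SEPARATED_SD, sources=list("abcd"))
        assert np.allclose(res.medians, m.medians_)
        assert res.group == ("A", "rainy", "fish")
        assert res.summary()["source"].tolist() == list("abcd")


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        r = gelman_rubin(rng.standard_normal((4, 1000)))
        assert 0.99 <= r <= 1.05

    def test_separated_chains_large(self):
        rng = np.random.default_rng(1)
        chains = np.vstack([rng.standard_normal(1000),
                            10.0 + rng.standard_normal(1000)])
        assert gelman_rubin(chains) > 3.0

    def test_duplicated_chains_at_most_one(self):
        rng = np.random.default_rng(2)
        c = rng.standard_normal(500)
        assert gelman_rubin(np.vstack([c, c])) <= 1.0

    def test_constant_chains_undefined(self):
        with pytest.warns(UserWarning, match="zero within-chain"):
            assert np.isnan(gelman_rubin(np.ones((3, 100))))


class TestGeweke:
    def test_iid_calibration(self):
        rng = np.random.default_rng(3)
        z = [geweke(rng.standard_normal(10_000)) for _ in range(100)]
        assert np.mean(np.abs(z) < 3.0) >= 0.99

    def test_trending_chain_flagged(self):
        assert abs(geweke(np.arange(10_000, dtype=float))) > 10.0

    def test_constant_chain_zero_with_flag(self):
        with pytest.warns(UserWarning, match="constant"):
            assert geweke(np.ones(500)) == 0.0

    def test_short_chain_raises(self):
        with pytest.raises(InputError):
            geweke(np.arange(50.0))


class TestSummarizePosterior:
    def test_constant_draws_zero_width(self):
        draws = np.tile([0.5, 0.5], (600, 1))
        med, ci = summarize_posterior(draws)
        assert np.allclose(med, 0.5)
        assert np.allclose(ci[:, 0], ci[:, 1])

    def test_uniform_dirichlet_matches_beta(self):
        rng = np.random.default_rng(5)
        draws = rng.dirichlet([1.0, 1.0], size=20_000)
        med, ci = summarize_posterior(draws)
        assert np.allclose(med, 0.5, atol=0.02)
        assert np.allclose(ci[:, 0], 0.025, atol=0.01)
        assert np.allclose(ci[:, 1], 0.975, atol=0.01)

    def test_interval_endpoints_within_simplex(self):
        rng = np.random.default_rng(6)
        draws = rng.dirichlet([2.0, 3.0, 4.0], size=1000)
        _, ci = summarize_posterior(draws)
        assert (ci >= 0).all() and (ci <= 1).all()

    def test_too_few_draws_raises(self):
        with pytest.raises(InputError):
            summarize_posterior(np.ones((100, 2)) * 0.5)
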