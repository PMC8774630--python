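"""Scenario generators and the replication harness."""

import numpy as np
import pytest
from scipy import stats

from csde import (EMConfig, PenaltySpec, Scenario, gaussian_scenario,
                  lowdim_scenarios, poisson_scenario, run_experiment)


class TestGaussianScenario:
    @pytest.mark.parametrize("W", [76, 81, 131, 321])
    def test_true_weights_on_simplex_with_8_components(self, W):
        s = gaussian_scenario(W)
        assert s.beta_star.sum() == pytest.approx(1.0, abs=1e-15)
        assert np.all(s.beta_star >= 0)
        assert s.support.size == 8
        assert (s.support + 1).tolist() == [9, 20, 26, 37, 48, 54, 65, 76]

    def test_sigma_block_pattern(self):
        s = gaussian_scenario(131)
        sig = np.array([c.params["sigma"] for c in s.dict_true.components])
        assert np.all(sig[:20] == 1.0)
        assert np.all(sig[20:26] == 0.8)
        assert np.all(sig[26:37] == 0.6)
        assert np.all(sig[37:48] == 0.4)
        assert np.all(sig[48:54] == 0.6)
        assert np.all(sig[54:65] == 0.8)
        assert np.all(sig[65:] == 1.2)

    def test_means_on_half_integer_grid(self):
        s = gaussian_scenario(81, a=0.5)
        means = np.array([c.params["a"] for c in s.dict_true.components])
        assert np.allclose(means, 0.5 * np.arange(1, 82))

    def test_observed_sds_inflated(self):
        s = gaussian_scenario(81, inflation=1.1)
        clean = np.array([c.params["sigma"] for c in s.dict_true.components])
        obs = np.array([c.params["sigma"] for c in s.dict_obs.components])
        assert np.allclose(obs, 1.1 * clean)

    def test_no_contamination_limit(self):
        s = gaussian_scenario(81, inflation=1.0)
        assert s.contamination == "none"
        xs = np.linspace(-5, 50, 2000)
        h_true = s.dict_true.evaluate(xs) @ s.beta_star
        h_obs = s.dict_obs.evaluate(xs) @ s.beta_star
        assert np.max(np.abs(h_true - h_obs)) < 1e-12

    def test_too_small_W_rejected(self):
        with pytest.raises(ValueError):
            gaussian_scenario(60)

    def test_observed_sample_mean_matches_mixture_mean(self):
        s = gaussian_scenario(81)
        means = 0.5 * np.arange(1, 82)
        mix_mean = float(s.beta_star @ means)
        sig = 1.1 * np.array([c.params["sigma"]
                              for c in s.dict_true.components])
        mix_var = float(s.beta_star @ (sig ** 2 + means ** 2) - mix_mean ** 2)
        x = s.sample(100_000, np.random.default_rng(8))
        se = np.sqrt(mix_var / x.size)
        assert abs(x.mean() - mix_mean) < 4 * se


class TestPoissonScenario:
    def test_rates_and_weights(self):
        s = poisson_scenario(81, a=0.1)
        rates = np.array([c.params["lam"] for c in s.dict_true.components])
        assert np.allclose(rates, 0.1 * np.arange(1, 82))
        assert s.beta_star.sum() == pytest.approx(1.0, abs=1e-15)
        assert s.dict_obs.family == "negbin"

    def test_negbin_sampler_mean_and_variance(self):
        # one-component scenario isolates the sampler:
        # mean lam, variance lam + lam^2/r
        from csde import Dictionary
        scen = Scenario(name="nb",
                        dict_true=Dictionary.poisson([2.0]),
                        dict_obs=Dictionary.negbin([2.0], 6.0),
                        beta_star=np.array([1.0]),
                        contamination="poisson_to_negbin",
                        contamination_param=6.0)
        x = scen.sample(100_000, np.random.default_rng(10))
        assert x.mean() == pytest.approx(2.0, abs=0.05)
        assert x.var() == pytest.approx(2.0 + 4.0 / 6.0, abs=0.1)

    def test_negbin_poisson_limit(self):
        from csde import Dictionary
        scen = Scenario(name="nb_limit",
                        dict_true=Dictionary.poisson([2.0]),
                        dict_obs=Dictionary.negbin([2.0], 1e9),
                        beta_star=np.array([1.0]),
                        contamination="poisson_to_negbin",
                        contamination_param=1e9)
        x = scen.sample(100_000, np.random.default_rng(12)).astype(int)
        kmax = 12
        counts = np.bincount(np.minimum(x, kmax), minlength=kmax + 1)
        p = stats.poisson.pmf(np.arange(kmax), 2.0)
        p = np.append(p, 1.0 - p.sum())  # lump the tail
        _, pval = stats.chisquare(counts, 100_000 * p)
        assert pval > 0.01


class TestLowdimScenarios:
    def test_printed_settings(self):
        s1, s2 = lowdim_scenarios()
        assert s1.beta_star.tolist() == [0.3, 0, 0, 0.3, 0, 0.4]
        assert s1.support.size == 3
        assert [c.params["a"] for c in s1.dict_true.components] == \
            [0, 10, 20, 30, 40, 50]
        assert s2.beta_star.tolist() == [0.1, 0, 0, 0.8, 0, 0, 0.1]
        assert [c.params["sigma"] for c in s2.dict_true.components] == \
            [0.3, 0.2, 0.2, 0.1, 0.2, 0.2, 0.3]
        assert s1.n == s2.n == 50
        assert s1.contamination == "none"

    def test_config_round_trip(self):
        for s in lowdim_scenarios():
            s2 = Scenario.from_config(s.to_config())
            assert np.allclose(s2.beta_star, s.beta_star)
            assert np.allclose(s2.dict_true.gram, s.dict_true.gram)
            assert s2.n == s.n and s2.name == s.name


class TestScenarioValidation:
    def test_off_simplex_weights_rejected(self):
        from csde import Dictionary
        d = Dictionary.gaussian([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            Scenario(name="bad", dict_true=d,
                     beta_star=np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            Scenario(name="bad", dict_true=d,
                     beta_star=np.array([-0.2, 1.2]))


class TestRunExperiment:
    def test_oracle_estimator_zero_errors(self):
        s1 = lowdim_scenarios()[0]
        oracle = lambda samples, d: s1.beta_star
        summ = run_experiment(s1, {"oracle": oracle}, N=1, base_seed=3)
        row = summ.summary.iloc[0]
        assert row["l1_mean"] == 0.0
        assert row["tv_mean"] == pytest.approx(0.0, abs=1e-12)
        assert row["exact_recovery_rate"] == 1.0

    def test_deterministic_under_base_seed(self):
        s2 = lowdim_scenarios()[1]
        est = {"em": EMConfig(), "csde": PenaltySpec(
            lam1=0.01, c=0.01, mode="csde", weight_scale_mode="fixed_lam1")}
        a = run_experiment(s2, est, N=4, base_seed=17)
        b = run_experiment(s2, est, N=4, base_seed=17)
        assert a.replicates.equals(b.replicates)
        assert a.summary.equals(b.summary)

    def test_replicate_seeds_disjoint_and_logged(self):
        s2 = lowdim_scenarios()[1]
        summ = run_experiment(s2, {"em": EMConfig()}, N=5, base_seed=100)
        seeds = summ.replicates["seed"]
        assert sorted(seeds.unique().tolist()) == [100, 101, 102, 103, 104]

    def test_failing_estimator_recorded_not_fatal(self):
        s1 = lowdim_scenarios()[0]

        def broken(samples, d):
            raise RuntimeError("boom")

        summ = run_experiment(s1, {"broken": broken, "em": EMConfig()}, N=3,
                              base_seed=2)
        row = summ.summary.set_index("estimator").loc["broken"]
        assert row["n_failed"] == 3 and row["n_ok"] == 0
        assert summ.summary.set_index("estimator").loc["em", "n_ok"] == 3
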