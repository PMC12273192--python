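"""Discrete tail fitting, k_min selection, Vuong comparisons."""

import numpy as np
import pytest
from scipy.special import zeta

from rxnnet import powerfit as pf
from rxnnet.synthetic import sample_discrete_powerlaw


class TestFitPowerLaw:
    def test_recovery_matches_grid_search_oracle(self):
        sample = sample_discrete_powerlaw(2.5, 2, 100_000, seed=3)
        fit = pf.fit_power_law(sample, 2)
        assert 2.47 <= fit.params["gamma"] <= 2.53
        # independent oracle: grid search of the log-likelihood
        gammas = np.arange(1.01, 6.0, 1e-3)
        sum_log = np.sum(np.log(sample))
        ll = -sample.size * np.log(zeta(gammas, 2)) - gammas * sum_log
        assert abs(gammas[np.argmax(ll)] - fit.params["gamma"]) < 2e-3

    def test_degenerate_tail_raises(self):
        with pytest.raises(pf.FitError, match="degenerate"):
            pf.fit_power_law(np.array([3] * 40), 3)

    def test_empty_tail_raises(self):
        with pytest.raises(pf.FitError):
            pf.fit_power_law(np.array([1, 2, 3]), 10)

    def test_continuous_approximation_cross_check(self):
        # the closed form 1 + n / sum ln(k/(kmin - 1/2)) is accurate for
        # larger kmin; cross-check inside its validity regime
        sample = sample_discrete_powerlaw(2.5, 6, 100_000, seed=3)
        fit = pf.fit_power_law(sample, 6)
        approx = 1.0 + sample.size / np.sum(np.log(sample / 5.5))
        assert abs(approx - fit.params["gamma"]) < 0.05

    @pytest.mark.parametrize("gamma", [1.8, 2.1, 3.0])
    def test_estimator_recovery_across_exponents(self, gamma):
        errs = [
            abs(pf.fit_power_law(sample_discrete_powerlaw(gamma, 1, 100_000, seed=s), 1).params["gamma"] - gamma)
            for s in range(3)
        ]
        assert np.mean(errs) < 0.05


class TestSelectKmin:
    def test_pure_powerlaw_selects_small_kmin(self):
        sample = sample_discrete_powerlaw(2.5, 1, 100_000, seed=1)
        assert pf.select_kmin(sample).kmin <= 3

    def test_support_bound(self):
        sample = sample_discrete_powerlaw(2.5, 5, 20_000, seed=1)
        assert pf.select_kmin(sample).kmin >= 5

    def test_known_changepoint_recovered(self):
        rng = np.random.default_rng(9)
        noise = rng.integers(1, 4, 30_000)
        tail = sample_discrete_powerlaw(2.5, 4, 70_000, seed=9)
        fit = pf.select_kmin(np.concatenate([noise, tail]))
        assert 3 <= fit.kmin <= 6

    def test_selection_matches_exhaustive_scan(self):
        sample = sample_discrete_powerlaw(2.3, 1, 20_000, seed=6)
        fit = pf.select_kmin(sample, kmin_candidates=range(1, 20))
        scanned = []
        for k in range(1, 20):
            try:
                scanned.append(pf.fit_power_law(sample, k))
            except pf.FitError:
                pass
        best = min(scanned, key=lambda f: (f.ks_distance, f.kmin))
        assert fit.kmin == best.kmin

    def test_no_viable_candidate_raises(self):
        with pytest.raises(pf.FitError):
            pf.select_kmin(np.array([1, 1, 2]), kmin_candidates=[1])


class TestAlternativeFamilies:
    def test_exponential_rate_recovered_closed_form(self):
        rng = np.random.default_rng(2)
        lam = 0.3
        sample = rng.geometric(p=1 - np.exp(-lam), size=100_000)  # support >= 1
        fit = pf.fit_alternative(sample, "exponential", 1)
        assert abs(fit.params["rate"] - lam) / lam < 0.02

    def test_correct_model_dominates_loglik(self):
        rng = np.random.default_rng(2)
        sample = rng.geometric(p=1 - np.exp(-0.3), size=100_000)
        f_exp = pf.fit_alternative(sample, "exponential", 1)
        f_pl = pf.fit_power_law(sample, 1)
        assert f_exp.loglik > f_pl.loglik

    def test_lognormal_positive_hits_mu_boundary(self):
        rng = np.random.default_rng(5)
        sample = np.maximum(np.rint(np.exp(rng.normal(-1.0, 0.6, 20_000))), 1).astype(int)
        fit = pf.fit_alternative(sample, "lognormal_positive", 1)
        assert fit.params["mu"] == pytest.approx(0.0, abs=1e-6)

    def test_unknown_family_raises(self):
        with pytest.raises(pf.FitError, match="unknown family"):
            pf.fit_alternative(np.arange(1, 100), "cauchy", 1)

    def test_logpmf_normalizes(self):
        """Fitted families put (almost) unit mass on the tail support."""
        sample = sample_discrete_powerlaw(2.5, 1, 5_000, seed=8)
        ks = np.arange(1, 20_000)
        for family in ("power_law", "exponential", "lognormal", "stretched_exponential"):
            fit = pf.fit_alternative(sample, family, 1)
            total = np.exp(fit.logpmf(ks)).sum()
            assert total == pytest.approx(1.0, abs=5e-3), family


class TestCompare:
    def test_powerlaw_beats_exponential_on_powerlaw_data(self):
        sample = sample_discrete_powerlaw(2.5, 1, 10_000, seed=0)
        f_pl = pf.fit_power_law(sample, 1)
        f_exp = pf.fit_alternative(sample, "exponential", 1)
        result = pf.compare(f_pl, f_exp)
        assert result.preferred == "power_law"
        assert result.p_value < 0.05

    def test_self_comparison_is_inconclusive(self):
        sample = sample_discrete_powerlaw(2.5, 1, 1_000, seed=0)
        fit = pf.fit_power_law(sample, 1)
        result = pf.compare(fit, fit)
        assert result.R == 0.0
        assert result.preferred == "inconclusive"

    def test_antisymmetry(self):
        sample = sample_discrete_powerlaw(2.5, 1, 10_000, seed=0)
        f_pl = pf.fit_power_law(sample, 1)
        f_exp = pf.fit_alternative(sample, "exponential", 1)
        assert pf.compare(f_pl, f_exp).R == pytest.approx(-pf.compare(f_exp, f_pl).R)

    def test_mismatched_kmin_is_contract_error(self):
        sample = sample_discrete_powerlaw(2.5, 1, 10_000, seed=0)
        with pytest.raises(ValueError, match="kmin"):
            pf.compare(pf.fit_power_law(sample, 1), pf.fit_power_law(sample, 2))


class TestEmpiricalCcdf:
    def test_hand_counted_example(self):
        assert pf.empirical_ccdf(np.array([1, 1, 2, 4])) == [(1, 1.0), (2, 0.5), (4, 0.25)]

    def test_single_value(self):
        assert pf.empirical_ccdf(np.array([7])) == [(7, 1.0)]

    def test_matches_counting_oracle_on_random_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            sample = rng.integers(1, 30, size=rng.integers(1, 60))
            got = pf.empirical_ccdf(sample)
            for k, p in got:
                assert p == pytest.approx((sample >= k).mean())
            probs = [p for _, p in got]
            assert probs == sorted(probs, reverse=True)
            assert probs[0] == 1.0


class TestDegreeSample:
    def test_in_out_sums_agree(self, clean_net):
        s_in = pf.degree_sample(clean_net, "in", "all")
        s_out = pf.degree_sample(clean_net, "out", "all")
        assert s_in.values.sum() == s_out.values.sum()

    def test_reaction_out_degree_constant_one(self, clean_net):
        s = pf.degree_sample(clean_net, "out", "reactions")
        assert np.all(s.values == 1)
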