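"""Unit tests for heavy-tail diagnostics and MLE model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from hopbasin.fitting import (
    MODEL_NAMES,
    bootstrap_model_preference,
    compare_models_aic,
    empirical_cdf_ccdf,
    excess_kurtosis,
    fit_exponential,
    fit_halfnormal_loc1,
    fit_lognormal,
    fit_powerlaw_continuous,
    fit_powerlaw_discrete,
)


class TestExcessKurtosis:
    def test_two_point_symmetric_law(self):
        x = np.tile([-1.0, 1.0], 500)
        # m4/m2^2 = 1 exactly; the small-sample factor is O(1/n) at n=1000.
        assert excess_kurtosis(x) == pytest.approx(-2.0, abs=0.01)

    def test_normal_sample_is_mesokurtic(self):
        x = np.random.default_rng(0).normal(size=100_000)
        assert excess_kurtosis(x) == pytest.approx(0.0, abs=0.1)

    def test_half_normal_reference_value(self):
        # Half-normal excess kurtosis is 8(pi-3)/(pi-2)^2 ~= 0.869.
        x = 1.0 + np.abs(np.random.default_rng(1).normal(size=100_000))
        assert excess_kurtosis(x) == pytest.approx(0.87, abs=0.1)

    def test_degenerate_sample(self):
        with pytest.raises(ValueError, match="degenerate"):
            excess_kurtosis([2.0, 2.0, 2.0, 2.0])


class TestLognormal:
    def test_closed_form(self):
        rep = fit_lognormal([1.0, np.e, np.e**2])
        assert rep.params["meanlog"] == pytest.approx(1.0)
        assert rep.params["sdlog"] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert rep.k == 2

    def test_loglik_matches_density_sum(self):
        x = np.random.default_rng(2).lognormal(1.0, 0.7, size=500)
        rep = fit_lognormal(x)
        direct = stats.lognorm.logpdf(
            x, s=rep.params["sdlog"], scale=np.exp(rep.params["meanlog"])
        ).sum()
        assert rep.loglik == pytest.approx(direct, abs=1e-8)

    def test_invalid_support(self):
        with pytest.raises(ValueError, match="invalid support"):
            fit_lognormal([1.0, 0.0, 2.0])


class TestExponential:
    def test_rate_is_reciprocal_mean(self):
        rep = fit_exponential([1.0, 2.0, 3.0])
        assert rep.params["rate"] == pytest.approx(0.5)

    def test_aic_identity(self):
        rep = fit_exponential(np.arange(1.0, 30.0))
        assert rep.aic == pytest.approx(2 * rep.k - 2 * rep.loglik)

    def test_loglik_matches_density_sum(self):
        x = np.random.default_rng(3).exponential(4.0, size=300)
        rep = fit_exponential(x)
        direct = stats.expon.logpdf(x, scale=1 / rep.params["rate"]).sum()
        assert rep.loglik == pytest.approx(direct, abs=1e-8)


class TestHalfNormal:
    def test_closed_form(self):
        rep = fit_halfnormal_loc1([1.0, 2.0, 3.0])
        assert rep.params["sigma"] == pytest.approx(np.sqrt(5.0 / 3.0))

    def test_loglik_matches_density_sum(self):
        x = 1.0 + np.abs(np.random.default_rng(4).normal(0, 2.5, size=400))
        rep = fit_halfnormal_loc1(x)
        direct = stats.halfnorm.logpdf(x, loc=1.0, scale=rep.params["sigma"]).sum()
        assert rep.loglik == pytest.approx(direct, abs=1e-8)

    def test_support_guards(self):
        with pytest.raises(ValueError, match="invalid support"):
            fit_halfnormal_loc1([0.5, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_halfnormal_loc1([1.0, 1.0, 1.0])


class TestPowerLaw:
    def test_zeta_parameter_recovery(self):
        # scipy's zipf is an independent generator of the zeta law.
        x = stats.zipf.rvs(2.5, size=50_000, random_state=5)
        rep = fit_powerlaw_discrete(x, x_min=1)
        assert 2.45 <= rep.params["alpha"] <= 2.55

    def test_zeta_mle_matches_grid_search_oracle(self):
        x = stats.zipf.rvs(1.8, size=2_000, random_state=6)
        rep = fit_powerlaw_discrete(x, x_min=1)
        grid = np.linspace(1.01, 4.0, 3000)
        sum_log = np.log(x).sum()
        nll = grid * sum_log + x.size * np.log(special.zeta(grid, 1))
        assert rep.params["alpha"] == pytest.approx(grid[nll.argmin()], abs=2e-3)

    def test_zeta_respects_x_min(self):
        x = stats.zipf.rvs(2.0, size=5_000, random_state=7) + 4
        rep = fit_powerlaw_discrete(x, x_min=5)
        direct = (
            -rep.params["alpha"] * np.log(x) - np.log(special.zeta(rep.params["alpha"], 5))
        ).sum()
        assert rep.loglik == pytest.approx(direct, abs=1e-6)

    def test_invalid_support(self):
        with pytest.raises(ValueError, match="invalid support"):
            fit_powerlaw_discrete([5, 6, 7], x_min=10)
        with pytest.raises(ValueError, match="invalid support"):
            fit_powerlaw_discrete([1.5, 2.0], x_min=1)

    def test_continuous_pareto_closed_form(self):
        x = stats.pareto.rvs(1.4, size=50_000, random_state=8)  # alpha = 2.4
        rep = fit_powerlaw_continuous(x, x_min=1.0)
        assert rep.params["alpha"] == pytest.approx(1.0 + x.size / np.log(x).sum())
        assert 2.35 <= rep.params["alpha"] <= 2.45

    def test_continuous_loglik_matches_density_sum(self):
        x = stats.pareto.rvs(0.9, size=300, random_state=9)
        rep = fit_powerlaw_continuous(x)
        direct = stats.pareto.logpdf(x, rep.params["alpha"] - 1.0).sum()
        assert rep.loglik == pytest.approx(direct, abs=1e-8)


@pytest.mark.parametrize(
    "fitter, sample",
    [
        (fit_lognormal, stats.lognorm.rvs(1.2, scale=np.exp(2.0), size=800, random_state=10)),
        (fit_exponential, stats.expon.rvs(scale=12.0, size=800, random_state=11)),
        (fit_halfnormal_loc1, stats.halfnorm.rvs(loc=1.0, scale=9.0, size=800, random_state=12)),
        (fit_powerlaw_discrete, stats.zipf.rvs(2.2, size=800, random_state=13)),
        (fit_powerlaw_continuous, stats.pareto.rvs(1.2, size=800, random_state=14)),
    ],
    ids=["lognormal", "exponential", "halfnormal", "zeta", "pareto"],
)
def test_mle_beats_local_perturbations(fitter, sample):
    """Each fitted parameter set is a local likelihood maximum (+/-1%)."""
    rep = fitter(sample)
    x = np.asarray(sample, dtype=float)

    def loglik(params):
        if rep.model == "lognormal":
            return stats.lognorm.logpdf(
                x, s=params["sdlog"], scale=np.exp(params["meanlog"])
            ).sum()
        if rep.model == "exponential":
            return stats.expon.logpdf(x, scale=1 / params["rate"]).sum()
        if rep.model == "halfnormal":
            return stats.halfnorm.logpdf(x, loc=1.0, scale=params["sigma"]).sum()
        a, xm = params["alpha"], rep.x_min or 1.0
        if rep.k == 1 and np.all(np.mod(x, 1) == 0) and fitter is fit_powerlaw_discrete:
            return (-a * np.log(x) - np.log(special.zeta(a, xm))).sum()
        return (np.log((a - 1) / xm) - a * np.log(x / xm)).sum()

    base = loglik(rep.params)
    assert base == pytest.approx(rep.loglik, rel=1e-9)
    for name, value in rep.params.items():
        for factor in (0.99, 1.01):
            perturbed = dict(rep.params)
            perturbed[name] = value * factor
            if rep.model == "powerlaw" and perturbed["alpha"] <= 1.0:
                continue
            assert loglik(perturbed) < base


@pytest.mark.parametrize(
    "name, sample, truth, tol",
    [
        ("meanlog", stats.lognorm.rvs(1.0, scale=np.exp(2.0), size=10_000, random_state=20), 2.0, None),
        ("rate", stats.expon.rvs(scale=5.0, size=10_000, random_state=21), 0.2, None),
        ("sigma", stats.halfnorm.rvs(loc=1.0, scale=7.0, size=10_000, random_state=22), 7.0, None),
        ("alpha", stats.zipf.rvs(2.5, size=10_000, random_state=23), 2.5, 0.05),
    ],
)
def test_parameter_recovery_within_two_se(name, sample, truth, tol):
    fitters = {
        "meanlog": fit_lognormal,
        "rate": fit_exponential,
        "sigma": fit_halfnormal_loc1,
        "alpha": fit_powerlaw_discrete,
    }
    rep = fitters[name](sample)
    est = rep.params[name]
    n = len(sample)
    if tol is None:
        # Asymptotic standard errors of the respective MLEs.
        se = {
            "meanlog": 1.0 / np.sqrt(n),  # sdlog/sqrt(n) with sdlog = 1
            "rate": 0.2 / np.sqrt(n),
            "sigma": 7.0 / np.sqrt(2 * n),
        }[name]
        tol = 2 * se
    assert abs(est - truth) <= tol


class TestModelComparison:
    def test_lognormal_sample_ranks_lognormal_first(self):
        rng = np.random.default_rng(30)
        x = rng.lognormal(2.0, 1.0, size=10_000)
        x = x[x >= 1.0]
        ranking = compare_models_aic(x)
        assert ranking[0].model == "lognormal"
        assert [r.aic for r in ranking] == sorted(r.aic for r in ranking)

    def test_support_guard(self):
        with pytest.raises(ValueError, match="invalid support"):
            compare_models_aic([0.5, 2.0, 3.0])

    def test_discrete_flag_switches_powerlaw_candidate(self):
        x = stats.zipf.rvs(2.0, size=2_000, random_state=31)
        cont = {r.model: r for r in compare_models_aic(x)}
        disc = {r.model: r for r in compare_models_aic(x, discrete_powerlaw=True)}
        assert cont["powerlaw"].params["alpha"] != disc["powerlaw"].params["alpha"]
        # The zeta law is the true model here, so it must win the ranking.
        assert compare_models_aic(x, discrete_powerlaw=True)[0].model == "powerlaw"


class TestBootstrap:
    def test_single_replicate_on_decisive_sample(self):
        rng = np.random.default_rng(32)
        x = rng.lognormal(2.0, 1.0, size=5_000)
        x = x[x >= 1.0]
        pref = bootstrap_model_preference(x, B=1, rng=np.random.default_rng(0))
        assert pref.counts["lognormal"] == 1

    def test_counts_conserved_and_reproducible(self):
        x = stats.zipf.rvs(1.9, size=400, random_state=33)
        a = bootstrap_model_preference(x, B=40, rng=np.random.default_rng(77))
        b = bootstrap_model_preference(x, B=40, rng=np.random.default_rng(77))
        assert a.counts == b.counts
        assert sum(a.counts.values()) + a.skipped == 40
        assert set(a.counts) == set(MODEL_NAMES)


class TestCdfCcdf:
    def test_direct_count(self):
        table = empirical_cdf_ccdf([1.0, 1.0, 2.0])
        assert table["value"].tolist() == [1.0, 2.0]
        assert table["cdf"].tolist() == pytest.approx([2 / 3, 1.0])
        assert table["ccdf"].tolist() == pytest.approx([1 / 3, 0.0])

    def test_monotonicity_and_complement(self):
        x = np.random.default_rng(34).integers(1, 40, size=500)
        table = empirical_cdf_ccdf(x)
        assert (np.diff(table["cdf"]) >= 0).all()
        assert (np.diff(table["ccdf"]) <= 0).all()
        assert np.allclose(table["cdf"] + table["ccdf"], 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=60))
    def test_properties_hold_for_arbitrary_samples(self, sample):
        table = empirical_cdf_ccdf(sample)
        assert table["cdf"].iloc[-1] == pytest.approx(1.0)
        assert table["ccdf"].iloc[-1] == pytest.approx(0.0)
        assert np.allclose(table["cdf"] + table["ccdf"], 1.0)
        assert (np.diff(table["value"]) > 0).all()
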