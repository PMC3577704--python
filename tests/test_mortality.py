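import datetime as dt

import numpy as np
import pandas as pd
import pytest

from driftstrand import (
    BetaHyper,
    CarcassCount,
    GammaPrior,
    MortalityModel,
    TrialWindow,
    count_carcasses,
    fit_beta_from_summary,
    prior_sensitivity,
    trial_window,
)


def direct_summation_mean(model: MortalityModel, p: float, c_max: int = 2000) -> float:
    """Exhaustive-summation oracle for the fixed-p̃ binomial-Poisson posterior."""
    support = np.arange(model.count.c, c_max + 1)
    log_pmf = model.log_pmf_fixed_p(support, p)
    return float(np.sum(support * np.exp(log_pmf)))


class TestTrialWindow:
    @pytest.mark.parametrize(
        "first, last, start, end",
        [
            # deployments 15-18 July centre the window on 9-23 July
            (dt.date(2010, 7, 15), dt.date(2010, 7, 18), dt.date(2010, 7, 9), dt.date(2010, 7, 23)),
            (dt.date(2011, 5, 2), dt.date(2011, 5, 2), dt.date(2011, 4, 25), dt.date(2011, 5, 9)),
            # midpoint 10 October gives the 3-17 October window
            (dt.date(2011, 10, 7), dt.date(2011, 10, 13), dt.date(2011, 10, 3), dt.date(2011, 10, 17)),
        ],
    )
    def test_midpoint_rule(self, first, last, start, end):
        w = trial_window(first, last)
        assert (w.start_date, w.end_date) == (start, end)
        assert (w.end_date - w.start_date).days + 1 == 15

    def test_reversed_dates_rejected(self):
        with pytest.raises(ValueError):
            trial_window(dt.date(2010, 7, 18), dt.date(2010, 7, 15))

    def test_non_15_day_window_rejected(self):
        with pytest.raises(ValueError, match="15 days"):
            TrialWindow(dt.date(2010, 7, 1), dt.date(2010, 7, 10))


class TestCountCarcasses:
    def make_records(self, rows):
        return pd.DataFrame(rows, columns=["species", "date", "lat", "lon", "ccl_cm", "gear_marks", "site_id"])

    def test_empty_records(self):
        w = trial_window(dt.date(2010, 7, 15), dt.date(2010, 7, 18), site_id="PSL")
        assert count_carcasses(self.make_records([]), w, "Cc").c == 0

    def test_matches_brute_force_filter(self, rng):
        w = trial_window(dt.date(2010, 7, 15), dt.date(2010, 7, 18), site_id="PSL")
        rows = []
        for i in range(40):
            rows.append(
                {
                    "species": rng.choice(["Cc", "Cm"]),
                    "date": dt.date(2010, 7, 1) + dt.timedelta(days=int(rng.integers(0, 40))),
                    "lat": 25.0, "lon": -112.4, "ccl_cm": 70.0, "gear_marks": False,
                    "site_id": rng.choice(["PSL", "SJU"]),
                }
            )
        records = self.make_records(rows)
        expected = sum(
            1
            for r in rows
            if r["species"] == "Cc" and r["site_id"] == "PSL"
            and w.start_date <= r["date"] <= w.end_date
        )
        assert count_carcasses(records, w, "Cc").c == expected

    def test_window_boundaries_inclusive(self):
        w = trial_window(dt.date(2010, 7, 15), dt.date(2010, 7, 18), site_id="PSL")
        rows = [
            {"species": "Cc", "date": w.start_date, "lat": 25.0, "lon": -112.4,
             "ccl_cm": 70.0, "gear_marks": False, "site_id": "PSL"},
            {"species": "Cc", "date": w.end_date, "lat": 25.0, "lon": -112.4,
             "ccl_cm": 70.0, "gear_marks": False, "site_id": "PSL"},
        ]
        assert count_carcasses(self.make_records(rows), w, "Cc").c == 2

    def test_missing_dates_excluded_and_lat_bounds_applied(self):
        w = trial_window(dt.date(2010, 7, 15), dt.date(2010, 7, 18), site_id="PSL")
        rows = [
            {"species": "Cc", "date": None, "lat": 25.0, "lon": -112.4,
             "ccl_cm": 70.0, "gear_marks": False, "site_id": "PSL"},
            {"species": "Cc", "date": dt.date(2010, 7, 16), "lat": 26.5, "lon": -112.4,
             "ccl_cm": 70.0, "gear_marks": False, "site_id": "PSL"},
            {"species": "Cc", "date": dt.date(2010, 7, 16), "lat": 25.0, "lon": -112.4,
             "ccl_cm": 70.0, "gear_marks": False, "site_id": "PSL"},
        ]
        cc = count_carcasses(self.make_records(rows), w, "Cc", lat_bounds=(24.8, 25.2))
        assert cc.c == 1


class TestGammaPrior:
    def test_moment_matching(self):
        prior = GammaPrior(mean=13, variance=100)
        assert prior.shape == pytest.approx(1.69)
        assert prior.rate == pytest.approx(0.13)
        # moments round-trip
        assert prior.shape / prior.rate == pytest.approx(13)
        assert prior.shape / prior.rate**2 == pytest.approx(100)

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            GammaPrior(mean=0, variance=100)


class TestBinomialPoisson:
    def test_perfect_stranding_concentrates_at_c(self):
        res = MortalityModel(5, 1.0).fit(n_draws=50_000, seed=1)
        assert (res.c_total_draws >= 5).all()
        assert res.mean == pytest.approx(5, abs=0.05)
        assert res.point_estimate == 5

    def test_support_never_below_c(self):
        for model in ("binomial_poisson", "negative_binomial"):
            res = MortalityModel(7, BetaHyper(2, 10), model=model).fit(n_draws=20_000, seed=2)
            assert res.c_total_draws.min() >= 7

    def test_matches_direct_summation_oracle(self):
        """Fixed p̃ = 0.5, c = 4: sampler mean equals exhaustive summation."""
        model = MortalityModel(4, 0.5, prior_variance=100)
        res = model.fit(n_draws=200_000, seed=3)
        oracle = direct_summation_mean(model, 0.5, c_max=500)
        assert res.mean == pytest.approx(oracle, abs=3 * res.mc_standard_error())

    @pytest.mark.parametrize("c, p", [(1, 0.8), (13, 0.06), (25, 0.3)])
    def test_oracle_equivalence_across_regimes(self, c, p):
        model = MortalityModel(c, p)
        res = model.fit(n_draws=150_000, seed=c)
        oracle = direct_summation_mean(model, p)
        assert res.mean == pytest.approx(oracle, abs=3 * res.mc_standard_error())

    def test_smaller_stranding_probability_means_more_deaths(self):
        low = MortalityModel(6, BetaHyper(2, 30)).fit(n_draws=50_000, seed=4)
        high = MortalityModel(6, BetaHyper(30, 2)).fit(n_draws=50_000, seed=4)
        assert low.mean > high.mean

    def test_published_low_count_cell_rounds_to_one(self):
        """c = 1 with stranding probability ~0.79 gives a point estimate of 1."""
        hyper, _ = fit_beta_from_summary(0.79, 0.67, 0.87)
        res = MortalityModel(1, hyper).fit(n_draws=100_000, seed=5)
        assert res.point_estimate == 1

    def test_zero_carcasses_refused(self):
        with pytest.raises(ValueError, match="zero observed carcasses"):
            MortalityModel(0, 0.5)


class TestNegativeBinomial:
    def test_perfect_stranding_gives_no_unobserved(self):
        res = MortalityModel(4, 1.0, model="negative_binomial").fit(n_draws=10_000, seed=6)
        assert (res.c_total_draws == 4).all()

    def test_closed_form_mean_at_fixed_p(self):
        # E[C_total] = c + c(1-p)/p = 6 for c = 3, p = 0.5
        res = MortalityModel(3, 0.5, model="negative_binomial").fit(n_draws=200_000, seed=7)
        assert res.mean == pytest.approx(6.0, abs=3 * res.mc_standard_error())

    def test_wider_than_binomial_poisson_on_matched_inputs(self):
        """Low stranding probability, c = 13: NB posterior spread exceeds BP."""
        hyper, _ = fit_beta_from_summary(0.05, 0.02, 0.12)
        bp = MortalityModel(13, hyper).fit(n_draws=100_000, seed=8)
        nb = MortalityModel(13, hyper, model="negative_binomial").fit(n_draws=100_000, seed=8)
        assert nb.sd > bp.sd


class TestPriorSensitivity:
    def test_identical_variances_agree(self):
        table = prior_sensitivity(6, BetaHyper(3, 20), [100, 100], n_draws=150_000, seed=9)
        assert table.attrs["max_relative_difference"] < 0.02

    def test_study_variances_small_difference_at_moderate_p(self):
        # c = 11 with p̃ mode 0.36: the count is informative about mu, so the
        # variance-50 and variance-100 priors give nearly the same posterior
        hyper, _ = fit_beta_from_summary(0.36, 0.26, 0.47)
        table = prior_sensitivity(11, hyper, [50, 100], n_draws=150_000, seed=10)
        assert table.attrs["max_relative_difference"] < 0.10

    def test_prior_matters_when_p_is_small(self):
        # with p̃ ~ 0.05 the likelihood barely constrains mu and the prior
        # variance has a large, exactly computable effect
        hyper, _ = fit_beta_from_summary(0.05, 0.02, 0.12)
        table = prior_sensitivity(13, hyper, [50, 100], n_draws=150_000, seed=12)
        assert table.attrs["max_relative_difference"] > 0.25

    def test_large_variance_approaches_weak_prior_oracle(self):
        """With a nearly uninformative gamma prior the sampler matches summation."""
        model = MortalityModel(4, 0.5, prior_variance=1e6)
        res = model.fit(n_draws=200_000, seed=11)
        oracle = direct_summation_mean(model, 0.5, c_max=800)
        assert res.mean == pytest.approx(oracle, abs=3 * res.mc_standard_error())


def test_parameter_recovery_coverage():
    """95% intervals cover the true total in ~95% of seeded replicates."""
    covered, used = 0, 0
    for seed in range(1, 101):
        rng = np.random.default_rng(seed + 55_000)
        mu_star, p_star = 40.0, 0.3
        c_total_star = int(rng.poisson(mu_star))
        c = int(rng.binomial(c_total_star, p_star))
        if c == 0:
            continue
        used += 1
        p_posterior = rng.beta(40 * p_star, 40 * (1 - p_star), size=4000)
        res = MortalityModel(c, p_posterior).fit(n_draws=20_000, seed=seed)
        lo, hi = res.interval
        covered += lo <= c_total_star <= hi
    assert used >= 95
    assert 0.89 * used <= covered <= 0.99 * used
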