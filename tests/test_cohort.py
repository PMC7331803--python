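"""Synthetic cohort generator: determinism, distributions, responses."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from stepdown.cohort import (CohortParameters, generate_cohort, generate_eda,
                             generate_fear_ratings, respond)
from stepdown.physio import classify_fear_group
from conftest import make_participant


def test_same_seed_reproduces_cohort_field_for_field():
    a = generate_cohort(CohortParameters(seed=11))
    b = generate_cohort(CohortParameters(seed=11))
    assert a == b
    for pa, pb in zip(a, b):
        assert pa.metadata == pb.metadata


def test_different_seed_changes_cohort():
    a = generate_cohort(CohortParameters(seed=11))
    b = generate_cohort(CohortParameters(seed=12))
    assert a != b


def test_degenerate_variance_collapses_conditions():
    params = CohortParameters(sd_hcrit_between=0.0, threat_shift=0.0, seed=1)
    for p in generate_cohort(params):
        assert p.true_hcrit_low == p.true_hcrit_high == params.mu_hcrit_low


def truncated_mean_oracle(params):
    """Population mean of the low-condition switching height under the
    generative model (bivariate normal truncated to the physical box),
    by dense-grid numerical integration."""
    s = params.sd_hcrit_between
    mu = np.array([params.mu_hcrit_low,
                   params.mu_hcrit_low + params.threat_shift])
    rho = params.within_correlation
    cov = s**2 * np.array([[1, rho], [rho, 1]])
    lo, hi = 0.005, 0.20
    x = np.linspace(lo, hi, 801)
    X, Y = np.meshgrid(x, x, indexing="ij")
    pos = np.dstack([X, Y])
    dens = stats.multivariate_normal(mu, cov).pdf(pos)
    mass = np.trapezoid(np.trapezoid(dens, x, axis=1), x)
    mean_low = np.trapezoid(np.trapezoid(dens * X, x, axis=1), x) / mass
    return float(mean_low)


def test_large_cohort_mean_matches_generative_mean():
    """The sample mean tracks the truncated-model mean (the physical
    truncation at 0.005 m shifts it slightly above the nominal centre)."""
    params = CohortParameters(n_participants=10_000, seed=5)
    cohort = generate_cohort(params)
    lows = np.array([p.true_hcrit_low for p in cohort])
    se = params.sd_hcrit_between / np.sqrt(lows.size)
    want = truncated_mean_oracle(params)
    assert abs(lows.mean() - want) < 3 * se
    assert abs(want - params.mu_hcrit_low) < 0.004  # truncation bias is small
    assert np.all((lows > 0.005) & (lows < 0.20))


def test_condition_order_balanced_within_one():
    for n in (7, 24):
        cohort = generate_cohort(CohortParameters(n_participants=n, seed=2))
        low_first = sum(p.condition_order == ("low", "high") for p in cohort)
        assert abs(low_first - (n - low_first)) <= 1


def test_fear_responder_count_matches_fraction():
    cohort = generate_cohort(CohortParameters(seed=3))
    assert sum(p.fear_responder for p in cohort) == 7  # 7/24 by default


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        CohortParameters(n_participants=0)
    with pytest.raises(ValueError):
        CohortParameters(slope_mean=-5.0)
    with pytest.raises(ValueError):
        CohortParameters(sd_hcrit_between=-0.01)
    with pytest.raises(ValueError):
        CohortParameters(within_correlation=1.5)


class TestRespond:
    def test_midpoint_is_a_fair_coin(self):
        p = make_participant(h_low=0.075, slope=150.0)
        rng = np.random.default_rng(0)
        draws = [respond(p, "low", 0.075, rng) == "heel" for _ in range(10_000)]
        frac = np.mean(draws)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_one_over_slope_above_midpoint_hits_logistic_value(self):
        """At h = h_crit + 1/b the heel fraction approaches 1/(1+e)."""
        b = 150.0
        p = make_participant(h_low=0.075, slope=b)
        rng = np.random.default_rng(1)
        h = 0.075 + 1.0 / b
        frac = np.mean([respond(p, "low", h, rng) == "heel"
                        for _ in range(10_000)])
        want = 1.0 / (1.0 + np.e)
        assert abs(frac - want) < 3 * np.sqrt(want * (1 - want) / 10_000)

    def test_step_function_limit(self):
        p = make_participant(h_low=0.075, slope=1e9)
        rng = np.random.default_rng(2)
        assert all(respond(p, "low", 0.05, rng) == "heel" for _ in range(50))
        assert all(respond(p, "low", 0.10, rng) == "toe" for _ in range(50))

    def test_goodness_of_fit_across_the_grid(self):
        """Generated heel counts match the latent logistic (chi-square)."""
        p = make_participant(h_low=0.06, slope=120.0)
        rng = np.random.default_rng(3)
        n = 10_000
        chi2 = 0.0
        for h in (0.025, 0.05, 0.075, 0.1):
            k = sum(respond(p, "low", h, rng) == "heel" for _ in range(n))
            pr = expit(120.0 * (0.06 - h))
            chi2 += (k - n * pr) ** 2 / (n * pr * (1 - pr))
        assert chi2 < stats.chi2.ppf(0.999, df=4)

    def test_validation(self):
        p = make_participant()
        with pytest.raises(ValueError):
            respond(p, "low", -0.01, np.random.default_rng(0))
        with pytest.raises(ValueError):
            respond(p, "medium", 0.05, np.random.default_rng(0))


class TestEdaAndFear:
    def test_noise_free_trace_mean_is_exact(self):
        p = make_participant(eda_tonic_uS=12.5)
        rng = np.random.default_rng(0)
        tr = generate_eda(p, "high", 10.0, rng, threat_shift=1.8,
                          session_sd=0.0, drift_amplitude=0.0, noise_sd=0.0)
        assert tr.signal.mean() == pytest.approx(12.5 + 1.8, abs=1e-12)
        assert tr.fs == 1000.0 and tr.duration() == pytest.approx(10.0)

    def test_trace_is_finite_and_sized(self):
        p = make_participant()
        tr = generate_eda(p, "low", 3.5, np.random.default_rng(1))
        assert np.all(np.isfinite(tr.signal))
        assert tr.signal.size == 3500
        with pytest.raises(ValueError):
            generate_eda(p, "low", 0.0, np.random.default_rng(1))

    def test_responder_first_block_rating_increases_with_threat(self):
        cohort = generate_cohort(CohortParameters(seed=9))
        for p in cohort:
            low = generate_fear_ratings(p, "low")[0]
            high = generate_fear_ratings(p, "high")[0]
            group = classify_fear_group(low, high)
            if p.fear_responder:
                assert high - low > 0 and group == "fearful"
            else:
                assert high - low <= 0 and group == "non-fearful"

    def test_ratings_stay_on_half_point_scale(self):
        cohort = generate_cohort(CohortParameters(seed=10))
        for p in cohort:
            for cond in ("low", "high"):
                for r in generate_fear_ratings(p, cond, n_blocks=6):
                    assert 1.0 <= r <= 10.0
                    assert (2 * r) == int(2 * r)
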