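"""JZS paired-t Bayes factors: oracles, identities, posterior summaries."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from stepdown.bayes import (PriorSpec, _jzs_t_bf, bf_robustness,
                            delta_posterior_quantile, jzs_paired_bf,
                            jzs_paired_bf_curve, jzs_paired_bf_from_data,
                            t_from_delta_median)


def quad_oracle_bf(t, n, scale, side):
    """Adaptive-quadrature Bayes factor, independent of the GL fast path."""
    nu = n - 1

    def integrand(d):
        return stats.nct.pdf(t, nu, d * np.sqrt(n)) * stats.cauchy.pdf(d, 0, scale)

    f0 = stats.t.pdf(t, nu)
    if side == "two":
        num = sum(integrate.quad(integrand, a, b, limit=300)[0]
                  for a, b in [(-np.inf, 0), (0, np.inf)])
        return num / f0
    if side == "negative":
        return 2 * integrate.quad(integrand, -np.inf, 0, limit=300)[0] / f0
    return 2 * integrate.quad(integrand, 0, np.inf, limit=300)[0] / f0


@pytest.mark.parametrize(
    "t,n,scale,side",
    [
        (-2.8904, 24, 0.5, "negative"),
        (-2.8904, 24, 1.0, "negative"),
        (2.8904, 24, 1.0, "two"),
        (-0.5408, 13, 1.0, "two"),
        (1.3, 8, 0.707, "positive"),
        (-6.5, 40, 0.707, "two"),
    ],
)
def test_gl_quadrature_matches_adaptive_quad(t, n, scale, side):
    got = jzs_paired_bf(t, n, PriorSpec(scale, side)).bf10
    want = quad_oracle_bf(t, n, scale, side)
    assert got == pytest.approx(want, rel=1e-8)


@pytest.mark.parametrize("t,n,r", [(2.8904, 24, 1.0), (-0.5408, 13, 1.0),
                                   (1.7, 20, 0.707)])
def test_two_sided_bf_matches_pingouin(t, n, r):
    """Independent-library cross-check of the two-sided JZS Bayes factor."""
    got = jzs_paired_bf(t, n, PriorSpec(r, "two")).bf10
    want = float(pg.bayesfactor_ttest(t, n, paired=True, r=r))
    assert got == pytest.approx(want, rel=1e-9)


def test_symmetry_at_t_zero():
    """At t = 0 the evidence cannot prefer a direction."""
    for n, scale in [(10, 0.5), (24, 1.0)]:
        two = jzs_paired_bf(0.0, n, PriorSpec(scale, "two")).bf10
        neg = jzs_paired_bf(0.0, n, PriorSpec(scale, "negative")).bf10
        pos = jzs_paired_bf(0.0, n, PriorSpec(scale, "positive")).bf10
        assert neg == pytest.approx(two, rel=1e-12)
        assert pos == pytest.approx(two, rel=1e-12)
        assert two < 1.0  # exactly null data favour H0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    t=st.floats(-6, 6),
    n=st.integers(5, 60),
    scale=st.floats(0.3, 1.5),
)
def test_mixture_identity_and_positivity(t, n, scale):
    """(BF+ + BF-) / 2 equals the two-sided BF; all BFs are positive."""
    two = jzs_paired_bf(t, n, PriorSpec(scale, "two")).bf10
    neg = jzs_paired_bf(t, n, PriorSpec(scale, "negative")).bf10
    pos = jzs_paired_bf(t, n, PriorSpec(scale, "positive")).bf10
    assert min(two, neg, pos) > 0
    assert (pos + neg) / 2 == pytest.approx(two, rel=1e-6)


def test_mixture_identity_against_monte_carlo_prior_predictive():
    """Prior-predictive Monte-Carlo oracle for the two-sided marginal."""
    t, n, scale = -1.8, 18, 0.8
    rng = np.random.default_rng(7)
    deltas = stats.cauchy.rvs(0, scale, size=200_000, random_state=rng)
    vals = stats.nct.pdf(t, n - 1, deltas * np.sqrt(n)) / stats.t.pdf(t, n - 1)
    mc, se = vals.mean(), vals.std(ddof=1) / np.sqrt(vals.size)
    got = jzs_paired_bf(t, n, PriorSpec(scale, "two")).bf10
    assert abs(got - mc) < 4 * se


def test_vanishing_prior_width_gives_unit_bf():
    """As the Cauchy scale shrinks, H1 collapses onto H0 and BF -> 1."""
    bfs = [jzs_paired_bf(1.7, 20, PriorSpec(s, "two")).bf10
           for s in (0.1, 0.01, 0.001)]
    gaps = [abs(b - 1.0) for b in bfs]
    assert gaps[0] > gaps[1] > gaps[2]  # monotone approach to 1
    assert gaps[2] < 0.005


def test_robustness_scan_decreasing_for_moderate_negative_t():
    res = bf_robustness(-2.8904, 24, side="negative", scales=(0.5, 0.707, 1.0))
    bfs = [b for _, b in res]
    assert bfs[0] > bfs[1] > bfs[2]
    single = jzs_paired_bf(-2.8904, 24, PriorSpec(0.5, "negative")).bf10
    assert res[0][1] == pytest.approx(single, rel=1e-12)


def test_robustness_rejects_empty_grid():
    with pytest.raises(ValueError):
        bf_robustness(1.0, 10, scales=())


def test_curve_matches_scalar_path():
    ts = np.linspace(-4, 4, 17)
    prior = PriorSpec(0.707, "two")
    curve = jzs_paired_bf_curve(ts, 13, prior)
    scal = [jzs_paired_bf(t, 13, prior).bf10 for t in ts]
    np.testing.assert_allclose(curve, scal, rtol=1e-10)


def test_from_data_matches_t_statistic(rng):
    x = rng.normal(0.3, 1.0, 20)
    y = rng.normal(0.0, 1.0, 20)
    d = x - y
    t = d.mean() / (d.std(ddof=1) / np.sqrt(20))
    res = jzs_paired_bf_from_data(x, y, PriorSpec(0.707, "two"))
    assert res.t_statistic == pytest.approx(t)
    assert res.bf10 == pytest.approx(
        jzs_paired_bf(t, 20, PriorSpec(0.707, "two")).bf10)


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        jzs_paired_bf(1.0, 1)
    with pytest.raises(ValueError):
        jzs_paired_bf(np.inf, 10)
    with pytest.raises(ValueError):
        PriorSpec(scale=-0.5)
    with pytest.raises(ValueError):
        PriorSpec(side="up")
    with pytest.raises(ValueError):
        delta_posterior_quantile(1.0, 10, PriorSpec(), 1.5)


# ---------------------------------------------------------------------------
# posterior of the standardized effect
# ---------------------------------------------------------------------------


def mh_posterior_oracle(t, n, prior, n_draws=120_000, seed=11):
    """Random-walk Metropolis sample of the posterior of delta under H1."""
    rng = np.random.default_rng(seed)
    nu = n - 1

    def logpost(d):
        if prior.side == "negative" and d >= 0:
            return -np.inf
        if prior.side == "positive" and d <= 0:
            return -np.inf
        return (np.log(stats.nct.pdf(t, nu, d * np.sqrt(n)) + 1e-320)
                + stats.cauchy.logpdf(d, 0, prior.scale))

    d = t / np.sqrt(n)
    if prior.side == "negative":
        d = min(d, -0.1)
    if prior.side == "positive":
        d = max(d, 0.1)
    lp = logpost(d)
    out = np.empty(n_draws)
    for i in range(n_draws):
        prop = d + rng.normal(0, 0.35)
        lpp = logpost(prop)
        if np.log(rng.random()) < lpp - lp:
            d, lp = prop, lpp
        out[i] = d
    return out[20_000:]


def test_posterior_median_zero_at_null_two_sided():
    q = delta_posterior_quantile(0.0, 24, PriorSpec(1.0, "two"), 0.5)
    assert abs(q) < 1e-6


def test_posterior_quantiles_match_mcmc_oracle():
    prior = PriorSpec(1.0, "negative")
    t = -3.06
    draws = mh_posterior_oracle(t, 24, prior)
    for q in (0.025, 0.5, 0.975):
        got = delta_posterior_quantile(t, 24, prior, q)
        want = np.quantile(draws, q)
        assert got == pytest.approx(want, abs=0.02)


def test_posterior_median_inversion_round_trip():
    prior = PriorSpec(1.0, "negative")
    t = t_from_delta_median(-0.59, 24, prior)
    assert delta_posterior_quantile(t, 24, prior, 0.5) == pytest.approx(
        -0.59, abs=1e-6)
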