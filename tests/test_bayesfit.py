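"""Bayesian machinery: prior recovery, evidence oracles, Bayes factors."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import oucheck as oc
from oucheck.bayesfit import posterior_mode
from oucheck.oufit import _align, _stats


@pytest.fixture(scope="module")
def dataset():
    tree = oc.rescale_height(oc.simulate_pure_birth(10, 3), 1.0)
    return tree, oc.simulate_bm(tree, seed=4)


def bm_log_evidence_quadrature(tree, traits, priors=oc.PriorSpec()) -> float:
    """Independent oracle: the BM marginal likelihood with uniform priors,
    with mu integrated analytically and sigma2 by quadrature."""
    x = _align(tree, traits)
    n = len(x)
    p, s, q, ld = _stats(tree, x, 0.0)
    rss = q - s * s / p

    def integrand(ls2):
        s2 = math.exp(ls2)
        ll = -0.5 * (n * math.log(2 * math.pi * s2) + ld + rss / s2)
        return math.exp(ll + 0.5 * math.log(2 * math.pi * s2 / p) + ls2)

    val, err = integrate.quad(integrand, math.log(1e-10),
                              math.log(priors.sigma2_high), limit=300)
    assert err < 1e-3 * val  # quadrature error negligible vs MC tolerance
    return (math.log(val) - math.log(priors.mu_high - priors.mu_low)
            - math.log(priors.sigma2_high))


def test_prior_recovery_with_constant_likelihood(dataset):
    """Tempering power 0 must return the prior for every parameter."""
    tree, x = dataset
    res = oc.mcmc_sample(tree, x, "OU", oc.PriorSpec("exp10"),
                         oc.ChainSettings(iterations=120_000, burn_in=10_000,
                                          thin=50, n_chains=1),
                         seed=5, power=0.0)
    a = res.samples["alpha"].to_numpy()
    mu = res.samples["mu"].to_numpy()
    s2 = res.samples["sigma2"].to_numpy()
    assert stats.kstest(a, stats.expon(scale=10).cdf).pvalue > 0.01
    assert stats.kstest(mu, stats.uniform(-100, 200).cdf).pvalue > 0.01
    assert stats.kstest(s2, stats.uniform(0, 100).cdf).pvalue > 0.01


def test_mcmc_is_deterministic_and_converges(dataset):
    tree, x = dataset
    kw = dict(priors=oc.PriorSpec("exp10"),
              settings=oc.ChainSettings(iterations=20_000, burn_in=4_000,
                                        thin=10, n_chains=2), seed=11)
    r1 = oc.mcmc_sample(tree, x, "OU", **kw)
    r2 = oc.mcmc_sample(tree, x, "OU", **kw)
    assert r1.samples.equals(r2.samples)
    assert r1.converged
    assert all(v < 1.05 for v in r1.rhat.values())


def test_posterior_shrinks_toward_data(dataset):
    """With informative data the posterior mean of mu sits between the
    sample mean and the prior midpoint (0), far from the prior spread."""
    tree, x = dataset
    res = oc.mcmc_sample(tree, x, "BM", seed=3,
                         settings=oc.ChainSettings(iterations=20_000,
                                                   burn_in=4_000, thin=10,
                                                   n_chains=1))
    post_mu = res.samples["mu"].mean()
    assert abs(post_mu - x.mean()) < 2.0  # nowhere near the U(-100,100) spread


def test_stepping_stone_matches_quadrature_oracle(dataset):
    tree, x = dataset
    oracle = bm_log_evidence_quadrature(tree, x)
    settings = oc.SteppingStoneSettings(n_stones=30, iterations_per_stone=4000,
                                        burn_per_stone=1000)
    estimates = [
        oc.stepping_stone_log_ml(tree, x, "BM", settings=settings, seed=s).log_ml
        for s in (1, 2, 3)
    ]
    # tolerance = 3 x the MC spread observed for these settings (~0.05)
    assert abs(np.mean(estimates) - oracle) < 0.15
    for e in estimates:
        assert abs(e - oracle) < 0.3


def test_stepping_stone_conjugate_toy_closed_form():
    """Normal-mean model with conjugate N(0,1) prior grafted into the same
    stepping-stone harness; the closed-form evidence is the oracle."""
    rng = np.random.default_rng(7)
    n = 20
    y = 0.3 + rng.standard_normal(n)

    def loglik(theta):
        return float(-0.5 * n * math.log(2 * math.pi) - 0.5 * np.sum((y - theta[0]) ** 2))

    def logprior(theta):
        return float(-0.5 * math.log(2 * math.pi) - 0.5 * theta[0] ** 2)

    # closed form: y ~ MVN(0, I + J)
    C = np.eye(n) + np.ones((n, n))
    sign, ld = np.linalg.slogdet(C)
    exact = float(-0.5 * (n * math.log(2 * math.pi) + ld + y @ np.linalg.solve(C, y)))

    log_ml, per_stone = oc.stepping_stone_evidence(
        loglik, logprior, [0.0], n_stones=50, iterations_per_stone=2000,
        burn_per_stone=500, seed=1,
    )
    assert per_stone.shape == (50,)
    assert abs(log_ml - exact) < 0.05


def test_stepping_stone_variance_shrinks_with_iterations(dataset):
    tree, x = dataset

    def spread(iters):
        vals = [
            oc.stepping_stone_log_ml(
                tree, x, "OU",
                settings=oc.SteppingStoneSettings(n_stones=10,
                                                  iterations_per_stone=iters,
                                                  burn_per_stone=iters // 4),
                seed=s,
            ).log_ml
            for s in range(8)
        ]
        return np.var(vals)

    assert spread(3000) < spread(150)


def test_bayes_factor_conventions():
    s = oc.SteppingStoneSettings()
    mk = lambda model, ml: oc.MarginalLikelihood(model, ml, s)
    equal = oc.bayes_factor(mk("OU", -10.0), mk("BM", -10.0))
    assert equal.bayes_factor == 0.0 and not equal.reject_bm
    # a log-ML difference of 1 sits exactly at the 2lnBF = 2 boundary
    edge = oc.bayes_factor(mk("OU", -9.0), mk("BM", -10.0))
    assert edge.bayes_factor == pytest.approx(2.0) and not edge.reject_bm
    win = oc.bayes_factor(mk("OU", -8.0), mk("BM", -10.0))
    assert win.reject_bm
    raw = oc.bayes_factor(mk("OU", -9.0), mk("BM", -10.0), scale="raw")
    assert raw.bayes_factor == pytest.approx(math.e)
    with pytest.raises(ValueError):
        oc.bayes_factor(mk("BM", -9.0), mk("OU", -10.0))


def test_posterior_alpha_calibration():
    """True attraction strengths should be recovered by the posterior: the
    central 95% interval covers the truth in nearly all replicates and the
    modal estimate tracks it."""
    alpha_true = 5.0
    tree = oc.rescale_height(oc.simulate_pure_birth(200, 13), 1.0)
    settings = oc.ChainSettings(iterations=20_000, burn_in=4_000, thin=10,
                                n_chains=1)
    covered = 0
    modes = []
    for rep in range(20):
        x = oc.simulate_ou(tree, alpha_true, seed=100 + rep)
        res = oc.mcmc_sample(tree, x, "OU", oc.PriorSpec("exp10"), settings,
                             seed=rep)
        a = res.samples["alpha"].to_numpy()
        lo, hi = np.quantile(a, [0.025, 0.975])
        covered += int(lo <= alpha_true <= hi)
        modes.append(posterior_mode(a))
    # credible intervals need not have exact frequentist coverage; >= 17/20
    # is binomially compatible with a nominal 95% rate
    assert covered >= 17
    assert 0.5 * alpha_true < np.median(modes) < 2.0 * alpha_true
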