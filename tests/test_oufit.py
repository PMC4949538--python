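"""ML fitting: covariances, profiled likelihood, LRT, interpretation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import oucheck as oc
from oucheck.oufit import DegenerateDataError, gls_profile_loglik, profile_alpha
from oucheck.phylo import NonUltrametricError

from conftest import brute_mrca_depths, dense_ou_loglik


# ----------------------------------------------------------------------
# covariances
# ----------------------------------------------------------------------

def test_bm_cov_small_example(tree3):
    S = oc.bm_cov(tree3)
    idx = {lab: i for i, lab in enumerate(tree3.tip_labels)}
    a, b, c = idx["A"], idx["B"], idx["C"]
    assert S[a, a] == S[c, c] == pytest.approx(2.0)
    assert S[a, b] == pytest.approx(1.0)
    assert S[a, c] == pytest.approx(0.0)


def test_bm_cov_matches_brute_force(tree10):
    assert np.allclose(oc.bm_cov(tree10), brute_mrca_depths(tree10), atol=1e-9)


def test_ou_cov_limits(tree10):
    assert np.max(np.abs(oc.ou_cov(tree10, 1e-9) - oc.bm_cov(tree10))) < 1e-6
    alpha = 50.0
    V = oc.ou_cov(tree10, alpha)
    S = oc.bm_cov(tree10)
    mask = ~np.eye(10, dtype=bool)
    assert np.all(np.diag(V) == pytest.approx(1.0 / (2 * alpha), rel=1e-6))
    # history is erased at the rate e^{-2 alpha (T - s)}
    bound = np.exp(-2 * alpha * (1.0 - S[mask])) / (2 * alpha)
    assert np.all(np.abs(V[mask]) <= bound + 1e-15)
    assert np.all(np.abs(V[mask][S[mask] < 0.5]) < 1e-6)


def test_ou_cov_two_tip_hand_value():
    tree = oc.loads_newick("((A:0.5,B:0.5):0.5,C:1);")
    V = oc.ou_cov(tree, 1.0)
    idx = {lab: i for i, lab in enumerate(tree.tip_labels)}
    expected = math.exp(-1) * (1 - math.exp(-1)) / 2
    assert V[idx["A"], idx["B"]] == pytest.approx(expected, rel=1e-12)


def test_ou_cov_matches_discrete_time_simulation(tree6):
    """Entrywise agreement with a brute-force Euler simulation of the OU
    process run down the tree."""
    alpha, dt, reps = 2.0, 5e-4, 3000
    rng = np.random.default_rng(0)
    pre = tree6.preorder()
    par, elen = tree6.parent, tree6.edge_length
    vals = np.zeros((reps, tree6.n_nodes))
    for v in pre[1:]:
        steps = max(int(round(elen[v] / dt)), 1)
        h = elen[v] / steps
        x = vals[:, par[v]].copy()
        for _ in range(steps):
            x += -alpha * x * h + math.sqrt(h) * rng.standard_normal(reps)
        vals[:, v] = x
    tips = vals[:, : tree6.n_tips]
    emp = np.cov(tips, rowvar=False)
    V = oc.ou_cov(tree6, alpha)
    se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V ** 2) / reps)
    assert np.all(np.abs(emp - V) < 3.5 * se + alpha * dt * 5)


def test_ou_cov_is_symmetric_psd(tree10):
    for alpha in (0.0, 0.5, 5.0, 50.0):
        V = oc.ou_cov(tree10, alpha)
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-9


# ----------------------------------------------------------------------
# profiled likelihood
# ----------------------------------------------------------------------

def test_profile_loglik_matches_dense_oracle(tree6):
    x = oc.simulate_bm(tree6, seed=3)
    for alpha in (0.0, 0.4, 2.0, 9.0):
        ll, mu, s2 = gls_profile_loglik(tree6, x, alpha)
        assert ll == pytest.approx(dense_ou_loglik(tree6, x, alpha, mu, s2), abs=1e-8)


def test_alpha_zero_reduces_to_bm(tree6):
    x = oc.simulate_bm(tree6, seed=5)
    ll0, mu0, s20 = gls_profile_loglik(tree6, x, 0.0)
    bm = oc.fit_bm(tree6, x)
    assert bm.loglik == pytest.approx(ll0)
    assert bm.params.x0 == pytest.approx(mu0)
    assert bm.params.sigma2 == pytest.approx(s20)


def test_location_shift_moves_only_mu(tree6):
    x = oc.simulate_bm(tree6, seed=6)
    ll, mu, s2 = gls_profile_loglik(tree6, x, 1.0)
    ll2, mu2, s22 = gls_profile_loglik(tree6, x + 7.5, 1.0)
    assert mu2 == pytest.approx(mu + 7.5)
    assert ll2 == pytest.approx(ll)
    assert s22 == pytest.approx(s2)


def test_non_ultrametric_rejected():
    tree = oc.loads_newick("((A:1,B:2):1,C:2);")
    with pytest.raises(NonUltrametricError):
        oc.fit_bm(tree, {"A": 0.0, "B": 1.0, "C": 2.0})


def test_constant_traits_rejected(tree6):
    x = oc.simulate_bm(tree6, seed=1) * 0 + 3.0
    with pytest.raises(DegenerateDataError):
        oc.fit_bm(tree6, x)


def test_label_mismatch_rejected(tree6):
    x = oc.simulate_bm(tree6, seed=1)
    x.index = [f"z{i}" for i in range(len(x))]
    with pytest.raises(ValueError, match="labels"):
        oc.fit_bm(tree6, x)


# ----------------------------------------------------------------------
# fitting and the LRT
# ----------------------------------------------------------------------

def test_fit_ou_matches_fine_grid_search(tree6):
    x = oc.simulate_ou(tree6, 2.5, seed=8)
    ou = oc.fit_ou(tree6, x)
    grid = np.arange(1e-4, 20, 1e-4)
    lls = [gls_profile_loglik(tree6, x, a)[0] for a in grid]
    a_star = grid[int(np.argmax(lls))]
    assert ou.params.alpha == pytest.approx(a_star, abs=1e-3)


def test_nesting_and_lrt_nonnegativity(tree10):
    for seed in range(25):
        x = oc.simulate_bm(tree10, seed=seed)
        bm, ou = oc.fit_bm(tree10, x), oc.fit_ou(tree10, x)
        assert ou.loglik >= bm.loglik - 1e-8
        res = oc.lrt(bm, ou)
        assert res.lrt_stat >= 0.0
        assert 0.0 <= res.p_value <= 1.0


def test_lrt_boundary_values(tree6):
    x = oc.simulate_bm(tree6, seed=2)
    bm = oc.fit_bm(tree6, x)
    ou = oc.fit_ou(tree6, x)
    # equal logliks -> stat 0, p 1
    fake_ou = type(ou)(model="OU", params=ou.params, loglik=bm.loglik,
                       n_params=3, converged=True, alpha_at_bound=False,
                       data_fingerprint=bm.data_fingerprint)
    res = oc.lrt(bm, fake_ou)
    assert res.lrt_stat == 0.0
    assert res.p_value == pytest.approx(1.0)
    assert not res.reject_bm
    # the 5% critical value of chi-square(1)
    assert stats.chi2.sf(3.841459, 1) == pytest.approx(0.05, abs=1e-6)


def test_lrt_rejects_mismatched_data(tree6):
    bm = oc.fit_bm(tree6, oc.simulate_bm(tree6, seed=1))
    ou = oc.fit_ou(tree6, oc.simulate_bm(tree6, seed=2))
    with pytest.raises(ValueError, match="different datasets"):
        oc.lrt(bm, ou)


def test_affine_invariance_of_alpha_and_lrt(tree10):
    x = oc.simulate_bm(tree10, seed=17)
    bm, ou = oc.fit_bm(tree10, x), oc.fit_ou(tree10, x)
    y = 3.7 * x - 12.0
    bm2, ou2 = oc.fit_bm(tree10, y), oc.fit_ou(tree10, y)
    assert ou2.params.alpha == pytest.approx(ou.params.alpha, abs=1e-6)
    assert oc.lrt(bm2, ou2).lrt_stat == pytest.approx(oc.lrt(bm, ou).lrt_stat,
                                                      abs=1e-6)


def test_parameter_recovery_on_ou_data(tree10):
    """Moderate-n sanity check that the optimizer tracks the truth; the
    full-scale recovery property lives in the acceptance suite."""
    tree = oc.rescale_height(oc.simulate_pure_birth(150, 3), 1.0)
    alphas = [oc.fit_ou(tree, oc.simulate_ou(tree, 2.0, seed=s)).params.alpha
              for s in range(40)]
    assert 1.0 < np.median(alphas) < 4.0


# ----------------------------------------------------------------------
# profile curve
# ----------------------------------------------------------------------

def test_profile_alpha_consistency(tree10):
    x = oc.simulate_bm(tree10, seed=21)
    grid = np.concatenate([[0.0], np.geomspace(1e-3, 20, 80)])
    prof = profile_alpha(tree10, x, grid)
    ou = oc.fit_ou(tree10, x)
    assert prof.loglik.max() <= ou.loglik + 1e-6
    assert prof.cutoff == pytest.approx(prof.loglik.max() - 1.92)
    # pointwise re-evaluation against the dense oracle
    for a, ll in zip(grid[::20], prof.loglik[::20]):
        _, mu, s2 = gls_profile_loglik(tree10, x, a)
        assert ll == pytest.approx(dense_ou_loglik(tree10, x, a, mu, s2), abs=1e-8)
    with pytest.raises(ValueError):
        profile_alpha(tree10, x, [])


def test_profile_on_bm_data_usually_includes_zero():
    """On small trees with Brownian data the 1.92-unit support interval
    should typically contain the true value alpha = 0."""
    tree = oc.rescale_height(oc.simulate_pure_birth(50, 9), 1.0)
    grid = np.concatenate([[0.0], np.geomspace(1e-3, 20, 60)])
    hits = 0
    for seed in range(10):
        x = oc.simulate_bm(tree, seed=seed)
        if profile_alpha(tree, x, grid).contains_zero():
            hits += 1
    assert hits >= 7


# ----------------------------------------------------------------------
# interpretation helpers
# ----------------------------------------------------------------------

def test_half_life_values():
    assert oc.half_life(math.log(2)) == pytest.approx(1.0)
    assert oc.half_life(math.log(2) / 100) == pytest.approx(100.0)
    assert oc.half_life(1.0) > oc.half_life(2.0)
    with pytest.raises(ValueError, match="Brownian"):
        oc.half_life(0.0)


def test_interpret_alpha_categories():
    low = oc.interpret_alpha(math.exp(-4.0))
    assert low.neg_log_alpha == pytest.approx(4.0)
    assert "Brownian" in low.category
    high = oc.interpret_alpha(math.exp(4.0))
    assert high.neg_log_alpha == pytest.approx(-4.0)
    assert "white noise" in high.category
    mid = oc.interpret_alpha(1.0)
    assert mid.half_life == pytest.approx(math.log(2))
    assert mid.category == "moderate"


def test_expected_correlation_examples():
    assert oc.expected_correlation(0.0, 0.5) == pytest.approx(0.5)
    assert oc.expected_correlation(3.0, 1.0) == pytest.approx(1.0)
    assert oc.expected_correlation(50.0, 0.5) == pytest.approx(math.exp(-50), rel=1e-6)
    assert oc.expected_correlation(1000.0, 0.5) == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(s=st.floats(0.0, 0.99), a1=st.floats(0.0, 40.0), da=st.floats(0.01, 10.0))
def test_expected_correlation_monotone_in_alpha(s, a1, da):
    assert oc.expected_correlation(a1 + da, s) <= oc.expected_correlation(a1, s) + 1e-12
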