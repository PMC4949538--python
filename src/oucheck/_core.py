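"""Numerical kernels shared by the ML and Bayesian fitting code.

The single-stationary-peak OU model on an ultrametric tree of height T has
tip covariance (unit rate)

    V_ij(alpha) = exp(-2 alpha (T - s_ij)) * (1 - exp(-2 alpha s_ij)) / (2 alpha)

where s_ij is the root-to-MRCA distance. Because V_ij is an increasing
function f of s_ij alone, V is itself a tree-structured covariance on the
same topology with node "depths" f(depth). All Gaussian quantities needed
for the likelihood -- 1'V^-1 1, 1'V^-1 x, x'V^-1 x and log det V -- are
therefore computed in O(n) by a bottom-up pruning pass (the three-point /
Sherman-Morrison recursion) instead of dense O(n^3) algebra.

Kernels are JIT-compiled with numba when available; the same source runs
as pure Python otherwise. The Metropolis-Hastings chain used for Bayesian
fitting lives here for the same reason: its inner loop is the pruning pass.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - numba is expected to be present
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


ALPHA_ZERO = 1e-8  # below this the BM covariance is used analytically


@njit(cache=True)
def transformed_depths(depths, T, alpha):
    """Map node depths d to f(d) = V(alpha) "depths"; identity for alpha ~ 0."""
    m = depths.shape[0]
    g = np.empty(m)
    if alpha <= ALPHA_ZERO:
        for v in range(m):
            g[v] = depths[v]
    else:
        c = 1.0 / (2.0 * alpha)
        for v in range(m):
            dv = depths[v]
            g[v] = math.exp(-2.0 * alpha * (T - dv)) * (-math.expm1(-2.0 * alpha * dv)) * c
    return g


@njit(cache=True)
def gls_stats(parent, order, depths, T, x, alpha):
    """(1'V^-1 1, 1'V^-1 x, x'V^-1 x, log det V) for V = V(alpha).

    ``order`` must list children before parents with the root last. Returns
    NaNs when a terminal edge of the transformed tree is nonpositive (the
    caller falls back to dense algebra).
    """
    g = transformed_depths(depths, T, alpha)
    m = parent.shape[0]
    n = x.shape[0]
    P = np.zeros(m)
    S = np.zeros(m)
    Q = np.zeros(m)
    D = np.zeros(m)
    for idx in range(m):
        v = order[idx]
        pa = parent[v]
        if v < n:  # tip
            ell = g[v] - g[pa]
            if ell <= 0.0:
                return np.nan, np.nan, np.nan, np.nan
            pv = 1.0 / ell
            sv = x[v] / ell
            qv = x[v] * x[v] / ell
            dv = math.log(ell)
        else:
            pv = P[v]
            sv = S[v]
            qv = Q[v]
            dv = D[v]
            if pa < 0:  # root: all tips merged
                return pv, sv, qv, dv
            ell = g[v] - g[pa]
            if ell < 0.0:
                ell = 0.0
            denom = 1.0 + ell * pv
            dv += math.log(denom)
            qv -= ell * sv * sv / denom
            pv /= denom
            sv /= denom
        P[pa] += pv
        S[pa] += sv
        Q[pa] += qv
        D[pa] += dv
    return np.nan, np.nan, np.nan, np.nan  # unreachable on valid trees


@njit(cache=True)
def mvn_loglik(p, s, q, logdet, n, mu, sig2):
    """Full MVN log-likelihood at (mu, sig2) given the pruning statistics."""
    rss = q - 2.0 * mu * s + mu * mu * p
    return -0.5 * (n * math.log(2.0 * math.pi * sig2) + logdet + rss / sig2)


@njit(cache=True)
def _logprior(mu, lsig, lal, is_ou, aprior_code, aprior_param,
              mu_low, mu_high, sig2_high):
    """Log prior density on the sampling scale (mu, log sig2, log alpha).

    Jacobian terms for the log transforms are included. aprior_code 0 is
    exponential with mean aprior_param; 1 is uniform on (0, aprior_param).
    """
    if mu < mu_low or mu > mu_high:
        return -1e300
    sig2 = math.exp(lsig)
    if sig2 >= sig2_high:
        return -1e300
    lp = -math.log(mu_high - mu_low) - math.log(sig2_high) + lsig
    if is_ou:
        a = math.exp(lal)
        if aprior_code == 0:
            lp += -math.log(aprior_param) - a / aprior_param + lal
        else:
            if a >= aprior_param:
                return -1e300
            lp += -math.log(aprior_param) + lal
    return lp


@njit(cache=True)
def mh_chain(parent, order, depths, T, x, is_ou,
             aprior_code, aprior_param, mu_low, mu_high, sig2_high,
             beta, n_iter, burn, thin, seed,
             mu0, lsig0, lal0, sc_mu, sc_ls, sc_la, adapt):
    """Component-wise random-walk Metropolis chain targeting
    prior(theta) * likelihood(theta)^beta on (mu, log sig2[, log alpha]).

    Proposal scales adapt toward ~35% acceptance during burn-in only.
    Returns post-burn-in thinned rows (mu, sig2, alpha, data loglik),
    per-component acceptance rates, the final state and the final scales.
    """
    np.random.seed(seed)
    n = x.shape[0]
    mu = mu0
    lsig = lsig0
    lal = lal0
    alpha = math.exp(lal) if is_ou else 0.0
    p, s, q, ld = gls_stats(parent, order, depths, T, x, alpha)
    sig2 = math.exp(lsig)
    ll = mvn_loglik(p, s, q, ld, n, mu, sig2)
    lp = _logprior(mu, lsig, lal, is_ou, aprior_code, aprior_param,
                   mu_low, mu_high, sig2_high)
    ncomp = 3 if is_ou else 2
    scales = np.empty(3)
    scales[0] = sc_mu
    scales[1] = sc_ls
    scales[2] = sc_la
    acc = np.zeros(3)
    trials = np.zeros(3)
    wacc = np.zeros(3)
    wtry = np.zeros(3)
    n_keep = 0
    if n_iter > burn:
        n_keep = (n_iter - burn + thin - 1) // thin
    out = np.empty((n_keep, 4))
    k = 0
    for it in range(n_iter):
        for comp in range(ncomp):
            trials[comp] += 1.0
            wtry[comp] += 1.0
            if comp == 0:
                prop = mu + scales[0] * np.random.normal()
                nlp = _logprior(prop, lsig, lal, is_ou, aprior_code, aprior_param,
                                mu_low, mu_high, sig2_high)
                if nlp > -1e299:
                    nll = mvn_loglik(p, s, q, ld, n, prop, sig2)
                    if math.log(np.random.random()) < beta * (nll - ll) + (nlp - lp):
                        mu = prop
                        ll = nll
                        lp = nlp
                        acc[0] += 1.0
                        wacc[0] += 1.0
            elif comp == 1:
                prop = lsig + scales[1] * np.random.normal()
                nlp = _logprior(mu, prop, lal, is_ou, aprior_code, aprior_param,
                                mu_low, mu_high, sig2_high)
                if nlp > -1e299:
                    nsig2 = math.exp(prop)
                    nll = mvn_loglik(p, s, q, ld, n, mu, nsig2)
                    if math.log(np.random.random()) < beta * (nll - ll) + (nlp - lp):
                        lsig = prop
                        sig2 = nsig2
                        ll = nll
                        lp = nlp
                        acc[1] += 1.0
                        wacc[1] += 1.0
            else:
                prop = lal + scales[2] * np.random.normal()
                nlp = _logprior(mu, lsig, prop, is_ou, aprior_code, aprior_param,
                                mu_low, mu_high, sig2_high)
                if nlp > -1e299:
                    nalpha = math.exp(prop)
                    np_, ns_, nq_, nld = gls_stats(parent, order, depths, T, x, nalpha)
                    nll = mvn_loglik(np_, ns_, nq_, nld, n, mu, sig2)
                    if math.log(np.random.random()) < beta * (nll - ll) + (nlp - lp):
                        lal = prop
                        alpha = nalpha
                        p = np_
                        s = ns_
                        q = nq_
                        ld = nld
                        ll = nll
                        lp = nlp
                        acc[2] += 1.0
                        wacc[2] += 1.0
        if adapt and it < burn and (it + 1) % 50 == 0:
            for c in range(ncomp):
                if wtry[c] > 0.0:
                    rate = wacc[c] / wtry[c]
                    scales[c] *= math.exp(1.2 * (rate - 0.35))
                    if scales[c] < 1e-4:
                        scales[c] = 1e-4
                    elif scales[c] > 50.0:
                        scales[c] = 50.0
                wacc[c] = 0.0
                wtry[c] = 0.0
        if it >= burn and (it - burn) % thin == 0:
            out[k, 0] = mu
            out[k, 1] = sig2
            out[k, 2] = alpha
            out[k, 3] = ll
            k += 1
    rates = np.empty(3)
    for c in range(3):
        rates[c] = acc[c] / trials[c] if trials[c] > 0 else 0.0
    return out, rates, mu, lsig, lal, scales
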