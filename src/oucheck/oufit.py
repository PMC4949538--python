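"""Maximum-likelihood fitting of BM and single-stationary-peak OU models.

Both models imply multivariate-normal tip values. For Brownian motion the
(unit-rate) covariance is the shared-ancestry matrix S with
``S_ij = s_ij`` (root-to-MRCA path length); for the OU model with pull
``alpha`` toward an optimum equal to the root state,

    V_ij(alpha) = exp(-2 alpha (T - s_ij)) * (1 - exp(-2 alpha s_ij)) / (2 alpha),

which tends to S as ``alpha -> 0`` (BM is nested at ``alpha = 0``). The
mean ``mu`` and rate ``sigma2`` are profiled out in closed form by GLS:

    mu_hat    = (1' V^-1 x) / (1' V^-1 1)
    sig2_hat  = (x - mu_hat 1)' V^-1 (x - mu_hat 1) / n
    loglik    = -1/2 [ n ln(2 pi sig2_hat) + ln det V + n ]

leaving a one-dimensional likelihood in ``alpha`` that is maximized by a
bounded search. Because ``alpha`` enters per unit of tree height, fitting is
intended for trees rescaled to height 1 (a warning is emitted otherwise).

Interpretation helpers follow common practice for unit-height trees: the
phylogenetic half-life ``t1/2 = ln(2) / alpha`` (time to close half the gap
to the optimum; half-life large relative to tree height means effectively
Brownian), the ``-log(alpha)`` scale (about +4 is almost Brownian, about -4
is essentially white noise), and the expected between-species correlation
``(e^{2 alpha s} - 1) / (e^{2 alpha} - 1)`` as a function of relative shared
time s.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sstats

from . import _core
from .phylo import Phylo, NonUltrametricError, PhyloError
from .traitsim import BMParams

__all__ = [
    "OUParams",
    "ModelFit",
    "ComparisonResult",
    "ProfileCurve",
    "AlphaInterpretation",
    "DegenerateDataError",
    "bm_cov",
    "ou_cov",
    "gls_profile_loglik",
    "fit_bm",
    "fit_ou",
    "lrt",
    "profile_alpha",
    "half_life",
    "interpret_alpha",
    "expected_correlation",
]

LRT_DF = 1
#: half the 5% critical value of chi-square(1); profile-likelihood cutoff
PROFILE_CUTOFF = 1.92
_ALPHA_ZERO = _core.ALPHA_ZERO
DEFAULT_ALPHA_UPPER = 20.0


class DegenerateDataError(ValueError):
    """Raised for trait data with (numerically) zero phylogenetic variance."""


@dataclass(frozen=True)
class OUParams:
    """Single-stationary-peak OU parameters. ``alpha`` is per unit tree
    height; ``mu`` is both the optimum and the root state."""

    alpha: float
    sigma2: float
    mu: float

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class ModelFit:
    model: str  # "BM" or "OU"
    params: object  # BMParams or OUParams
    loglik: float
    n_params: int
    converged: bool
    alpha_at_bound: bool | None = None
    data_fingerprint: str = field(default="", repr=False)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a BM-vs-OU comparison (likelihood-ratio or Bayes factor)."""

    method: str  # "lrt" or "bayes"
    reject_bm: bool
    lrt_stat: float | None = None
    df: int | None = None
    p_value: float | None = None
    bayes_factor: float | None = None
    bf_scale: str | None = None
    log_ml_bm: float | None = None
    log_ml_ou: float | None = None
    level: float | None = None


@dataclass(frozen=True)
class ProfileCurve:
    """Profile log-likelihood of alpha on a grid, with the 1.92-unit cutoff."""

    alpha_grid: np.ndarray
    loglik: np.ndarray
    cutoff: float

    @property
    def support_interval(self) -> tuple[float, float]:
        """Smallest/largest grid alpha whose profile loglik clears the cutoff
        (the LRT-consistent interval at the 5% level)."""
        mask = self.loglik >= self.cutoff
        a = self.alpha_grid[mask]
        return float(a.min()), float(a.max())

    def contains_zero(self) -> bool:
        lo, _ = self.support_interval
        return lo <= _ALPHA_ZERO


# ----------------------------------------------------------------------
# covariances
# ----------------------------------------------------------------------

def _require_ultrametric(tree: Phylo) -> None:
    if not tree.is_ultrametric():
        raise NonUltrametricError(
            "the single-stationary-peak OU model requires an ultrametric tree"
        )


def bm_cov(tree: Phylo) -> np.ndarray:
    """Shared-ancestry matrix S: S_ij = root-to-MRCA path length, S_ii = T."""
    _require_ultrametric(tree)
    return tree.mrca_depths()


def ou_cov(tree: Phylo, alpha: float) -> np.ndarray:
    """Unit-rate OU tip covariance V(alpha); V(0) is the BM matrix S."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    S = bm_cov(tree)
    if alpha <= _ALPHA_ZERO:
        return S
    T = tree.height
    return np.exp(-2.0 * alpha * (T - S)) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)


# ----------------------------------------------------------------------
# likelihood machinery
# ----------------------------------------------------------------------

def _fit_arrays(tree: Phylo):
    arrs = tree._cache.get("fit_arrays")
    if arrs is None:
        arrs = (tree.parent, tree.bottomup(), tree.depths(), tree.height)
        tree._cache["fit_arrays"] = arrs
    return arrs


def _align(tree: Phylo, traits) -> np.ndarray:
    if isinstance(traits, pd.Series):
        missing = set(tree.tip_labels) - set(traits.index)
        extra = set(traits.index) - set(tree.tip_labels)
        if missing or extra:
            raise ValueError(
                f"trait labels do not match the tree (missing: {sorted(missing)[:5]}, "
                f"extra: {sorted(extra)[:5]})"
            )
        x = traits.reindex(list(tree.tip_labels)).to_numpy(dtype=float)
    elif isinstance(traits, dict):
        return _align(tree, pd.Series(traits))
    else:
        x = np.asarray(traits, dtype=float)
        if x.shape != (tree.n_tips,):
            raise ValueError("trait array length must equal the number of tips")
    if not np.all(np.isfinite(x)):
        raise ValueError("traits must be finite")
    return np.ascontiguousarray(x)


def _fingerprint(tree: Phylo, x: np.ndarray) -> str:
    h = hashlib.md5()
    h.update(tree.parent.tobytes())
    h.update(tree.edge_length.tobytes())
    h.update(x.tobytes())
    return h.hexdigest()


def _dense_stats(tree: Phylo, x: np.ndarray, alpha: float):
    V = ou_cov(tree, alpha)
    try:
        cf = linalg.cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise PhyloError(
            f"singular OU covariance at alpha={alpha:g} "
            f"(condition estimate {np.linalg.cond(V):.2e})"
        ) from exc
    ones = np.ones(len(x))
    Vi1 = linalg.cho_solve(cf, ones)
    Vix = linalg.cho_solve(cf, x)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return float(ones @ Vi1), float(ones @ Vix), float(x @ Vix), logdet


def _stats(tree: Phylo, x: np.ndarray, alpha: float):
    parent, order, depths, T = _fit_arrays(tree)
    p, s, q, ld = _core.gls_stats(parent, order, depths, T, x, float(alpha))
    if math.isnan(p):  # zero-length terminal edges: dense fallback
        return _dense_stats(tree, x, alpha)
    return p, s, q, ld


def _profile_ll(tree: Phylo, x: np.ndarray, alpha: float):
    n = tree.n_tips
    p, s, q, ld = _stats(tree, x, alpha)
    mu = s / p
    rss = q - s * s / p
    if rss <= 1e-12 * max(1.0, abs(q)):
        raise DegenerateDataError(
            "traits have (numerically) zero variance around the phylogenetic "
            "mean; the ML rate is degenerate"
        )
    sig2 = rss / n
    ll = -0.5 * (n * math.log(2.0 * math.pi * sig2) + ld + n)
    return ll, mu, sig2


def gls_profile_loglik(tree: Phylo, traits, alpha: float):
    """Profile log-likelihood at fixed ``alpha``.

    Returns ``(loglik, mu_hat, sigma2_hat)`` with the mean and rate at their
    exact GLS maximizers for the covariance ``sigma2 * V(alpha)``.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    _require_ultrametric(tree)
    if tree.n_tips < 3:
        raise PhyloError("model fitting requires at least 3 tips")
    x = _align(tree, traits)
    return _profile_ll(tree, x, float(alpha))


def _warn_height(tree: Phylo) -> None:
    if abs(tree.height - 1.0) > 1e-6:
        warnings.warn(
            "tree height is not 1; alpha estimates are per unit of this "
            "tree's height and are not comparable across trees",
            UserWarning,
            stacklevel=3,
        )


def fit_bm(tree: Phylo, traits) -> ModelFit:
    """ML fit of Brownian motion (phylogenetic mean and rate)."""
    _require_ultrametric(tree)
    if tree.n_tips < 3:
        raise PhyloError("model fitting requires at least 3 tips")
    _warn_height(tree)
    x = _align(tree, traits)
    ll, mu, sig2 = _profile_ll(tree, x, 0.0)
    return ModelFit("BM", BMParams(sigma2=sig2, x0=mu), ll, 2, True,
                    None, _fingerprint(tree, x))


def fit_ou(tree: Phylo, traits, alpha_upper: float = DEFAULT_ALPHA_UPPER) -> ModelFit:
    """ML fit of the single-stationary-peak OU model.

    ``alpha`` is searched on ``[0, alpha_upper]`` by a log-spaced grid scan
    followed by bounded Brent refinement, with the ``alpha = 0`` endpoint
    always evaluated so the OU log-likelihood can never fall below the BM
    one. Ties within 1e-8 log-likelihood units resolve toward smaller
    ``alpha`` (the simpler reading). ``alpha_at_bound`` flags estimates
    pinned at either end of the search interval.
    """
    if alpha_upper <= 0:
        raise ValueError("alpha_upper must be positive")
    _require_ultrametric(tree)
    if tree.n_tips < 3:
        raise PhyloError("model fitting requires at least 3 tips")
    _warn_height(tree)
    x = _align(tree, traits)

    def nll(a: float) -> float:
        return -_profile_ll(tree, x, a)[0]

    grid = np.concatenate([[0.0], np.geomspace(alpha_upper * 1e-4, alpha_upper, 24)])
    vals = np.array([nll(a) for a in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    converged = True
    best_a, best_v = float(grid[i]), float(vals[i])
    if hi > lo:
        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-7 * max(1.0, alpha_upper)},
        )
        converged = bool(res.success)
        if res.fun < best_v:
            best_a, best_v = float(res.x), float(res.fun)
    # tie-break toward the nested model
    if -best_v - (-vals[0]) <= 1e-8:
        best_a, best_v = 0.0, float(vals[0])
    ll, mu, sig2 = _profile_ll(tree, x, best_a)
    at_bound = best_a <= _ALPHA_ZERO or best_a >= alpha_upper * (1.0 - 1e-4)
    return ModelFit("OU", OUParams(alpha=best_a, sigma2=sig2, mu=mu), ll, 3,
                    converged, at_bound, _fingerprint(tree, x))


def lrt(bm: ModelFit, ou: ModelFit, level: float = 0.05,
        boundary_mixture: bool = False) -> ComparisonResult:
    """Likelihood-ratio test of BM against OU with 1 degree of freedom.

    The plain chi-square(1) reference distribution is used by default (the
    convention whose type-I behaviour this package characterizes);
    ``boundary_mixture=True`` applies instead the 50:50 point-mass/chi2(1)
    null appropriate for a parameter on its boundary.
    """
    if bm.model != "BM" or ou.model != "OU":
        raise ValueError("lrt expects (BM fit, OU fit) in that order")
    if bm.data_fingerprint and ou.data_fingerprint and \
            bm.data_fingerprint != ou.data_fingerprint:
        raise ValueError("the two fits describe different datasets")
    stat = 2.0 * (ou.loglik - bm.loglik)
    stat = max(stat, 0.0)
    if boundary_mixture:
        p = 0.5 * float(sstats.chi2.sf(stat, LRT_DF)) if stat > 0 else 1.0
    else:
        p = float(sstats.chi2.sf(stat, LRT_DF))
    return ComparisonResult(method="lrt", reject_bm=bool(p < level),
                            lrt_stat=stat, df=LRT_DF, p_value=p, level=level)


def profile_alpha(tree: Phylo, traits, alpha_grid) -> ProfileCurve:
    """Profile log-likelihood along ``alpha_grid`` with the 1.92-unit cutoff.

    Values of alpha whose profile log-likelihood stays within 1.92 units of
    the maximum are statistically indistinguishable from the ML estimate
    under the 1-df likelihood-ratio test.
    """
    grid = np.asarray(alpha_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alpha_grid must not be empty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("alpha_grid must be nonnegative and strictly increasing")
    _require_ultrametric(tree)
    x = _align(tree, traits)
    lls = np.array([_profile_ll(tree, x, a)[0] for a in grid])
    return ProfileCurve(grid, lls, float(lls.max()) - PROFILE_CUTOFF)


# ----------------------------------------------------------------------
# interpretation helpers
# ----------------------------------------------------------------------

def half_life(alpha: float) -> float:
    """Phylogenetic half-life ln(2)/alpha, in the time units of 1/alpha."""
    if alpha <= 0:
        raise ValueError(
            "alpha <= 0 is effectively Brownian; the phylogenetic half-life "
            "is undefined (infinite)"
        )
    return math.log(2.0) / alpha


@dataclass(frozen=True)
class AlphaInterpretation:
    alpha: float
    neg_log_alpha: float
    half_life: float
    category: str
    note: str


def interpret_alpha(alpha: float, tree_height: float = 1.0) -> AlphaInterpretation:
    """Categorical reading of an attraction strength on a unit-height tree.

    Thresholds: ``-ln(alpha) >= 4`` reads "almost Brownian" and
    ``-ln(alpha) <= -4`` reads "essentially white noise"; everything in
    between is "moderate". The half-life relative to tree height carries the
    same information (half-life comparable to tree height is moderate).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive; alpha = 0 is exactly Brownian")
    if abs(tree_height - 1.0) > 1e-6:
        warnings.warn("interpretation thresholds assume a unit-height tree",
                      UserWarning, stacklevel=2)
    nla = -math.log(alpha)
    hl = half_life(alpha)
    if nla >= 4.0:
        cat = "almost Brownian"
        note = ("attraction is negligible on the timescale of the tree; "
                "do not interpret an OU process")
    elif nla <= -4.0:
        cat = "essentially white noise"
        note = ("history is erased; tip values are nearly independent of the "
                "phylogeny")
    else:
        cat = "moderate"
        note = "half-life is comparable to tree height; inspect the profile"
    return AlphaInterpretation(alpha, nla, hl, cat, note)


def expected_correlation(alpha: float, rel_shared_time):
    """Expected correlation between two species under the OU model.

    For relative shared time ``s = s_ij / T`` on a unit-height tree the
    correlation is ``(e^{2 alpha s} - 1) / (e^{2 alpha} - 1)``; the
    ``alpha -> 0`` limit is ``s`` (Brownian motion) and for large ``alpha``
    the correlation vanishes for every ``s < 1``.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    s = np.asarray(rel_shared_time, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("rel_shared_time must lie in [0, 1]")
    z = 2.0 * alpha
    if z <= 1e-12:
        out = s.copy()
    elif z < 350.0:
        out = np.expm1(z * s) / np.expm1(z)
    else:  # avoid overflow; the -1 terms are negligible
        out = np.exp(z * (s - 1.0))
    if np.isscalar(rel_shared_time) or np.ndim(rel_shared_time) == 0:
        return float(out)
    return out
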