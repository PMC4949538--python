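"""Simulate continuous traits on trees, and the tip-elongation error model.

Brownian motion accumulates independent normal increments along every edge,
so tip values are multivariate normal with mean ``x0`` and covariance
``sigma2 * S`` where ``S_ij`` is the shared root-to-MRCA path length. The
default simulation is the O(n) edge-wise recursion; a dense Cholesky draw
is available as an alternative route for cross-checking.

"Measurement error" (intraspecific variation, sampling noise, ...) is
emulated the way the tip-elongation procedure defines it: every terminal
edge of the tree is lengthened by a stated fraction of tree height *before*
traits are simulated, which adds independent variance
``sigma2 * fraction * T`` to every tip, while model fitting later uses the
original, unelongated tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .phylo import Phylo, PhyloError

__all__ = [
    "BMParams",
    "TraitVector",
    "simulate_bm",
    "simulate_ou",
    "elongate_tips",
    "simulate_bm_with_error",
    "read_traits",
    "write_traits",
]

#: Trait vectors are represented as pandas Series indexed by tip label.
TraitVector = pd.Series


@dataclass(frozen=True)
class BMParams:
    """Brownian-motion parameters: rate sigma2 (trait variance per unit
    branch length) and root state x0."""

    sigma2: float = 1.0
    x0: float = 0.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def _series(values: np.ndarray, tree: Phylo) -> TraitVector:
    s = pd.Series(values, index=list(tree.tip_labels), name="value")
    s.index.name = "tip_label"
    return s


def _recursive_gaussian(tree: Phylo, edge_var: np.ndarray, root_state: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Accumulate independent N(0, edge_var) increments from root to tips."""
    incr = rng.standard_normal(tree.n_nodes) * np.sqrt(edge_var)
    values = np.empty(tree.n_nodes)
    pre = tree.preorder()
    values[tree.root] = root_state
    par = tree.parent
    for v in pre[1:]:
        values[v] = values[par[v]] + incr[v]
    return values[: tree.n_tips]


def simulate_bm(tree: Phylo, params: BMParams = BMParams(), seed: int = 0,
                method: str = "recursive") -> TraitVector:
    """Simulate one Brownian trait on ``tree``.

    ``method="recursive"`` draws edge-wise increments in O(n);
    ``method="cholesky"`` draws from the dense MVN directly. The two agree
    in distribution (not draw-for-draw for a given seed).
    """
    if not tree.is_ultrametric():
        raise PhyloError("trait simulation expects an ultrametric tree")
    rng = np.random.default_rng(seed)
    if method == "recursive":
        ev = params.sigma2 * tree.edge_length.copy()
        ev[tree.root] = 0.0
        x = _recursive_gaussian(tree, ev, params.x0, rng)
    elif method == "cholesky":
        S = tree.mrca_depths()
        L = np.linalg.cholesky(params.sigma2 * S)
        x = params.x0 + L @ rng.standard_normal(tree.n_tips)
    else:
        raise ValueError("method must be 'recursive' or 'cholesky'")
    return _series(x, tree)


def simulate_ou(tree: Phylo, alpha: float, sigma2: float = 1.0, mu: float = 0.0,
                seed: int = 0) -> TraitVector:
    """Exact draw from the single-stationary-peak OU tip distribution.

    The OU covariance on an ultrametric tree is tree-structured, so the
    draw reduces to Gaussian increments with variances given by differences
    of the OU-transformed node depths; the root state equals the optimum mu.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not tree.is_ultrametric():
        raise PhyloError("the single-stationary-peak OU model requires an ultrametric tree")
    rng = np.random.default_rng(seed)
    depths = tree.depths()
    g = _core.transformed_depths(depths, tree.height, float(alpha))
    ev = np.zeros(tree.n_nodes)
    par = tree.parent
    mask = par >= 0
    ev[mask] = sigma2 * np.maximum(g[mask] - g[par[mask]], 0.0)
    x = _recursive_gaussian(tree, ev, mu, rng)
    return _series(x, tree)


def elongate_tips(tree: Phylo, fraction: float) -> Phylo:
    """Lengthen every terminal edge by ``fraction`` of the tree height.

    The result is ultrametric with height ``T * (1 + fraction)``; topology
    and internal edges are untouched.
    """
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    elen = tree.edge_length.copy()
    elen[: tree.n_tips] += fraction * tree.height
    return Phylo(tree.parent.copy(), elen, tree.tip_labels, validate=False)


def simulate_bm_with_error(tree: Phylo, params: BMParams = BMParams(),
                           fraction: float = 0.0, seed: int = 0) -> TraitVector:
    """Brownian trait simulated on the tip-elongated tree.

    Equivalent to ``simulate_bm(elongate_tips(tree, fraction), params, seed)``.
    The fitting layer deliberately receives the *original* tree, which is what
    turns the extra terminal variance into apparent attraction.
    """
    return simulate_bm(elongate_tips(tree, fraction), params, seed)


def read_traits(path) -> TraitVector:
    """Read a two-column delimited table (header ``tip_label<TAB>value``)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] != 2:
        raise ValueError(f"expected a two-column trait table, got {df.shape[1]} columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                  index=df.iloc[:, 0].astype(str))
    s.name = "value"
    s.index.name = "tip_label"
    if s.index.duplicated().any():
        raise ValueError("duplicate tip labels in trait table")
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("trait table contains non-finite values")
    return s


def write_traits(traits: TraitVector, path) -> None:
    df = pd.DataFrame({"tip_label": traits.index, "value": traits.to_numpy()})
    df.to_csv(path, sep="\t", index=False)
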