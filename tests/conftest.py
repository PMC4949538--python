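"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the package's own tree arithmetic:
shared-ancestry matrices come from dendropy node-path enumeration, and
likelihoods from dense multivariate-normal evaluation.
"""

import numpy as np
import pytest
import dendropy

import oucheck as oc


@pytest.fixture(autouse=True)
def _silence_height_warning():
    """Many fixtures use non-unit-height trees on purpose."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="tree height is not 1")
        yield


@pytest.fixture
def tree3():
    return oc.loads_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree6():
    return oc.rescale_height(oc.simulate_pure_birth(6, 42), 1.0)


@pytest.fixture(scope="session")
def tree10():
    return oc.rescale_height(oc.simulate_pure_birth(10, 7), 1.0)


def brute_mrca_depths(tree: oc.Phylo) -> np.ndarray:
    """Shared-ancestry matrix via dendropy pairwise MRCA search."""
    dtree = dendropy.Tree.get(data=oc.dumps_newick(tree), schema="newick",
                              preserve_underscores=True)
    pdm = dtree.phylogenetic_distance_matrix()
    labels = list(tree.tip_labels)
    taxa = {t.label: t for t in dtree.taxon_namespace}
    depth = {leaf.taxon.label: leaf.distance_from_root()
             for leaf in dtree.leaf_node_iter()}
    n = len(labels)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                S[i, j] = depth[labels[i]]
            else:
                mrca = pdm.mrca(taxa[labels[i]], taxa[labels[j]])
                S[i, j] = mrca.distance_from_root()
    return S


def dense_ou_loglik(tree: oc.Phylo, traits, alpha: float, mu: float,
                    sigma2: float) -> float:
    """Dense MVN log density with the OU covariance built from the
    dendropy-derived shared-ancestry matrix."""
    S = brute_mrca_depths(tree)
    T = float(np.max(np.diag(S)))
    if alpha <= 1e-8:
        V = S
    else:
        V = np.exp(-2 * alpha * (T - S)) * (-np.expm1(-2 * alpha * S)) / (2 * alpha)
    x = np.asarray(traits.reindex(list(tree.tip_labels)), dtype=float)
    n = len(x)
    C = sigma2 * V
    sign, logdet = np.linalg.slogdet(C)
    r = x - mu
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(C, r)))


def branching_depths(tree: oc.Phylo) -> np.ndarray:
    """Depths of the internal (branching) nodes, root included at 0."""
    d = tree.depths()
    return np.sort(d[tree.n_tips:])
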