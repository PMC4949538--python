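"""Simulate ultrametric phylogenies conditioned on a fixed number of tips.

Three diversification regimes are provided:

``pure_birth``
    Constant per-lineage speciation rate (Yule process).
``birth_death``
    Constant speciation and extinction rates, parameterized by the
    extinction fraction d/b; the *reconstructed* tree of extant tips is
    returned.
``time_varying``
    Pure birth whose per-lineage speciation rate at time t from the root is
    proportional to ``t ** exponent``; small exponents give nearly constant
    rates, large exponents concentrate branching near the present ("tippy"
    trees).

All simulators condition on the number of extant tips by forward simulation:
the process is run until n extant lineages exist and the present is set to
the epoch at which the next event would have occurred (rejection and restart
if a birth-death process dies out first). Absolute rates are immaterial
because trees are rescaled to unit height before traits are simulated or
models fitted, so the base speciation rate and the proportionality constant
of the time-varying rate are fixed at 1.

Tips are labelled ``t1 .. tn`` in the order their lineages were born.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phylo import Phylo, PhyloError, read_newick, write_newick, rescale_height

__all__ = [
    "TreeModelSpec",
    "simulate_pure_birth",
    "simulate_birth_death",
    "simulate_time_varying",
    "rescale_height",
    "read_newick",
    "write_newick",
]

_REGIMES = ("pure_birth", "birth_death", "time_varying")


@dataclass(frozen=True)
class TreeModelSpec:
    """A diversification regime plus a target tip count.

    ``extinction_fraction`` applies to ``birth_death`` only (d/b, must be
    < 1); ``exponent`` applies to ``time_varying`` only (must be > 0).
    ``n_tips`` may be left as None in grid templates and filled in with
    :meth:`with_n_tips`.
    """

    regime: str
    n_tips: int | None = None
    extinction_fraction: float = 0.0
    exponent: float | None = None

    def __post_init__(self):
        if self.regime not in _REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {_REGIMES}")
        if not (0.0 <= self.extinction_fraction < 1.0):
            raise ValueError("extinction_fraction must be in [0, 1)")
        if self.regime == "time_varying":
            if self.exponent is None or self.exponent <= 0:
                raise ValueError("time_varying regime requires exponent > 0")
        if self.n_tips is not None and self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")

    def with_n_tips(self, n_tips: int) -> "TreeModelSpec":
        return replace(self, n_tips=n_tips)

    @property
    def label(self) -> str:
        if self.regime == "birth_death" or (
            self.regime == "pure_birth" and self.extinction_fraction == 0.0
        ):
            frac = self.extinction_fraction if self.regime == "birth_death" else 0.0
            return f"d/b = {frac:g}"
        if self.regime == "pure_birth":
            return "d/b = 0"
        return f"rate ~ t^{self.exponent:g}"

    def simulate(self, seed: int) -> Phylo:
        if self.n_tips is None:
            raise ValueError("n_tips not set on this TreeModelSpec")
        if self.regime == "pure_birth":
            return simulate_pure_birth(self.n_tips, seed)
        if self.regime == "birth_death":
            return simulate_birth_death(self.n_tips, self.extinction_fraction, seed)
        return simulate_time_varying(self.n_tips, self.exponent, seed)


def _check_n(n_tips: int) -> None:
    if n_tips < 3:
        raise PhyloError("n_tips must be >= 3")


def _assemble(internal_parent, internal_time, branches, t_end, n):
    """Build a Phylo from the bookkeeping of a forward birth simulation.

    ``branches`` holds the surviving lineages as (parent internal id, birth
    order); internal ids index ``internal_parent``/``internal_time``.
    """
    order = np.argsort([b[1] for b in branches], kind="stable")
    m = 2 * n - 1
    parent = np.empty(m, dtype=np.int64)
    elen = np.zeros(m)
    itime = np.asarray(internal_time)
    for i, k in enumerate(order):
        pid = branches[k][0]
        parent[i] = n + pid
        elen[i] = t_end - itime[pid]
    for j in range(n - 1):
        p = internal_parent[j]
        parent[n + j] = -1 if p < 0 else n + p
        elen[n + j] = 0.0 if p < 0 else itime[j] - itime[p]
    labels = [f"t{i + 1}" for i in range(n)]
    return Phylo(parent, elen, labels, validate=False)


def simulate_pure_birth(n_tips: int, seed: int, rate: float = 1.0) -> Phylo:
    """Simulate a Yule tree with exactly ``n_tips`` extant tips.

    Waiting times between speciation events are exponential with total rate
    ``k * rate`` for k current lineages; the splitting lineage is chosen
    uniformly. Deterministic for a given seed.
    """
    _check_n(n_tips)
    if rate <= 0:
        raise PhyloError("rate must be positive")
    rng = np.random.default_rng(seed)
    internal_parent = [-1]
    internal_time = [0.0]
    branches = [(0, 0), (0, 1)]
    counter = 2
    t = 0.0
    while len(branches) < n_tips:
        k = len(branches)
        t += rng.exponential(1.0 / (rate * k))
        i = int(rng.integers(k))
        pid, _ = branches.pop(i)
        v = len(internal_time)
        internal_parent.append(pid)
        internal_time.append(t)
        branches.append((v, counter))
        branches.append((v, counter + 1))
        counter += 2
    t_end = t + rng.exponential(1.0 / (rate * n_tips))
    return _assemble(internal_parent, internal_time, branches, t_end, n_tips)


def simulate_time_varying(n_tips: int, exponent: float, seed: int) -> Phylo:
    """Pure-birth tree whose per-lineage speciation rate at time t from the
    root is ``t ** exponent``.

    Waiting times are drawn by inverting the cumulative per-lineage rate
    ``Lambda(t) = t**(exponent+1) / (exponent+1)``: with k lineages alive at
    time t0, the next event solves
    ``k * (Lambda(t) - Lambda(t0)) = E``, ``E ~ Exp(1)``, giving
    ``t = (t0**(b+1) + (b+1) E / k) ** (1/(b+1))``.
    """
    _check_n(n_tips)
    if exponent is None or exponent <= 0:
        raise PhyloError("exponent must be > 0")
    rng = np.random.default_rng(seed)
    b1 = exponent + 1.0

    def next_time(t0: float, k: int) -> float:
        e = rng.exponential()
        return (t0 ** b1 + b1 * e / k) ** (1.0 / b1)

    internal_parent = [-1]
    internal_time = [0.0]
    branches = [(0, 0), (0, 1)]
    counter = 2
    t = 0.0
    while len(branches) < n_tips:
        k = len(branches)
        t = next_time(t, k)
        i = int(rng.integers(k))
        pid, _ = branches.pop(i)
        v = len(internal_time)
        internal_parent.append(pid)
        internal_time.append(t)
        branches.append((v, counter))
        branches.append((v, counter + 1))
        counter += 2
    t_end = next_time(t, n_tips)
    return _assemble(internal_parent, internal_time, branches, t_end, n_tips)


def simulate_birth_death(
    n_tips: int, extinction_fraction: float, seed: int, birth_rate: float = 1.0
) -> Phylo:
    """Constant-rate birth-death tree conditioned on ``n_tips`` extant tips.

    ``extinction_fraction`` is the death/birth rate ratio d/b and must be
    < 1. The process starts from the root split, is restarted whenever all
    lineages die, and stops the first time ``n_tips`` lineages are alive;
    extinct lineages are then pruned and unifurcations suppressed, so the
    returned (reconstructed) tree is ultrametric with exactly ``n_tips``
    tips and no zero-length terminal edges.
    """
    _check_n(n_tips)
    if not (0.0 <= extinction_fraction < 1.0):
        raise PhyloError("extinction_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    b = float(birth_rate)
    d = extinction_fraction * b
    total = b + d
    p_birth = b / total

    while True:  # rejection on total extinction
        # full-tree bookkeeping: nodes are created parents-before-children
        node_parent = [-1]
        node_time = [0.0]
        alive = [(0, 0), (0, 1)]  # (parent node id, birth order)
        counter = 2
        t = 0.0
        extinct = True
        while alive:
            k = len(alive)
            if k >= n_tips:
                extinct = False
                break
            t += rng.exponential(1.0 / (total * k))
            i = int(rng.integers(k))
            pid, order = alive.pop(i)
            v = len(node_time)
            node_parent.append(pid)
            node_time.append(t)
            if rng.random() < p_birth:
                alive.append((v, counter))
                alive.append((v, counter + 1))
                counter += 2
            # else: v is an extinct tip; nothing more to do
        if not extinct:
            break

    t_end = t + rng.exponential(1.0 / (total * n_tips))
    # materialize extant tips as nodes
    extant_ids = []
    orders = {}
    for pid, order in alive:
        v = len(node_time)
        node_parent.append(pid)
        node_time.append(t_end)
        extant_ids.append(v)
        orders[v] = order
    return _reconstruct(node_parent, node_time, extant_ids, orders, n_tips)


def _reconstruct(node_parent, node_time, extant_ids, orders, n):
    """Prune extinct lineages and suppress unifurcations.

    Relies on nodes being created parents-before-children so a single
    reversed pass counts extant descendants.
    """
    m = len(node_parent)
    children = [[] for _ in range(m)]
    for v in range(1, m):
        children[node_parent[v]].append(v)
    extant = set(extant_ids)
    # children have larger indices than parents, so a single reversed pass
    # accumulates extant-descendant counts
    count = [1 if v in extant else 0 for v in range(m)]
    for v in range(m - 1, 0, -1):
        count[node_parent[v]] += count[v]

    def descend(v):
        """Follow single-survivor chains down to the next branching node or tip."""
        while v not in extant:
            surv = [c for c in children[v] if count[c] > 0]
            if len(surv) >= 2:
                return v
            v = surv[0]
        return v

    new_root = descend(0)
    # breadth-first construction of the reconstructed tree
    tip_entries = []  # (order, old id, parent old id)
    edges = {}  # old id -> (parent old id)
    stack = [new_root]
    while stack:
        v = stack.pop()
        if v in extant:
            continue
        for c in children[v]:
            if count[c] == 0:
                continue
            real = descend(c)
            edges[real] = v
            stack.append(real)

    old_tips = sorted(extant, key=lambda v: orders[v])
    old_internals = [new_root] + [v for v in edges if v not in extant]
    # deterministic internal ordering: by node creation id
    old_internals = sorted(set(old_internals))
    index = {v: i for i, v in enumerate(old_tips)}
    index.update({v: n + j for j, v in enumerate(old_internals)})
    mm = 2 * n - 1
    parent = np.full(mm, -1, dtype=np.int64)
    elen = np.zeros(mm)
    for old, pold in edges.items():
        v = index[old]
        parent[v] = index[pold]
        elen[v] = node_time[old] - node_time[pold]
    labels = [f"t{i + 1}" for i in range(n)]
    return Phylo(parent, elen, labels)
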