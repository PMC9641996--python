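"""Independent reference implementations used to verify the package.

Everything here is deliberately brute-force and shares no code with the
implementations under test: likelihoods by enumeration over internal
node states, parsimony by exhaustive labeling, Stuart's statistic by an
explicit dense solve, densities via scipy's multivariate normal.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm
from scipy.stats import multivariate_normal

from gerrophylo.tree import Tree


def enum_mk_likelihood(
    tree: Tree, tip_states: dict[str, int | None], Q: np.ndarray, prior: np.ndarray
) -> tuple[float, dict[int, np.ndarray]]:
    """Likelihood and marginals by summing over all internal assignments."""
    k = Q.shape[0]
    P = {v: expm(Q * float(tree.blen[v])) for v in range(tree.n_nodes)}
    internals = tree.internal_indices
    tips = tree.tip_indices
    total = 0.0
    mass = {v: np.zeros(k) for v in range(tree.n_nodes)}
    tip_choices = {}
    for tp in tips:
        s = tip_states.get(tree.labels[tp])
        tip_choices[tp] = [s] if s is not None else list(range(k))
    for assign_int in itertools.product(range(k), repeat=len(internals)):
        a = dict(zip(internals, assign_int))
        for assign_tip in itertools.product(*(tip_choices[tp] for tp in tips)):
            a.update(dict(zip(tips, assign_tip)))
            w = prior[a[tree.root]]
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                w *= P[v][a[tree.parent[v]], a[v]]
            total += w
            for v in range(tree.n_nodes):
                mass[v][a[v]] += w
    marg = {v: mass[v] / total for v in mass}
    return total, marg


def exhaustive_parsimony(
    tree: Tree, tip_states: dict[str, int | None], cost: np.ndarray
) -> float:
    """Minimum total cost over all internal labelings (and missing tips)."""
    k = cost.shape[0]
    internals = tree.internal_indices
    tips = tree.tip_indices
    tip_choices = {}
    for tp in tips:
        s = tip_states.get(tree.labels[tp])
        tip_choices[tp] = [s] if s is not None else list(range(k))
    best = math.inf
    for assign_int in itertools.product(range(k), repeat=len(internals)):
        a = dict(zip(internals, assign_int))
        for assign_tip in itertools.product(*(tip_choices[tp] for tp in tips)):
            a.update(dict(zip(tips, assign_tip)))
            c = 0.0
            for v in range(tree.n_nodes):
                if v != tree.root:
                    c += cost[a[tree.parent[v]], a[v]]
            best = min(best, c)
    return best


def fitch_changes(tree: Tree, tip_states: dict[str, int]) -> int:
    """Fitch small-parsimony change count (binary or multistate, unit cost)."""
    sets: dict[int, frozenset[int]] = {}
    changes = 0
    for v in tree.postorder:
        if tree.is_tip(v):
            sets[v] = frozenset({tip_states[tree.labels[v]]})
            continue
        inter = None
        union: frozenset[int] = frozenset()
        for c in tree.children[v]:
            inter = sets[c] if inter is None else inter & sets[c]
            union = union | sets[c]
        if inter:
            sets[v] = inter
        else:
            sets[v] = union
            changes += len(tree.children[v]) - 1  # binary: +1
    return changes


def mvn_logdensity(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    return float(multivariate_normal(mean=mean, cov=cov).logpdf(x))


def stuart_stat_dense(n: np.ndarray) -> float | None:
    """Stuart's marginal-homogeneity statistic by explicit construction."""
    n = np.asarray(n, dtype=float)
    d = n.sum(axis=1) - n.sum(axis=0)
    V = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            if i == j:
                V[i, j] = n.sum(axis=1)[i] + n.sum(axis=0)[i] - 2 * n[i, i]
            else:
                V[i, j] = -(n[i, j] + n[j, i])
    u = d[:3]
    Vp = np.linalg.pinv(V)
    if not np.allclose(V @ (Vp @ u), u, atol=1e-8):
        return None  # u outside the range of V: statistic undefined
    return float(u @ Vp @ u)


def two_state_p_matrix(q: float, t: float) -> np.ndarray:
    """Closed-form 2-state ER transition matrix, off-rate q each way."""
    same = 0.5 * (1.0 + math.exp(-2.0 * q * t))
    return np.array([[same, 1 - same], [1 - same, same]])


def random_tree(rng: np.random.Generator, n_tips: int, max_bl: float = 1.0) -> Tree:
    """Random binary tree topology with uniform branch lengths."""
    # start from a cherry, attach remaining tips by subdividing random edges
    parent = [-1, 0, 0]
    blen = [0.0, rng.uniform(0.05, max_bl), rng.uniform(0.05, max_bl)]
    labels: list[str | None] = [None, "t1", "t2"]
    children = {0: [1, 2]}
    for i in range(3, n_tips + 1):
        # pick a non-root node to split above
        cand = [v for v in range(1, len(parent))]
        v = int(cand[rng.integers(len(cand))])
        p = parent[v]
        new_int = len(parent)
        parent.append(p)
        blen.append(blen[v] * rng.uniform(0.2, 0.8))
        labels.append(None)
        blen[v] = blen[v] - blen[new_int]
        parent[v] = new_int
        new_tip = len(parent)
        parent.append(new_int)
        blen.append(rng.uniform(0.05, max_bl))
        labels.append(f"t{i}")
    return Tree(parent, blen, labels)
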