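"""Continuous-trait phylogenetic signal and Brownian ancestral states.

Pagel's lambda by profile maximum likelihood (sigma^2 and the root value
concentrated out analytically at each lambda), Brownian-motion
log-likelihoods, and GLS ancestral state estimation with variances and
95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .tree import Tree

__all__ = [
    "ContinuousTrait",
    "LambdaFit",
    "AncestralEstimates",
    "lambda_max",
    "lambda_transform",
    "bm_loglik",
    "fit_lambda",
    "anc_bm",
]


@dataclass
class ContinuousTrait:
    values: dict[str, float]  # tip label -> value

    def __post_init__(self) -> None:
        bad = [t for t, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite trait values at {bad}")

    def vector(self, labels: list[str]) -> np.ndarray:
        return np.array([self.values[t] for t in labels], dtype=float)


@dataclass
class LambdaFit:
    lam: float
    sigma2: float
    z0: float
    lnL: float
    lnL_lambda0: float
    p_vs_zero: float


@dataclass
class AncestralEstimates:
    estimates: dict[int, float]  # node index -> value
    variances: dict[int, float]
    ci_low: dict[int, float]
    ci_high: dict[int, float]
    sigma2: float
    node_labels: dict[int, str]


# ----------------------------------------------------------------------
# lambda transform
# ----------------------------------------------------------------------
def lambda_max(tree: Tree) -> float:
    """Largest lambda keeping all transformed tip branch lengths >= 0."""
    depth = tree.depths()
    lo = math.inf
    for tip in tree.tip_indices:
        pd = depth[tree.parent[tip]]
        if pd > 0:
            lo = min(lo, depth[tip] / pd)
    return float(lo) if math.isfinite(lo) else 1.0


def lambda_transform(tree: Tree, lam: float) -> Tree:
    """Scale internal-branch contributions by lambda, preserving
    root-to-tip distances (tip branches absorb the difference)."""
    if not 0.0 <= lam <= lambda_max(tree) + 1e-12:
        raise ValueError(f"lambda {lam} outside [0, {lambda_max(tree):.6g}]")
    out = tree.copy()
    depth = tree.depths()
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        if tree.is_tip(v):
            out.blen[v] = depth[v] - lam * depth[tree.parent[v]]
        else:
            out.blen[v] = lam * tree.blen[v]
    return Tree(out.parent, out.blen, out.labels)


def _lambda_vcv(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


# ----------------------------------------------------------------------
# BM likelihood
# ----------------------------------------------------------------------
def bm_loglik(tree: Tree, trait: ContinuousTrait, sigma2: float, z0: float) -> float:
    """Multivariate-normal log-density of tip values under BM."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    labels = [t for t in tree.tip_labels if t in trait.values]
    if len(labels) < 1:
        raise ValueError("no tips with data")
    x = trait.vector(labels)
    C = _sub_vcv(tree, labels)
    V = sigma2 * C
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular BM covariance (zero-length tips?)")
    r = x - z0
    quad = float(r @ np.linalg.solve(V, r))
    n = len(x)
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


def _sub_vcv(tree: Tree, labels: list[str]) -> np.ndarray:
    all_labels = tree.tip_labels
    C = tree.vcv()
    idx = [all_labels.index(t) for t in labels]
    return C[np.ix_(idx, idx)]


# ----------------------------------------------------------------------
# Pagel's lambda
# ----------------------------------------------------------------------
def _profile_lnL(C_lam: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """ML lnL with z0 and sigma2 concentrated out, given unit-rate cov."""
    n = len(x)
    sign, logdet = np.linalg.slogdet(C_lam)
    if sign <= 0:
        return -math.inf, math.nan, math.nan
    Cinv_x = np.linalg.solve(C_lam, x)
    ones = np.ones(n)
    Cinv_1 = np.linalg.solve(C_lam, ones)
    z0 = float(ones @ Cinv_x) / float(ones @ Cinv_1)
    r = x - z0
    quad = float(r @ np.linalg.solve(C_lam, r))
    sigma2 = quad / n
    if sigma2 <= 0:
        return -math.inf, z0, 0.0
    lnL = -0.5 * (
        n * math.log(2.0 * math.pi) + n * math.log(sigma2) + logdet + n
    )
    return lnL, z0, sigma2


def fit_lambda(
    tree: Tree,
    trait: ContinuousTrait,
    boundary_correction: bool = False,
) -> LambdaFit:
    """Joint ML fit of (lambda, sigma2, z0) by bounded profile search.

    The p-value against lambda = 0 is the chi-square(df=1) upper tail of
    the likelihood ratio (optionally halved for the boundary case).
    """
    labels = [t for t in tree.tip_labels if t in trait.values]
    if len(labels) < 3:
        raise ValueError("need >= 3 tips with data")
    x = trait.vector(labels)
    if np.ptp(x) == 0:
        raise ValueError("no variance in trait values")
    C = _sub_vcv(tree, labels)
    ub = min(lambda_max(tree), 1.0 if _offdiag_max(C) == 0 else _lam_ub(C))

    def neg(lam: float) -> float:
        return -_profile_lnL(_lambda_vcv(C, lam), x)[0]

    res = minimize_scalar(
        neg, bounds=(0.0, ub), method="bounded", options={"xatol": 1e-8}
    )
    lam = float(res.x)
    # the bounded optimiser can miss boundary optima; check them explicitly
    cands = [(neg(0.0), 0.0), (neg(ub), ub), (float(res.fun), lam)]
    best_fun, lam = min(cands, key=lambda c: c[0])
    lnL, z0, sigma2 = _profile_lnL(_lambda_vcv(C, lam), x)
    lnL0 = _profile_lnL(_lambda_vcv(C, 0.0), x)[0]
    stat = max(2.0 * (lnL - lnL0), 0.0)
    p = float(chi2.sf(stat, 1))
    if boundary_correction:
        p = 0.5 * p if stat > 0 else 1.0
    return LambdaFit(lam=lam, sigma2=sigma2, z0=z0, lnL=lnL, lnL_lambda0=lnL0, p_vs_zero=p)


def _offdiag_max(C: np.ndarray) -> float:
    off = C - np.diag(np.diag(C))
    return float(np.abs(off).max())


def _lam_ub(C: np.ndarray) -> float:
    # keep C_lam positive definite: diagonal dominance bound is too strict;
    # use the realisable-tree bound via diag/offdiag ratio, capped at ~1.1
    d = np.diag(C)
    off = C - np.diag(d)
    mx = off.max()
    if mx <= 0:
        return 1.0
    return min(float(d.min() / mx), 1.1)


# ----------------------------------------------------------------------
# ancestral estimation (GLS / rerooting)
# ----------------------------------------------------------------------
def _node_tip_distances(tree: Tree) -> np.ndarray:
    """Path distance d(v, tip) for every node x tip (via depths + MRCA)."""
    depth = tree.depths()
    tips = tree.tip_indices
    n = tree.n_nodes
    D = np.zeros((n, len(tips)))
    # ancestor sets for MRCA by path intersection
    anc: list[list[int]] = [[] for _ in range(n)]
    for v in range(n):
        u = v
        chain = []
        while u != -1:
            chain.append(u)
            u = tree.parent[u]
        anc[v] = chain
    anc_sets = [set(ch) for ch in anc]
    for ti, tip in enumerate(tips):
        tip_anc = anc_sets[tip]
        for v in range(n):
            # first common ancestor on v's chain
            for u in anc[v]:
                if u in tip_anc:
                    D[v, ti] = depth[v] + depth[tip] - 2.0 * depth[u]
                    break
    return D


def anc_bm(tree: Tree, trait: ContinuousTrait, z_alpha: float = 1.96) -> AncestralEstimates:
    """ML (GLS) ancestral states under BM with variances and CIs.

    Each internal node's estimate is the GLS mean of the tree rerooted
    at that node; its variance is sigma2_hat / (1' C_v^-1 1) with
    sigma2_hat the (n-1)-denominator GLS estimate at the original root.
    Tips missing data are pruned with a warning upstream.
    """
    labels = [t for t in tree.tip_labels if t in trait.values]
    if len(labels) < 2:
        raise ValueError("need >= 2 tips with data")
    x = trait.vector(labels)
    n = len(x)
    tips_all = tree.tip_labels
    col = [tips_all.index(t) for t in labels]
    C = _sub_vcv(tree, labels)
    ones = np.ones(n)
    Cinv_1 = np.linalg.solve(C, ones)
    Cinv_x = np.linalg.solve(C, x)
    z0 = float(ones @ Cinv_x) / float(ones @ Cinv_1)
    r = x - z0
    sigma2 = float(r @ np.linalg.solve(C, r)) / max(n - 1, 1)

    depth = tree.depths()
    D = _node_tip_distances(tree)[:, col]  # node x kept-tip distances
    est: dict[int, float] = {}
    var: dict[int, float] = {}
    # tip-tip distances: d(i,j) = C[i,i] + C[j,j] - 2 C[i,j]
    dij = np.add.outer(np.diag(C), np.diag(C)) - 2.0 * C
    for v in tree.internal_indices:
        d_v = D[v]
        # vcv of the tree rerooted at v: C_v[i,j] = (d(v,i)+d(v,j)-d(i,j))/2
        Cv = 0.5 * (np.add.outer(d_v, d_v) - dij)
        # guard: exact zeros on the diagonal mean v coincides with a tip
        jitter = 0.0
        try:
            Cv_inv_1 = np.linalg.solve(Cv, ones)
            Cv_inv_x = np.linalg.solve(Cv, x)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * max(float(np.diag(Cv).max()), 1.0)
            Cv_inv_1 = np.linalg.solve(Cv + jitter * np.eye(n), ones)
            Cv_inv_x = np.linalg.solve(Cv + jitter * np.eye(n), x)
        denom = float(ones @ Cv_inv_1)
        est[v] = float(ones @ Cv_inv_x) / denom
        var[v] = sigma2 / denom
    for tip in tree.tip_indices:
        lab = tree.labels[tip]
        if lab in trait.values:
            est[tip] = trait.values[lab]
            var[tip] = 0.0
    lo = {v: est[v] - z_alpha * math.sqrt(max(var[v], 0.0)) for v in est}
    hi = {v: est[v] + z_alpha * math.sqrt(max(var[v], 0.0)) for v in est}
    return AncestralEstimates(
        estimates=est,
        variances=var,
        ci_low=lo,
        ci_high=hi,
        sigma2=sigma2,
        node_labels={v: tree.node_label(v) for v in est},
    )
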