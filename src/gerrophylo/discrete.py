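"""Discrete-character ancestral reconstruction.

Mk-model likelihoods via Felsenstein pruning, ML fitting of ER/SYM/ARD
rate matrices with AICc and likelihood-ratio model choice, marginal
ancestral state probabilities ("pies"), stochastic character mapping by
endpoint-conditioned uniformization sampling, Sankoff parsimony with
configurable transition costs, and independent-transition counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .history import CharacterHistory
from .tree import Tree

__all__ = [
    "DiscreteTrait",
    "MkFit",
    "StochasticMapSet",
    "ParsimonyReconstruction",
    "TransitionSummary",
    "build_q",
    "mk_loglik",
    "fit_mk",
    "compare_models_lrt",
    "select_model_lrt",
    "marginal_ancestrals",
    "stochastic_map",
    "sankoff_parsimony",
    "count_transitions",
]

_RATE_LO, _RATE_HI = 1e-8, 1e3
_UNIFORMIZATION_CAP = 10_000


# ----------------------------------------------------------------------
# trait container
# ----------------------------------------------------------------------
@dataclass
class DiscreteTrait:
    state_space: list[str]
    tip_states: dict[str, str | None]  # tip label -> state label (None = missing)

    def __post_init__(self) -> None:
        observed = {s for s in self.tip_states.values() if s is not None}
        unknown = observed - set(self.state_space)
        if unknown:
            raise ValueError(f"states not in state_space: {sorted(unknown)}")

    @property
    def k(self) -> int:
        return len(self.state_space)

    def index_of(self, state: str) -> int:
        return self.state_space.index(state)

    def as_indices(self) -> dict[str, int | None]:
        idx = {s: i for i, s in enumerate(self.state_space)}
        return {
            t: (idx[s] if s is not None else None)
            for t, s in self.tip_states.items()
        }

    @classmethod
    def from_ints(cls, tip_states: dict[str, int], k: int) -> "DiscreteTrait":
        space = [str(i) for i in range(k)]
        return cls(space, {t: str(s) for t, s in tip_states.items()})


# ----------------------------------------------------------------------
# rate matrices
# ----------------------------------------------------------------------
def n_free_rates(model: str, k: int) -> int:
    if model == "ER":
        return 1
    if model == "SYM":
        return k * (k - 1) // 2
    if model == "ARD":
        return k * (k - 1)
    raise ValueError(f"unknown model {model!r}")


def build_q(model: str, k: int, rates: np.ndarray) -> np.ndarray:
    """Assemble a k x k rate matrix from free off-diagonal rates.

    ER: one shared rate; SYM: one rate per unordered pair in row-major
    upper-triangle order; ARD: one per ordered pair, row-major skipping
    the diagonal.
    """
    rates = np.asarray(rates, dtype=float)
    if len(rates) != n_free_rates(model, k):
        raise ValueError(f"{model} with k={k} needs {n_free_rates(model, k)} rates")
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        it = iter(rates)
        for i in range(k):
            for j in range(i + 1, k):
                r = next(it)
                Q[i, j] = Q[j, i] = r
    else:  # ARD
        it = iter(rates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = next(it)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _branch_pmats(Q: np.ndarray, blens: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for every branch length, batched by eigendecomposition
    with an expm fallback for defective matrices."""
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            E = np.exp(np.outer(blens, w))  # (B, k)
            P = np.einsum("ij,bj,jk->bik", V, E, Vinv)
            P = np.real(P)
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=2, keepdims=True)
            if np.all(np.isfinite(P)):
                return P
    except np.linalg.LinAlgError:
        pass
    P = np.empty((len(blens), k, k))
    for b, t in enumerate(blens):
        P[b] = expm(Q * t)
    if not np.all(np.isfinite(P)):
        raise FloatingPointError("non-finite transition matrix exp(Qt)")
    return P


def _tip_partials(tree: Tree, trait: DiscreteTrait, k: int) -> np.ndarray:
    part = np.ones((tree.n_nodes, k))
    states = trait.as_indices()
    for tip in tree.tip_indices:
        lab = tree.labels[tip]
        s = states.get(lab)
        if s is None:
            continue  # missing data: all-ones
        part[tip] = 0.0
        part[tip, s] = 1.0
    return part


def _root_prior(k: int, prior) -> np.ndarray:
    if prior is None or prior == "equal":
        return np.full(k, 1.0 / k)
    p = np.asarray(prior, dtype=float)
    if p.shape != (k,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("root prior must be a length-k probability vector")
    return p


def _prune(
    tree: Tree, trait: DiscreteTrait, Q: np.ndarray, root_prior
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Upward pass. Returns (partials, per-branch P, log scale, prior)."""
    k = Q.shape[0]
    P = _branch_pmats(Q, tree.blen)
    part = _tip_partials(tree, trait, k)
    logscale = 0.0
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        acc = np.ones(k)
        for c in kids:
            acc = acc * (P[c] @ part[c])
        mx = acc.max()
        if mx <= 0:
            return part, P, -math.inf, _root_prior(k, root_prior)
        part[v] = acc / mx
        logscale += math.log(mx)
    return part, P, logscale, _root_prior(k, root_prior)


def mk_loglik(
    tree: Tree, trait: DiscreteTrait, Q: np.ndarray, root_prior="equal"
) -> float:
    """Felsenstein pruning log-likelihood of tip states under rate matrix Q."""
    part, _, logscale, prior = _prune(tree, trait, Q, root_prior)
    if not np.isfinite(logscale):
        return -math.inf
    lik = float(prior @ part[tree.root])
    if lik <= 0:
        return -math.inf
    return math.log(lik) + logscale


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
@dataclass
class MkFit:
    model: str
    Q: np.ndarray
    lnL: float
    k_free: int
    aicc: float
    rates: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True


def _aicc(lnL: float, k_free: int, n: int) -> float:
    aic = -2.0 * lnL + 2.0 * k_free
    denom = n - k_free - 1
    if denom <= 0:
        return math.inf
    return aic + 2.0 * k_free * (k_free + 1) / denom


def fit_mk(
    tree: Tree,
    trait: DiscreteTrait,
    model: str = "ER",
    root_prior="equal",
    n_starts: int = 3,
    seed: int = 0,
    warm_start: np.ndarray | None = None,
) -> MkFit:
    """Maximum-likelihood Mk fit by bounded multi-start optimisation.

    Rates are optimised on a log scale with L-BFGS-B from ``n_starts``
    seeded initial points (plus an optional warm start, e.g. the rates
    of a nested fit). AICc uses the number of tips as sample size.
    """
    k = trait.k
    p = n_free_rates(model, k)
    n_tips = tree.n_tips
    observed = {s for s in trait.tip_states.values() if s is not None}
    if len(observed) < 2:
        warnings.warn("all tips share one state: boundary fit at the rate floor")
        rates = np.full(p, _RATE_LO)
        Q = build_q(model, k, rates)
        lnL = mk_loglik(tree, trait, Q, root_prior)
        return MkFit(model, Q, lnL, p, _aicc(lnL, p, n_tips), rates)

    def nll(log_rates: np.ndarray) -> float:
        Q = build_q(model, k, np.exp(log_rates))
        ll = mk_loglik(tree, trait, Q, root_prior)
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(seed)
    depth = max(tree.depths().max(), 1e-6)
    base = math.log(1.0 / depth)
    best = None
    bounds = [(math.log(_RATE_LO), math.log(_RATE_HI))] * p
    starts = [np.full(p, base) + (rng.standard_normal(p) if s else 0.0) for s in range(n_starts)]
    if warm_start is not None:
        starts.append(np.log(np.clip(np.asarray(warm_start, float), _RATE_LO, _RATE_HI)))
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    Q = build_q(model, k, rates)
    lnL = -float(best.fun)
    return MkFit(model, Q, lnL, p, _aicc(lnL, p, n_tips), rates, bool(best.success))


def compare_models_lrt(
    fit_simple: MkFit, fit_complex: MkFit, alpha: float = 0.05
) -> tuple[float, str]:
    """Likelihood-ratio test of nested Mk fits.

    p = upper chi-square tail of |2 dlnL| at df = dk_free; the complex
    model is chosen iff p < alpha. df = 0 gives p 1 and the simple model.
    """
    df = fit_complex.k_free - fit_simple.k_free
    if df < 0:
        raise ValueError("fit_simple must be nested in fit_complex")
    if df == 0:
        return 1.0, fit_simple.model
    stat = abs(2.0 * (fit_simple.lnL - fit_complex.lnL))
    p = float(chi2.sf(stat, df))
    return p, (fit_complex.model if p < alpha else fit_simple.model)


def _expand_rates(
    model_from: str, model_to: str, k: int, rates: np.ndarray
) -> np.ndarray | None:
    """Embed a nested model's rates as a start point for a richer one."""
    if rates is None or len(rates) == 0:
        return None
    Q = build_q(model_from, k, rates)
    if model_to == "SYM":
        out = []
        for i in range(k):
            for j in range(i + 1, k):
                out.append(max(Q[i, j], _RATE_LO))
        return np.array(out)
    if model_to == "ARD":
        out = []
        for i in range(k):
            for j in range(k):
                if i != j:
                    out.append(max(Q[i, j], _RATE_LO))
        return np.array(out)
    return None


def select_model_lrt(
    tree: Tree,
    trait: DiscreteTrait,
    models: tuple[str, ...] = ("ER", "SYM", "ARD"),
    alpha: float = 0.05,
    root_prior="equal",
    seed: int = 0,
) -> tuple[MkFit, dict[str, MkFit], list[tuple[str, str, float]]]:
    """Walk the nested ladder ER -> SYM -> ARD by LRT at ``alpha``.

    Returns (chosen fit, all fits, [(simple, complex, p)] comparisons).
    """
    order = [m for m in ("ER", "SYM", "ARD") if m in models]
    fits: dict[str, MkFit] = {}
    prev: MkFit | None = None
    for m in order:
        warm = None
        if prev is not None:
            warm = _expand_rates(prev.model, m, trait.k, prev.rates)
        fits[m] = fit_mk(
            tree, trait, m, root_prior=root_prior, seed=seed, warm_start=warm
        )
        prev = fits[m]
    chosen = order[0]
    comparisons = []
    for m in order[1:]:
        p, pick = compare_models_lrt(fits[chosen], fits[m], alpha)
        comparisons.append((chosen, m, p))
        if pick == m:
            chosen = m
    return fits[chosen], fits, comparisons


# ----------------------------------------------------------------------
# marginal ancestral states
# ----------------------------------------------------------------------
def marginal_ancestrals(
    tree: Tree, trait: DiscreteTrait, Q: np.ndarray, root_prior="equal"
) -> dict[int, np.ndarray]:
    """Marginal posterior state probabilities at every node.

    Upward partials are combined with downward flows (the standard
    two-pass algorithm); each vector is normalised to sum to 1. Tips
    with observed states get degenerate vectors.
    """
    k = Q.shape[0]
    part, P, logscale, prior = _prune(tree, trait, Q, root_prior)
    if not np.isfinite(logscale):
        raise FloatingPointError("zero likelihood: marginals undefined")
    down = np.zeros((tree.n_nodes, k))
    down[tree.root] = prior
    for v in tree.preorder():
        kids = tree.children[v]
        if not kids:
            continue
        lifted = {c: P[c] @ part[c] for c in kids}
        for c in kids:
            sib = down[v].copy()
            for b in kids:
                if b != c:
                    sib = sib * lifted[b]
            vec = sib @ P[c]  # sum_s sib[s] P[c][s, s']
            tot = vec.sum()
            down[c] = vec / tot if tot > 0 else vec
    out: dict[int, np.ndarray] = {}
    for v in range(tree.n_nodes):
        vec = down[v] * part[v]
        tot = vec.sum()
        if tot <= 0:
            raise FloatingPointError(f"node {v}: zero marginal mass")
        out[v] = vec / tot
    return out


# ----------------------------------------------------------------------
# stochastic character mapping
# ----------------------------------------------------------------------
@dataclass
class StochasticMapSet:
    tree: Tree
    state_space: list[str]
    maps: list[CharacterHistory]

    @property
    def nsim(self) -> int:
        return len(self.maps)

    def node_state_frequencies(self) -> dict[int, np.ndarray]:
        k = len(self.state_space)
        freq = {v: np.zeros(k) for v in range(self.tree.n_nodes)}
        for m in self.maps:
            for v, s in m.node_states().items():
                freq[v][s] += 1.0
        for v in freq:
            freq[v] /= self.nsim
        return freq

    def mean_dwell_times(self) -> np.ndarray:
        k = len(self.state_space)
        return sum(m.dwell_times(k) for m in self.maps) / self.nsim

    def transition_count_matrix(self) -> np.ndarray:
        """Posterior mean count of i->j changes."""
        k = len(self.state_space)
        counts = np.zeros((k, k))
        for m in self.maps:
            for _, s0, s1 in m.change_points():
                counts[s0, s1] += 1.0
        return counts / self.nsim


def stochastic_map(
    tree: Tree,
    trait: DiscreteTrait,
    Q: np.ndarray,
    nsim: int = 100,
    seed: int = 0,
    root_prior="equal",
) -> StochasticMapSet:
    """Sample explicit character histories conditional on tip states.

    Node states are drawn from their joint conditional distribution
    (root from the posterior, children given parents); branch paths are
    endpoint-conditioned uniformization samples. Sampling is vectorised
    across simulations branch by branch.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    part, P, logscale, prior = _prune(tree, trait, Q, root_prior)
    if not np.isfinite(logscale):
        raise FloatingPointError("zero likelihood: cannot map")
    mu = float(max(-np.diag(Q).min(), 0.0))
    R = np.eye(k) + (Q / mu if mu > 0 else 0.0 * Q)

    # --- joint node states, all simulations at once -------------------
    states = np.empty((tree.n_nodes, nsim), dtype=np.int64)
    root_w = prior * part[tree.root]
    root_w = root_w / root_w.sum()
    states[tree.root] = rng.choice(k, size=nsim, p=root_w)
    preorder = [v for v in tree.preorder() if v != tree.root]
    for v in preorder:
        w = P[v] * part[v][None, :]  # w[a, s]
        row_sums = w.sum(axis=1)
        if np.any(row_sums <= 0):
            bad = np.flatnonzero(row_sums <= 0)
            pa = states[tree.parent[v]]
            if np.any(np.isin(pa, bad)):
                raise FloatingPointError(f"node {v}: zero conditional mass")
        pa = states[tree.parent[v]]
        out = np.empty(nsim, dtype=np.int64)
        for a in range(k):
            m = pa == a
            cnt = int(m.sum())
            if cnt:
                out[m] = rng.choice(k, size=cnt, p=w[a] / row_sums[a])
        states[v] = out

    # --- branch paths, vectorised over simulations --------------------
    all_segments: list[dict[int, list[tuple[int, float]]]] = [
        {} for _ in range(nsim)
    ]
    for v in preorder:
        t = float(tree.blen[v])
        a = states[tree.parent[v]]
        b = states[v]
        if t <= 0 or mu <= 0:
            if np.any(a != b):
                raise RuntimeError(
                    f"branch {v}: endpoint change with zero length or rate"
                )
            for i in range(nsim):
                all_segments[i][v] = [(int(a[i]), t)]
            continue
        N = _sample_jump_counts(a, b, t, mu, R, P[v], rng, v)
        idx0 = np.flatnonzero(N == 0)
        for i in idx0:
            all_segments[i][v] = [(int(a[i]), t)]
        idx1 = np.flatnonzero(N == 1)
        if len(idx1):
            times = rng.random(len(idx1)) * t
            for j, i in enumerate(idx1):
                ai, bi = int(a[i]), int(b[i])
                if ai == bi:  # virtual self-jump
                    all_segments[i][v] = [(ai, t)]
                else:
                    t1 = float(times[j])
                    all_segments[i][v] = [(ai, t1), (bi, t - t1)]
        for i in np.flatnonzero(N >= 2):
            all_segments[i][v] = _sample_bridge(
                int(a[i]), int(b[i]), int(N[i]), t, R, rng
            )

    maps = [
        CharacterHistory(
            tree=tree, root_state=int(states[tree.root, i]), segments=all_segments[i]
        )
        for i in range(nsim)
    ]
    return StochasticMapSet(tree=tree, state_space=list(trait.state_space), maps=maps)


def _sample_jump_counts(
    a: np.ndarray,
    b: np.ndarray,
    t: float,
    mu: float,
    R: np.ndarray,
    P_t: np.ndarray,
    rng: np.random.Generator,
    node: int,
) -> np.ndarray:
    """Vectorised draw of the uniformization jump count per simulation:
    P(N = n | a, b, t) = Pois(n; mu t) R^n[a, b] / P_t[a, b]."""
    nsim = len(a)
    P_ab = P_t[a, b]
    if np.any(P_ab <= 0):
        raise FloatingPointError(f"branch {node}: zero endpoint probability")
    u = rng.random(nsim)
    cum = np.zeros(nsim)
    N = np.full(nsim, -1, dtype=np.int64)
    pois = math.exp(-mu * t)
    Rp = np.eye(R.shape[0])
    for n in range(_UNIFORMIZATION_CAP + 1):
        if n > 0:
            pois *= mu * t / n
            Rp = Rp @ R
        cum += pois * Rp[a, b] / P_ab
        newly = (N < 0) & (u <= cum)
        N[newly] = n
        if not np.any(N < 0):
            break
    if np.any(N < 0):
        raise RuntimeError(
            f"branch {node}: uniformization cap {_UNIFORMIZATION_CAP} reached"
        )
    return N


def _sample_bridge(
    a: int, b: int, N: int, t: float, R: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Forward-filtering backward-sampling bridge through R given N jumps."""
    k = R.shape[0]
    R_pows = [np.eye(k), R]
    while len(R_pows) <= N:
        R_pows.append(R_pows[-1] @ R)
    states = [a]
    for j in range(1, N + 1):
        prev = states[-1]
        w = R[prev] * R_pows[N - j][:, b]
        states.append(int(rng.choice(k, p=w / w.sum())))
    times = np.sort(rng.random(N)) * t
    bounds = np.concatenate(([0.0], times, [t]))
    segs: list[tuple[int, float]] = []
    for i, s in enumerate(states):
        dur = float(bounds[i + 1] - bounds[i])
        if segs and segs[-1][0] == s:
            segs[-1] = (s, segs[-1][1] + dur)
        else:
            segs.append((s, dur))
    total_head = sum(d for _, d in segs[:-1])
    segs[-1] = (segs[-1][0], t - total_head)
    return segs


# ----------------------------------------------------------------------
# Sankoff parsimony
# ----------------------------------------------------------------------
@dataclass
class ParsimonyReconstruction:
    cost_scheme: str
    total_cost: float
    node_states: dict[int, set[int]]  # states in >=1 globally optimal labeling


def parsimony_cost_matrix(scheme: str, k: int) -> np.ndarray:
    """all_equal: unit cost off-diagonal. exponential (ordered states):
    cost(i, j) = 2^|i-j| - 1."""
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            C[i, j] = 1.0 if scheme == "all_equal" else 2.0 ** abs(i - j) - 1.0
    if scheme not in ("all_equal", "exponential"):
        raise ValueError(f"unknown cost scheme {scheme!r}")
    return C


def sankoff_parsimony(
    tree: Tree, trait: DiscreteTrait, cost_scheme: str = "all_equal"
) -> ParsimonyReconstruction:
    """Minimum-cost ancestral labeling under a transition-cost matrix.

    Bottom-up DP yields subtree cost vectors; a top-down pass computes,
    per node and state, the best total cost achievable with that
    assignment, from which the sets of states occurring in at least one
    globally optimal labeling follow.
    """
    k = trait.k
    C = parsimony_cost_matrix(cost_scheme, k)
    states = trait.as_indices()
    INF = math.inf
    S = np.zeros((tree.n_nodes, k))
    for tip in tree.tip_indices:
        s = states.get(tree.labels[tip])
        if s is not None:
            S[tip] = INF
            S[tip, s] = 0.0
    # child contribution m[c][s_parent] = min_x (C[s_parent, x] + S[c, x])
    m = np.zeros((tree.n_nodes, k))
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        for c in kids:
            m[c] = (C + S[c][None, :]).min(axis=1)
            S[v] += m[c]
    total = float(S[tree.root].min())
    # top-down: T[v, s] = best total cost with node v in state s
    T = np.full((tree.n_nodes, k), INF)
    T[tree.root] = S[tree.root]
    for v in tree.preorder():
        for c in tree.children[v]:
            base = T[v] - m[c]  # total minus c's optimised contribution
            cand = base[:, None] + C + S[c][None, :]
            T[c] = cand.min(axis=0)
    tol = 1e-9
    node_states = {
        v: {int(s) for s in range(k) if T[v, s] <= total + tol}
        for v in range(tree.n_nodes)
    }
    return ParsimonyReconstruction(cost_scheme, total, node_states)


# ----------------------------------------------------------------------
# transition counting
# ----------------------------------------------------------------------
@dataclass
class TransitionSummary:
    derived_state: str
    n_origins: float
    n_reversals: float
    origin_branches: list[int] = field(default_factory=list)
    reversal_branches: list[int] = field(default_factory=list)
    origins_sd: float | None = None
    reversals_sd: float | None = None
    origin_distribution: list[int] = field(default_factory=list)


def count_transitions(
    source: CharacterHistory | StochasticMapSet,
    derived_state: str | int,
    state_space: list[str] | None = None,
) -> TransitionSummary:
    """Independent gains of / losses from the derived state.

    For a single explicit history the counts are exact (each entry into
    the derived state counted once). For a stochastic map set the
    summary is the posterior mean with sd and the full per-map count
    distribution.
    """
    if isinstance(source, StochasticMapSet):
        space = source.state_space
        if isinstance(derived_state, str):
            if derived_state not in space:
                raise ValueError(f"state {derived_state!r} not in state space")
            d = space.index(derived_state)
        else:
            d = int(derived_state)
        origins = [len(m.entries_into(d)) for m in source.maps]
        revs = [len(m.exits_from(d)) for m in source.maps]
        return TransitionSummary(
            derived_state=space[d],
            n_origins=float(np.mean(origins)),
            n_reversals=float(np.mean(revs)),
            origins_sd=float(np.std(origins)),
            reversals_sd=float(np.std(revs)),
            origin_distribution=origins,
        )
    hist = source
    if isinstance(derived_state, str):
        if state_space is None:
            raise ValueError("state_space required for a labelled state")
        if derived_state not in state_space:
            raise ValueError(f"state {derived_state!r} not in state space")
        d = state_space.index(derived_state)
        label = derived_state
    else:
        d = int(derived_state)
        label = state_space[d] if state_space else str(d)
    ob = hist.entries_into(d)
    rb = hist.exits_from(d)
    return TransitionSummary(
        derived_state=label,
        n_origins=float(len(ob)),
        n_reversals=float(len(rb)),
        origin_branches=ob,
        reversal_branches=rb,
    )
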