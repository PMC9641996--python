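"""Synthetic data generation with recorded ground truth.

Everything the pipeline consumes can be generated here: birth-death
trees, discrete traits with explicit histories, Brownian traits with a
lambda transform, ortholog clusters (isoforms, paralogs, planted
chimeras, contaminants) with a similarity hit table, and codon
alignments that satisfy or violate SRH conditions.

All generators are pure functions of their arguments plus a seed (or an
explicit :class:`numpy.random.Generator`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .history import CharacterHistory
from .tree import Tree

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_tree",
    "simulate_discrete_trait",
    "simulate_continuous_trait",
    "simulate_ortholog_clusters",
    "simulate_chimeric_cluster",
    "simulate_codon_alignment",
    "perturb_branch_lengths",
    "ClusterSim",
    "write_cluster_sim",
]

BASES = np.array(list("ACGT"))
_MAX_BD_RETRIES = 100


# ----------------------------------------------------------------------
# configuration / truth containers
# ----------------------------------------------------------------------
@dataclass
class SimConfig:
    """Parameters of a full synthetic run."""

    seed: int = 0
    n_species: int = 20
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_clusters: int = 20
    isoforms_per_species: int = 1
    p_paralog: float = 0.0
    p_chimera: float = 0.0
    p_contaminant: float = 0.0
    gene_length_codons: int = 200
    q_matrix: np.ndarray | None = None
    sigma2: float = 1.0
    lambda_true: float = 1.0
    srh_violation: str = "none"

    def __post_init__(self) -> None:
        for name in ("p_paralog", "p_chimera", "p_contaminant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.isoforms_per_species < 1:
            raise ValueError("isoforms_per_species must be >= 1")
        if self.srh_violation not in ("none", "clade_shift"):
            raise ValueError(f"unknown srh_violation {self.srh_violation!r}")
        if self.q_matrix is not None:
            q = np.asarray(self.q_matrix, dtype=float)
            off = q - np.diag(np.diag(q))
            if np.any(off < -1e-12):
                raise ValueError("q_matrix off-diagonals must be non-negative")
            if np.any(np.abs(q.sum(axis=1)) > 1e-9):
                raise ValueError("q_matrix rows must sum to 0")
            self.q_matrix = q


@dataclass
class SimTruth:
    """Ground truth emitted alongside synthetic data (fragments optional)."""

    tree: Tree | None = None
    node_states: dict[str, dict[int, int]] = field(default_factory=dict)
    histories: dict[str, CharacterHistory] = field(default_factory=dict)
    true_transition_count: dict[tuple[str, int], int] = field(default_factory=dict)
    chimera_map: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    contaminant_ids: set[str] = field(default_factory=set)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------
def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed=0,
) -> Tree:
    """Forward birth-death simulation stopped at ``n_species`` extant tips.

    Extinct lineages are pruned and unary nodes suppressed, so the
    returned tree is binary with all tips at the stopping time
    (ultrametric). Simulations that go extinct are retried up to 100
    times on the same seeded stream; persistent extinction is an error.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _rng(seed)
    for _ in range(_MAX_BD_RETRIES):
        tree = _bd_once(n_species, birth_rate, death_rate, rng)
        if tree is not None:
            return tree
    raise RuntimeError(
        f"birth-death simulation went extinct {_MAX_BD_RETRIES} times "
        f"(birth={birth_rate}, death={death_rate})"
    )


def _bd_once(n: int, b: float, d: float, rng: np.random.Generator) -> Tree | None:
    # node records: parent, birth time, death/None
    parent = [-1, 0, 0]
    t_start = [0.0, 0.0, 0.0]
    t_end: list[float | None] = [0.0, None, None]
    alive = [1, 2]
    t = 0.0
    while len(alive) < n:
        if not alive:
            return None
        total = len(alive) * (b + d)
        t += rng.exponential(1.0 / total)
        u = alive[rng.integers(len(alive))]
        if rng.random() < b / (b + d):
            t_end[u] = t
            for _ in range(2):
                parent.append(u)
                t_start.append(t)
                t_end.append(None)
                alive.append(len(parent) - 1)
            alive.remove(u)
        else:
            t_end[u] = t
            alive.remove(u)
    # a final waiting time so tip branches are not zero at the last split
    t += rng.exponential(1.0 / (len(alive) * (b + d)))
    for u in alive:
        t_end[u] = t
    extant = set(alive)
    return _prune_to_extant(parent, t_start, t_end, extant)


def _prune_to_extant(parent, t_start, t_end, extant: set[int]) -> Tree | None:
    n = len(parent)
    keep = [False] * n
    for u in extant:
        v = u
        while v != -1 and not keep[v]:
            keep[v] = True
            v = parent[v]
    children: list[list[int]] = [[] for _ in range(n)]
    for v in range(1, n):
        if keep[v]:
            children[parent[v]].append(v)

    # rebuild, suppressing unary nodes
    new_parent: list[int] = []
    new_blen: list[float] = []
    new_labels: list[str | None] = []

    def add(v: int, par_new: int, extra: float) -> None:
        kids = [c for c in children[v] if keep[c]]
        blen = t_end[v] - t_start[v] + extra
        if len(kids) == 1 and v not in extant:
            add(kids[0], par_new, blen)
            return
        idx = len(new_parent)
        new_parent.append(par_new)
        new_blen.append(blen)
        new_labels.append(None)
        for c in kids:
            add(c, idx, 0.0)

    root_kids = [c for c in children[0] if keep[c]]
    if len(root_kids) < 2:
        # root survived on one side only: descend until first real split
        v = 0
        while True:
            kids = [c for c in children[v] if keep[c]]
            if len(kids) >= 2 or v in extant:
                break
            v = kids[0]
        if v in extant and not children[v]:
            return None
        new_parent.append(-1)
        new_blen.append(0.0)
        new_labels.append(None)
        for c in [c for c in children[v] if keep[c]]:
            add(c, 0, 0.0)
    else:
        new_parent.append(-1)
        new_blen.append(0.0)
        new_labels.append(None)
        for c in root_kids:
            add(c, 0, 0.0)

    has_child = [False] * len(new_parent)
    for p in new_parent:
        if p >= 0:
            has_child[p] = True
    tips = [i for i, hc in enumerate(has_child) if not hc]
    if len(tips) != len(extant):
        return None
    width = max(3, len(str(len(tips))))
    for i, tp in enumerate(tips, start=1):
        new_labels[tp] = f"sp{i:0{width}d}"
    return Tree(new_parent, new_blen, new_labels)


def perturb_branch_lengths(tree: Tree, seed=0, sd: float = 0.3) -> Tree:
    """Multiply branch lengths by i.i.d. lognormal noise (phylogram-iser)."""
    rng = _rng(seed)
    out = tree.copy()
    for v in range(out.n_nodes):
        if v != out.root:
            out.blen[v] *= float(rng.lognormal(0.0, sd))
    return Tree(out.parent, out.blen, out.labels)


# ----------------------------------------------------------------------
# discrete traits
# ----------------------------------------------------------------------
def _check_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("q must be square")
    off = q - np.diag(np.diag(q))
    if np.any(off < -1e-12):
        raise ValueError("q off-diagonals must be non-negative")
    if np.any(np.abs(q.sum(axis=1)) > 1e-9):
        raise ValueError("q rows must sum to 0")
    return q


def simulate_discrete_trait(
    tree: Tree,
    q: np.ndarray,
    root_state: int = 0,
    seed=0,
    trait_name: str = "trait",
) -> tuple[dict[str, int], SimTruth]:
    """Gillespie simulation of a Markov character along every branch.

    Returns the tip states and a :class:`SimTruth` fragment holding the
    explicit history plus per-state independent-entry counts.
    """
    q = _check_q(q)
    k = q.shape[0]
    if not 0 <= root_state < k:
        raise ValueError("root_state out of range")
    rng = _rng(seed)
    hist = CharacterHistory(tree=tree, root_state=int(root_state))
    state_at = {tree.root: int(root_state)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = state_at[tree.parent[v]]
        t_len = float(tree.blen[v])
        segs: list[tuple[int, float]] = []
        t = 0.0
        while True:
            rate = -q[s, s]
            if rate <= 0:
                segs.append((s, t_len - t))
                break
            wait = rng.exponential(1.0 / rate)
            if t + wait >= t_len:
                segs.append((s, t_len - t))
                break
            segs.append((s, wait))
            t += wait
            probs = q[s].copy()
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
        # merge zero-duration artefacts (cannot occur with exp draws, but safe)
        hist.segments[v] = segs
        state_at[v] = s
    truth = SimTruth(tree=tree)
    truth.histories[trait_name] = hist
    truth.node_states[trait_name] = hist.node_states()
    for st in range(k):
        truth.true_transition_count[(trait_name, st)] = len(hist.entries_into(st))
    return hist.tip_states(), truth


# ----------------------------------------------------------------------
# continuous traits
# ----------------------------------------------------------------------
def lambda_vcv(tree: Tree, lam: float) -> np.ndarray:
    """Tip covariance structure of a lambda-transformed tree (unit rate)."""
    C = tree.vcv()
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def simulate_continuous_trait(
    tree: Tree,
    sigma2: float,
    lambda_true: float = 1.0,
    root_value: float = 0.0,
    seed=0,
) -> dict[str, float]:
    """Draw tip values from the MVN implied by the lambda-transformed tree."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    rng = _rng(seed)
    labels = tree.tip_labels
    if sigma2 == 0:
        return {lab: float(root_value) for lab in labels}
    cov = sigma2 * lambda_vcv(tree, lambda_true)
    # Cholesky with a tiny jitter guard for zero-length cherries
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(labels)))
    x = root_value + L @ rng.standard_normal(len(labels))
    return {lab: float(v) for lab, v in zip(labels, x)}


# ----------------------------------------------------------------------
# sequences
# ----------------------------------------------------------------------
def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _jc_evolve(seq: np.ndarray, dist: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor evolution by expected distance ``dist`` subs/site."""
    p_change = 0.75 * (1.0 - math.exp(-4.0 * dist / 3.0))
    out = seq.copy()
    hit = rng.random(len(seq)) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        shifts = rng.integers(1, 4, size=n_hit)
        out[hit] = (out[hit] + shifts) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(BASES[seq])


def _kmers(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# ----------------------------------------------------------------------
# ortholog clusters
# ----------------------------------------------------------------------
@dataclass
class ClusterSim:
    """In-memory result of :func:`simulate_ortholog_clusters`."""

    fasta: dict[str, list[tuple[str, str]]]  # species -> [(transcript_id, seq)]
    hits: list[dict]  # outfmt-6 style rows, intra-cluster pairs
    clusters: dict[str, set[tuple[str, str]]]  # cluster_id -> {(species, tid)}
    contaminant_hits: list[dict]  # planted rows against the contaminant DB
    truth: SimTruth


def _hit_row(qid: str, sid: str, qseq: str, sseq: str, k: int = 8) -> dict:
    kq, ks = _kmers(qseq, k), _kmers(sseq, k)
    denom = max(min(len(kq), len(ks)), 1)
    frac = len(kq & ks) / denom
    min_len = min(len(qseq), len(sseq))
    bitscore = frac * 2.0 * min_len / k
    m = min(len(qseq), len(sseq))
    ident = sum(a == b for a, b in zip(qseq[:m], sseq[:m])) / m * 100.0
    return {
        "qseqid": qid,
        "sseqid": sid,
        "pident": round(ident, 2),
        "length": m,
        "qlen": len(qseq),
        "slen": len(sseq),
        "evalue": 2.0 ** (-bitscore),
        "bitscore": round(bitscore, 2),
    }


def simulate_ortholog_clusters(config: SimConfig, seed=None) -> ClusterSim:
    """Generate per-species transcript sets, cluster membership and hits.

    Each cluster is a gene family evolved under Jukes-Cantor from a
    random root sequence. Isoforms are near-duplicates (>=99.5%
    identity); paralogs are extra, more divergent copies; a planted
    chimera fuses the 5' half of one family's sequence to the 3' half of
    another's and joins both clusters; contaminants are unrelated
    sequences listed in ``truth.contaminant_ids`` with planted rows in
    ``contaminant_hits``.
    """
    rng = _rng(config.seed if seed is None else seed)
    L = 3 * config.gene_length_codons
    if config.p_chimera > 0 and config.n_clusters < 2:
        raise ValueError("chimeras need at least 2 gene families")
    species = [f"sp{i:03d}" for i in range(1, config.n_species + 1)]
    fasta: dict[str, list[tuple[str, str]]] = {sp: [] for sp in species}
    clusters: dict[str, set[tuple[str, str]]] = {}
    hits: list[dict] = []
    cont_hits: list[dict] = []
    truth = SimTruth()
    seqs_by_cluster: dict[str, dict[str, str]] = {}  # cluster -> tid -> seq
    species_of: dict[str, str] = {}

    for g in range(config.n_clusters):
        cid = f"g{g:04d}"
        root = _random_seq(L, rng)
        p_incl = rng.uniform(0.6, 1.0)
        members: set[tuple[str, str]] = set()
        cseqs: dict[str, str] = {}
        for sp in species:
            if rng.random() > p_incl:
                continue
            d_sp = rng.uniform(0.02, 0.15)
            base = _jc_evolve(root, d_sp, rng)
            for iso in range(config.isoforms_per_species):
                tid = f"{sp}|{cid}t{iso}"
                seq = base if iso == 0 else _jc_evolve(base, 0.002, rng)
                cseqs[tid] = _to_str(seq)
                members.add((sp, tid))
                species_of[tid] = sp
                fasta[sp].append((tid, cseqs[tid]))
            if rng.random() < config.p_paralog:
                tid = f"{sp}|{cid}p"
                cseqs[tid] = _to_str(_jc_evolve(base, 0.30, rng))
                members.add((sp, tid))
                species_of[tid] = sp
                fasta[sp].append((tid, cseqs[tid]))
        clusters[cid] = members
        seqs_by_cluster[cid] = cseqs

    # planted chimeras: fuse cluster g with a random partner h
    cluster_ids = sorted(clusters)
    for cid in cluster_ids:
        if rng.random() >= config.p_chimera or not seqs_by_cluster[cid]:
            continue
        others = [c for c in cluster_ids if c != cid and seqs_by_cluster[c]]
        if not others:
            continue
        hid = others[rng.integers(len(others))]
        tid_a = sorted(seqs_by_cluster[cid])[rng.integers(len(seqs_by_cluster[cid]))]
        tid_b = sorted(seqs_by_cluster[hid])[rng.integers(len(seqs_by_cluster[hid]))]
        seq_a, seq_b = seqs_by_cluster[cid][tid_a], seqs_by_cluster[hid][tid_b]
        mid = len(seq_a) // 2
        bp = int(mid + rng.integers(-mid // 10, mid // 10 + 1))
        bp = min(max(bp, 1), len(seq_a) - 1)
        sp = species_of[tid_a]
        fid = f"{sp}|{cid}x{hid}"
        fused = seq_a[:bp] + seq_b[bp:]
        truth.chimera_map[fid] = (cid, hid, bp)
        species_of[fid] = sp
        fasta[sp].append((fid, fused))
        for c in (cid, hid):
            clusters[c].add((sp, fid))
            seqs_by_cluster[c][fid] = fused

    # contaminants: unrelated random sequences, one planted DB hit each
    for sp in species:
        n_cont = int(rng.binomial(config.n_clusters, config.p_contaminant))
        for j in range(n_cont):
            tid = f"{sp}|cont{j}"
            seq = _to_str(_random_seq(L, rng))
            fasta[sp].append((tid, seq))
            truth.contaminant_ids.add(tid)
            cont_hits.append(
                {
                    "qseqid": tid,
                    "sseqid": f"db|{tid}",
                    "pident": round(rng.uniform(92.0, 99.9), 2),
                    "length": int(0.5 * L),
                    "qlen": L,
                    "slen": L,
                    "evalue": 1e-30,
                    "bitscore": 500.0,
                }
            )

    # intra-cluster all-against-all hits
    for cid in cluster_ids:
        cseqs = seqs_by_cluster[cid]
        tids = sorted(cseqs)
        for qi in tids:
            for si in tids:
                if qi != si:
                    hits.append(_hit_row(qi, si, cseqs[qi], cseqs[si]))

    return ClusterSim(
        fasta=fasta,
        hits=hits,
        clusters=clusters,
        contaminant_hits=cont_hits,
        truth=truth,
    )


def simulate_chimeric_cluster(
    n_species_a: int,
    n_species_b: int,
    gene_length_codons: int = 150,
    seed=0,
    include_fusion: bool = False,
):
    """One merged cluster made of two well-separated gene families.

    Returns ``(members, hits, family_a_ids, family_b_ids, fusion_id)``
    where hits only connect transcripts within a family (plus, when
    ``include_fusion``, the fused transcript to both). The planted
    bipartition is the oracle for the two-list division.
    """
    rng = _rng(seed)
    L = 3 * gene_length_codons
    root_a, root_b = _random_seq(L, rng), _random_seq(L, rng)
    seqs: dict[str, str] = {}
    fam_a, fam_b = [], []
    members: set[tuple[str, str]] = set()
    # tight within-family divergence keeps cumulative scores dominated by
    # family size, so the two-list seeds land in different families
    for i in range(n_species_a):
        tid = f"spA{i:02d}|ga"
        seqs[tid] = _to_str(_jc_evolve(root_a, rng.uniform(0.02, 0.06), rng))
        fam_a.append(tid)
        members.add((f"spA{i:02d}", tid))
    for i in range(n_species_b):
        tid = f"spB{i:02d}|gb"
        seqs[tid] = _to_str(_jc_evolve(root_b, rng.uniform(0.02, 0.06), rng))
        fam_b.append(tid)
        members.add((f"spB{i:02d}", tid))
    fusion_id = None
    if include_fusion:
        bp = L // 2
        fusion_id = "spA00|fuse"
        seqs[fusion_id] = seqs[fam_a[0]][:bp] + seqs[fam_b[0]][bp:]
        members.add(("spA00", fusion_id))
    hits = []
    tids = sorted(seqs)
    for qi in tids:
        for si in tids:
            if qi == si:
                continue
            row = _hit_row(qi, si, seqs[qi], seqs[si])
            if row["bitscore"] > 1.0:  # families unrelated: drop noise hits
                hits.append(row)
    return members, hits, fam_a, fam_b, fusion_id


# ----------------------------------------------------------------------
# codon alignments (F81 with optional clade-specific composition shift)
# ----------------------------------------------------------------------
_SHIFT_PI = np.array([0.05, 0.45, 0.45, 0.05])  # strongly GC-rich


def _f81_evolve(
    seq: np.ndarray, t: float, pi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """F81 process: with prob 1-exp(-beta t) a site is redrawn from pi."""
    beta = 1.0 / (1.0 - float(pi @ pi))
    p_event = 1.0 - math.exp(-beta * t)
    out = seq.copy()
    hit = rng.random(len(seq)) < p_event
    n = int(hit.sum())
    if n:
        out[hit] = rng.choice(4, size=n, p=pi)
    return out


def simulate_codon_alignment(
    tree: Tree,
    gene_length_codons: int,
    srh_violation: str = "none",
    seed=0,
    shift_positions: tuple[int, ...] = (1, 2, 3),
    shift_strength: float = 3.0,
    n_blocks: int = 3,
) -> tuple[dict[str, str], list[tuple[int, int]]]:
    """Simulate a codon-framed alignment plus true conserved-block coords.

    Under ``srh_violation='none'`` all sites evolve under a stationary,
    reversible, homogeneous model (uniform-pi F81 = Jukes-Cantor).
    Under ``'clade_shift'`` branches inside one clade (the larger child
    of the root) redraw sites at ``shift_positions`` from a GC-rich
    composition, with rate boosted by ``shift_strength``. Conserved
    blocks (returned 1-based inclusive, codon-aligned) evolve at 0.15x
    rate.
    """
    if gene_length_codons < 50:
        raise ValueError("gene_length_codons must be >= 50")
    if srh_violation not in ("none", "clade_shift"):
        raise ValueError(f"unknown srh_violation {srh_violation!r}")
    rng = _rng(seed)
    L = 3 * gene_length_codons
    pi0 = np.full(4, 0.25)

    # conserved blocks: codon-aligned, non-overlapping
    blocks: list[tuple[int, int]] = []
    if n_blocks > 0:
        slot = gene_length_codons // n_blocks
        for b in range(n_blocks):
            lo_codon = b * slot
            width = max(slot // 2, 12)
            start_codon = lo_codon + int(rng.integers(0, max(slot - width, 1)))
            blocks.append((3 * start_codon + 1, 3 * (start_codon + width)))
    rate = np.ones(L)
    for s, e in blocks:
        rate[s - 1 : e] = 0.15

    shifted_nodes: set[int] = set()
    if srh_violation == "clade_shift":
        kids = tree.children[tree.root]
        sizes = []
        for c in kids:
            stack, cnt = [c], 0
            while stack:
                v = stack.pop()
                cnt += tree.is_tip(v)
                stack.extend(tree.children[v])
            sizes.append(cnt)
        focal = kids[int(np.argmax(sizes))]
        stack = [focal]
        while stack:
            v = stack.pop()
            shifted_nodes.add(v)
            stack.extend(tree.children[v])

    pos_mask = np.zeros(L, dtype=bool)  # sites subject to the shift
    for p in shift_positions:
        pos_mask[p - 1 :: 3] = True

    seqs: dict[int, np.ndarray] = {tree.root: _random_seq(L, rng)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent_seq = seqs[tree.parent[v]]
        t_len = float(tree.blen[v])
        child = parent_seq.copy()
        # evolve per rate class; vectorised by unique rate values
        for r in np.unique(rate):
            m = rate == r
            child[m] = _f81_evolve(parent_seq[m], r * t_len, pi0, rng)
        if v in shifted_nodes:
            m = pos_mask
            child[m] = _f81_evolve(
                child[m], shift_strength * t_len, _SHIFT_PI, rng
            )
        seqs[v] = child
    aln = {tree.labels[i]: _to_str(seqs[i]) for i in tree.tip_indices}
    return aln, blocks


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------
HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "qlen", "slen", "evalue", "bitscore"]


def write_cluster_sim(sim: ClusterSim, outdir: str | Path) -> None:
    """Write FASTA per species, hit/cluster TSVs and a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fastadir = out / "fasta"
    fastadir.mkdir(exist_ok=True)
    for sp, records in sim.fasta.items():
        with open(fastadir / f"{sp}.fasta", "w") as fh:
            for tid, seq in records:
                fh.write(f">{tid}\n{seq}\n")
    for name, rows in (("hits.tsv", sim.hits), ("contaminant_hits.tsv", sim.contaminant_hits)):
        with open(out / name, "w") as fh:
            fh.write("\t".join(HIT_COLUMNS) + "\n")
            for r in rows:
                fh.write("\t".join(str(r[c]) for c in HIT_COLUMNS) + "\n")
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tspecies_id\ttranscript_id\n")
        for cid in sorted(sim.clusters):
            for sp, tid in sorted(sim.clusters[cid]):
                fh.write(f"{cid}\t{sp}\t{tid}\n")
    truth = {
        "chimera_map": {k: list(v) for k, v in sim.truth.chimera_map.items()},
        "contaminant_ids": sorted(sim.truth.contaminant_ids),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
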