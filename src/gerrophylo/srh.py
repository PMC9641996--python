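"""Matched-pairs symmetry tests (Bowker, Stuart, internal) for screening
alignments against violations of stationarity, reversibility and
homogeneity at selected codon positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.stats import chi2

__all__ = [
    "PairedSiteCounts",
    "PairResult",
    "SRHResult",
    "paired_site_counts",
    "bowker_test",
    "stuart_test",
    "internal_symmetry_test",
    "srh_filter_cluster",
    "write_srh_report",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PairedSiteCounts:
    taxon_a: str
    taxon_b: str
    n: np.ndarray  # 4x4; n[i,j] = sites with base i in a, base j in b

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.n.shape != (4, 4) or np.any(self.n < 0):
            raise ValueError("counts must be a non-negative 4x4 matrix")

    @property
    def total(self) -> int:
        return int(self.n.sum())


@dataclass
class PairResult:
    taxon_a: str
    taxon_b: str
    bowker_stat: float
    bowker_df: int
    bowker_p: float
    stuart_stat: float | None
    stuart_p: float
    internal_stat: float | None
    internal_df: int
    internal_p: float
    flags: list[str] = field(default_factory=list)


@dataclass
class SRHResult:
    pairs: list[PairResult]
    verdict: str  # "pass" | "fail"
    alpha: float
    correction: str


def paired_site_counts(
    aln: dict[str, str],
    taxon_a: str,
    taxon_b: str,
    positions: tuple[int, ...] = (1, 2, 3),
) -> PairedSiteCounts:
    """4x4 site-pattern counts restricted to the given codon positions.

    Columns with a gap or ambiguity code in either taxon are excluded
    pairwise. The alignment is assumed codon framed (column 1 = codon
    position 1).
    """
    for t in (taxon_a, taxon_b):
        if t not in aln:
            raise KeyError(f"taxon {t!r} not in alignment")
    sa, sb = aln[taxon_a].upper(), aln[taxon_b].upper()
    if len(sa) != len(sb):
        raise ValueError("sequences differ in length")
    wanted = {(p - 1) % 3 for p in positions}
    n = np.zeros((4, 4), dtype=np.int64)
    for col in range(len(sa)):
        if col % 3 not in wanted:
            continue
        i = _BASE_INDEX.get(sa[col])
        j = _BASE_INDEX.get(sb[col])
        if i is None or j is None:
            continue
        n[i, j] += 1
    return PairedSiteCounts(taxon_a, taxon_b, n)


def bowker_test(counts: PairedSiteCounts) -> tuple[float, int, float]:
    """Bowker's test of symmetry: sum over unordered off-diagonal pairs
    with n_ij + n_ji > 0 of (n_ij - n_ji)^2 / (n_ij + n_ji); df = number
    of such pairs (<= 6). Degenerate tables (df 0) give stat 0, p 1."""
    n = counts.n
    stat, df = 0.0, 0
    for i, j in combinations(range(4), 2):
        tot = n[i, j] + n[j, i]
        if tot > 0:
            stat += (n[i, j] - n[j, i]) ** 2 / tot
            df += 1
    if df == 0:
        return 0.0, 0, 1.0
    return float(stat), df, float(chi2.sf(stat, df))


def stuart_test(counts: PairedSiteCounts) -> tuple[float | None, int, float, list[str]]:
    """Stuart's test of marginal homogeneity (df 3).

    u = first three components of (row sums - column sums); V[i,i] =
    row_i + col_i - 2 n_ii, V[i,j] = -(n_ij + n_ji); stat = u' V^-1 u.
    A singular V is reported as (None, 3, 1.0, ['degenerate']).
    """
    n = counts.n.astype(float)
    rows, cols = n.sum(axis=1), n.sum(axis=0)
    u = (rows - cols)[:3]
    if np.allclose(u, 0.0):
        return 0.0, 3, 1.0, []
    V = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            if i == j:
                V[i, i] = rows[i] + cols[i] - 2.0 * n[i, i]
            else:
                V[i, j] = -(n[i, j] + n[j, i])
    flags: list[str] = []
    if np.linalg.matrix_rank(V) < 3:
        # states with no off-diagonal flow make V singular; solve in the
        # range of V when u is consistent, otherwise report undefined
        sol, *_ = np.linalg.lstsq(V, u, rcond=None)
        if not np.allclose(V @ sol, u, atol=1e-8 * max(1.0, float(np.abs(u).max()))):
            return None, 3, 1.0, ["degenerate"]
        flags.append("singular_v")
        stat = float(u @ sol)
    else:
        stat = float(u @ np.linalg.solve(V, u))
    stat = max(stat, 0.0)
    return stat, 3, float(chi2.sf(stat, 3)), flags


def internal_symmetry_test(
    counts: PairedSiteCounts,
) -> tuple[float | None, int, float, list[str]]:
    """Internal symmetry: Bowker minus Stuart, df = bowker_df - 3.

    Undefined (df < 1 or degenerate Stuart) gives p 1 with a flag;
    a negative difference is clipped to 0 and flagged.
    """
    b_stat, b_df, _ = bowker_test(counts)
    df = b_df - 3
    if df < 1:
        return None, max(df, 0), 1.0, ["undefined_df"]
    s_stat, _, _, s_flags = stuart_test(counts)
    if s_stat is None:
        return None, df, 1.0, ["degenerate"] + s_flags
    stat = b_stat - s_stat
    flags = []
    if stat < 0:
        if stat < -1e-9:
            flags.append("clipped_negative")
        stat = 0.0
    return float(stat), df, float(chi2.sf(stat, df)), flags


def srh_filter_cluster(
    aln: dict[str, str],
    positions: tuple[int, ...] = (1, 2),
    alpha: float = 0.05,
    correction: str = "none",
) -> SRHResult:
    """Screen a cluster alignment: fail iff any taxon pair's Bowker p
    falls below alpha (after optional Bonferroni over pairs)."""
    taxa = sorted(aln)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    n_pairs = len(taxa) * (len(taxa) - 1) // 2
    cutoff = alpha / n_pairs if correction == "bonferroni" else alpha
    results: list[PairResult] = []
    verdict = "pass"
    for ta, tb in combinations(taxa, 2):
        counts = paired_site_counts(aln, ta, tb, positions)
        b_stat, b_df, b_p = bowker_test(counts)
        s_stat, _, s_p, s_flags = stuart_test(counts)
        i_stat, i_df, i_p, i_flags = internal_symmetry_test(counts)
        results.append(
            PairResult(
                taxon_a=ta,
                taxon_b=tb,
                bowker_stat=b_stat,
                bowker_df=b_df,
                bowker_p=b_p,
                stuart_stat=s_stat,
                stuart_p=s_p,
                internal_stat=i_stat,
                internal_df=i_df,
                internal_p=i_p,
                flags=s_flags + i_flags,
            )
        )
        if b_p < cutoff:
            verdict = "fail"
    return SRHResult(pairs=results, verdict=verdict, alpha=alpha, correction=correction)


def write_srh_report(
    results: dict[str, SRHResult], path: str | Path
) -> None:
    """Per-cluster, per-pair TSV report."""
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\ttaxon_a\ttaxon_b\tbowker_stat\tbowker_df\tbowker_p\t"
            "stuart_stat\tstuart_p\tinternal_stat\tinternal_df\tinternal_p\t"
            "flags\tverdict\n"
        )
        for cid in sorted(results):
            res = results[cid]
            for pr in res.pairs:
                fh.write(
                    f"{cid}\t{pr.taxon_a}\t{pr.taxon_b}\t"
                    f"{pr.bowker_stat:.6g}\t{pr.bowker_df}\t{pr.bowker_p:.6g}\t"
                    f"{'' if pr.stuart_stat is None else f'{pr.stuart_stat:.6g}'}\t"
                    f"{pr.stuart_p:.6g}\t"
                    f"{'' if pr.internal_stat is None else f'{pr.internal_stat:.6g}'}\t"
                    f"{pr.internal_df}\t{pr.internal_p:.6g}\t"
                    f"{','.join(pr.flags)}\t{res.verdict}\n"
                )
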