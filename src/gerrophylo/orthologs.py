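"""Ortholog cluster filtering and supermatrix construction.

Turns raw cluster membership plus tabular pairwise hits into a clean
one-sequence-per-species concatenated alignment: contaminant flagging,
greedy redundancy reduction, species-coverage filtering, cumulative-
best-score representative selection with two-list chimera splitting,
conserved-block selection and codon-position-1+2 concatenation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "TranscriptRecord",
    "HitRecord",
    "OrthologCluster",
    "BlockSet",
    "Supermatrix",
    "flag_contaminants",
    "reduce_redundancy",
    "filter_clusters_by_coverage",
    "cumulative_scores",
    "split_chimeric_cluster",
    "select_representatives",
    "select_blocks",
    "build_supermatrix",
    "read_hit_table",
    "read_cluster_table",
    "read_fasta_dir",
    "write_phylip",
    "read_phylip",
    "write_supermatrix_fasta",
    "write_partition_file",
    "read_partition_file",
]

GAP = "-"


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TranscriptRecord:
    species_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.transcript_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    qlen: int | None
    slen: int | None
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident out of [0,100]: {self.pident}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class OrthologCluster:
    cluster_id: str
    members: set[tuple[str, str]]  # (species_id, transcript_id)

    @property
    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}

    @property
    def transcript_ids(self) -> set[str]:
        return {tid for _, tid in self.members}

    def species_of(self, tid: str) -> str:
        for sp, t in self.members:
            if t == tid:
                return sp
        raise KeyError(tid)


@dataclass
class BlockSet:
    gene_id: str
    alignment_length: int
    blocks: list[tuple[int, int]]  # 1-based inclusive, sorted, disjoint

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.blocks:
            if not (1 <= s <= e <= self.alignment_length):
                raise ValueError(f"{self.gene_id}: block ({s},{e}) out of bounds")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: blocks overlap or unsorted")
            prev_end = e

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]  # taxon -> concatenated sequence
    partitions: list[tuple[str, int, int]]  # (gene_id, start, end) 1-based incl.

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def missing_fraction(self) -> dict[str, float]:
        L = self.length
        return {
            t: (self.rows[t].count(GAP) / L if L else 0.0) for t in self.taxa
        }

    def validate(self) -> None:
        L = self.length
        if any(len(s) != L for s in self.rows.values()):
            raise ValueError("ragged supermatrix rows")
        pos = 1
        for gid, s, e in self.partitions:
            if s != pos or e < s:
                raise ValueError(f"partitions do not tile at {gid}")
            if (e - s + 1) % 2 != 0:
                raise ValueError(f"gene {gid}: segment length not even")
            pos = e + 1
        if self.partitions and pos - 1 != L:
            raise ValueError("partitions do not cover the matrix")


# ----------------------------------------------------------------------
# contaminant flagging
# ----------------------------------------------------------------------
def flag_contaminants(hits: list[HitRecord], db_kind: str = "general") -> set[str]:
    """Transcript ids hit by the contaminant database.

    ``general``: flags pident > 90 AND query coverage > 25%
    (coverage = 100 * aln_length / qlen); both strict inequalities.
    ``cricket``: flags pident >= 90 with no coverage requirement.
    """
    if db_kind not in ("general", "cricket"):
        raise ValueError(f"unknown db_kind {db_kind!r}")
    flagged: set[str] = set()
    for i, h in enumerate(hits):
        if db_kind == "cricket":
            if h.pident >= 90.0:
                flagged.add(h.query_id)
            continue
        if not h.qlen:
            raise ValueError(
                f"hit row {i} (query {h.query_id}): qlen missing or zero, "
                "cannot compute coverage"
            )
        coverage = 100.0 * h.aln_length / h.qlen
        if h.pident > 90.0 and coverage > 25.0:
            flagged.add(h.query_id)
    return flagged


# ----------------------------------------------------------------------
# redundancy reduction (greedy longest-first)
# ----------------------------------------------------------------------
def _global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in one optimal global alignment."""
    if a == b:
        return 1.0
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != GAP for x, y in zip(sa, sb))
    return matches / len(sa)


def reduce_redundancy(
    records: list[TranscriptRecord], identity_threshold: float = 0.995
) -> list[TranscriptRecord]:
    """Greedy longest-first dedupe (naive CD-HIT stand-in).

    Records are visited by length descending then id ascending; a record
    is dropped when its global identity to an already-retained record is
    >= the threshold.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0.5, 1]")
    ordered = sorted(records, key=lambda r: (-r.length, r.transcript_id))
    retained: list[TranscriptRecord] = []
    for rec in ordered:
        if any(
            _global_identity(rec.sequence, kept.sequence) >= identity_threshold
            for kept in retained
        ):
            continue
        retained.append(rec)
    return retained


# ----------------------------------------------------------------------
# coverage filter
# ----------------------------------------------------------------------
def filter_clusters_by_coverage(
    clusters: list[OrthologCluster],
    n_species_total: int,
    min_fraction: float = 0.8,
) -> list[OrthologCluster]:
    """Keep clusters with >= min_fraction * n_species_total distinct species."""
    if n_species_total < 1:
        raise ValueError("n_species_total must be >= 1")
    threshold = min_fraction * n_species_total
    kept = []
    for cl in clusters:
        if not cl.members:
            warnings.warn(f"cluster {cl.cluster_id} is empty; dropped")
            continue
        if len(cl.species) >= threshold:
            kept.append(cl)
    return kept


# ----------------------------------------------------------------------
# cumulative scores & chimera splitting
# ----------------------------------------------------------------------
def _intra_hits(
    cluster: OrthologCluster, hits: list[HitRecord]
) -> list[HitRecord]:
    tids = cluster.transcript_ids
    return [h for h in hits if h.query_id in tids and h.subject_id in tids]


def cumulative_scores(
    cluster: OrthologCluster, hits: list[HitRecord]
) -> dict[str, float]:
    """Sum over other species of the best bitscore from each transcript.

    score(t) = sum over species s' != species(t) of the max bitscore of
    t against any transcript of s' in the cluster; species without a hit
    contribute 0.
    """
    sp_of = {tid: sp for sp, tid in cluster.members}
    best: dict[tuple[str, str], float] = {}
    for h in _intra_hits(cluster, hits):
        if h.query_id == h.subject_id:
            continue
        tgt_sp = sp_of[h.subject_id]
        if tgt_sp == sp_of[h.query_id]:
            continue
        key = (h.query_id, tgt_sp)
        if h.bitscore > best.get(key, -math.inf):
            best[key] = h.bitscore
    scores = {tid: 0.0 for tid in sp_of}
    for (qid, _), sc in best.items():
        scores[qid] += sc
    return scores


def _seq_len(tid: str, lengths: dict[str, int] | None) -> int:
    return lengths.get(tid, 0) if lengths else 0


def _pick_extreme(
    scores: dict[str, float],
    tids: list[str],
    lengths: dict[str, int] | None,
    top: bool,
) -> str:
    # ties: higher score (or lower for the min seed), then longer, then lex id
    key = lambda t: (
        scores[t] if top else -scores[t],
        _seq_len(t, lengths),
        # lexicographically smaller id wins, so invert for max()
    )
    best = None
    for t in sorted(tids):  # lex ascending so first max-hit wins ties
        if best is None or key(t) > key(best):
            best = t
    return best  # type: ignore[return-value]


def _one_division(
    tids: list[str],
    scores: dict[str, float],
    best_evalue: dict[tuple[str, str], tuple[float, float]],
    lengths: dict[str, int] | None,
) -> tuple[list[str], list[str]]:
    seed_hi = _pick_extreme(scores, tids, lengths, top=True)
    rest = [t for t in tids if t != seed_hi]
    seed_lo = _pick_extreme(scores, rest, lengths, top=False)
    list_a, list_b = [seed_hi], [seed_lo]
    for t in sorted(tids):
        if t in (seed_hi, seed_lo):
            continue
        ev_a, bs_a = best_evalue.get((t, seed_hi), (math.inf, -math.inf))
        ev_b, bs_b = best_evalue.get((t, seed_lo), (math.inf, -math.inf))
        # smaller e-value wins; ties by higher bitscore, then toward seed_hi
        if (ev_a, -bs_a) <= (ev_b, -bs_b):
            list_a.append(t)
        else:
            list_b.append(t)
    return list_a, list_b


def split_chimeric_cluster(
    cluster: OrthologCluster,
    hits: list[HitRecord],
    rounds: int = 2,
    lengths: dict[str, int] | None = None,
) -> tuple[list[str], list[str]]:
    """Two-list division that isolates the dominant gene family.

    Each round seeds list A with the max-cumulative-score transcript and
    list B with the min; every other transcript joins the seed to which
    it has the more significant best e-value (no hit = infinitely bad).
    The longer list is divided again (``rounds`` total). Returns
    ``(longest_list, everything_else)``; the two are disjoint and their
    union is the input.
    """
    tids = sorted(cluster.transcript_ids)
    if len(tids) < 2:
        return tids, []
    scores = cumulative_scores(cluster, hits)
    best_ev: dict[tuple[str, str], tuple[float, float]] = {}
    for h in _intra_hits(cluster, hits):
        key = (h.query_id, h.subject_id)
        cand = (h.evalue, h.bitscore)
        prev = best_ev.get(key)
        if prev is None or (cand[0], -cand[1]) < (prev[0], -prev[1]):
            best_ev[key] = cand

    current = tids
    others: list[str] = []
    for _ in range(max(rounds, 1)):
        if len(current) < 2:
            break
        la, lb = _one_division(current, scores, best_ev, lengths)
        if len(la) >= len(lb):
            current, dropped = la, lb
        else:
            current, dropped = lb, la
        others.extend(dropped)
    return sorted(current), sorted(others)


def select_representatives(
    cluster: OrthologCluster,
    hits: list[HitRecord],
    rounds: int = 2,
    lengths: dict[str, int] | None = None,
) -> dict[str, str]:
    """One transcript per species: best cumulative score within the final
    longest list, plus the best-e-value cluster transcript for species
    absent from that list. Covers every species present in the cluster.
    """
    sp_of = {tid: sp for sp, tid in cluster.members}
    longest, _ = split_chimeric_cluster(cluster, hits, rounds=rounds, lengths=lengths)
    scores = cumulative_scores(cluster, hits)

    reps: dict[str, str] = {}
    for tid in longest:
        sp = sp_of[tid]
        cur = reps.get(sp)
        if cur is None:
            reps[sp] = tid
            continue
        a = (scores[tid], _seq_len(tid, lengths))
        b = (scores[cur], _seq_len(cur, lengths))
        if a > b or (a == b and tid < cur):
            reps[sp] = tid

    longest_set = set(longest)
    missing = sorted(cluster.species - set(reps))
    if missing:
        best_ev: dict[str, tuple[float, float, str]] = {}
        for h in _intra_hits(cluster, hits):
            if h.subject_id not in longest_set or h.query_id in longest_set:
                continue
            sp = sp_of[h.query_id]
            cand = (h.evalue, -h.bitscore, h.query_id)
            if sp not in best_ev or cand < best_ev[sp]:
                best_ev[sp] = cand
        for sp in missing:
            if sp in best_ev:
                reps[sp] = best_ev[sp][2]
            else:
                # no hit into the longest list: fall back to best score
                cands = sorted(
                    (tid for t_sp, tid in cluster.members if t_sp == sp),
                )
                reps[sp] = max(
                    cands, key=lambda t: (scores[t], _seq_len(t, lengths), t)
                )
    return reps


# ----------------------------------------------------------------------
# conserved blocks
# ----------------------------------------------------------------------
def select_blocks(
    block_set: BlockSet,
    min_coverage: float = 0.5,
    min_total_nt: int = 100,
) -> tuple[bool, list[tuple[int, int]]]:
    """Gene kept iff cumulative block length covers > min_coverage of the
    alignment and totals >= min_total_nt; returns (kept, ordered blocks)."""
    total = block_set.total_length
    kept = (
        total / block_set.alignment_length > min_coverage
        and total >= min_total_nt
    )
    return kept, list(block_set.blocks) if kept else []


def _codon_trim(block: tuple[int, int], gene_id: str) -> tuple[int, int] | None:
    """Trim a 1-based inclusive block inward to codon boundaries."""
    s, e = block
    if s % 3 != 1:
        s = s + ((1 - s) % 3)
    length = e - s + 1
    if length % 3 != 0:
        e = s + (length // 3) * 3 - 1
    if e < s:
        return None
    if (s, e) != block:
        warnings.warn(
            f"gene {gene_id}: block {block} trimmed to codon frame ({s},{e})"
        )
    return s, e


# ----------------------------------------------------------------------
# supermatrix
# ----------------------------------------------------------------------
def build_supermatrix(
    gene_alignments: dict[str, dict[str, str]],
    gene_blocks: dict[str, list[tuple[int, int]]],
    taxa: list[str] | None = None,
    codon_positions: tuple[int, ...] = (1, 2),
) -> Supermatrix:
    """Concatenate selected codon positions of kept blocks across genes.

    ``gene_alignments`` maps gene_id -> {taxon: aligned sequence}; taxa
    missing from a gene are padded with gaps. Blocks must be codon
    framed (trimmed inward with a warning otherwise).
    """
    if taxa is None:
        universe: set[str] = set()
        for aln in gene_alignments.values():
            universe |= set(aln)
        taxa = sorted(universe)
    keep_offsets = sorted(p - 1 for p in codon_positions)
    if any(o not in (0, 1, 2) for o in keep_offsets):
        raise ValueError("codon_positions must be within {1,2,3}")

    rows = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 1
    for gid in sorted(gene_alignments):
        aln = gene_alignments[gid]
        aln_len = len(next(iter(aln.values())))
        if any(len(s) != aln_len for s in aln.values()):
            raise ValueError(f"gene {gid}: ragged alignment")
        cols: list[int] = []
        for block in gene_blocks.get(gid, []):
            s, e = block
            if (e - s + 1) % 3 != 0 or s % 3 != 1:
                trimmed = _codon_trim(block, gid)
                if trimmed is None:
                    continue
                s, e = trimmed
            if e > aln_len:
                raise ValueError(f"gene {gid}: block ({s},{e}) beyond alignment")
            for codon_start in range(s - 1, e, 3):
                cols.extend(codon_start + o for o in keep_offsets)
        if not cols:
            continue
        seg_len = len(cols)
        for t in taxa:
            seq = aln.get(t)
            if seq is None:
                rows[t].append(GAP * seg_len)
            else:
                rows[t].append("".join(seq[c] for c in cols))
        partitions.append((gid, pos, pos + seg_len - 1))
        pos += seg_len

    sm = Supermatrix(
        taxa=list(taxa),
        rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=partitions,
    )
    sm.validate()
    return sm


# ----------------------------------------------------------------------
# IO
# ----------------------------------------------------------------------
def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read an outfmt-6 extended hit table (header optional, '#' comments)."""
    cols = ["qseqid", "sseqid", "pident", "length", "qlen", "slen", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    first = [str(x) for x in df.iloc[0]]
    if first[:2] == ["qseqid", "sseqid"]:
        df = df.iloc[1:]
    if df.shape[1] < 8:
        raise ValueError(f"{path}: expected >=8 columns, got {df.shape[1]}")
    df = df.iloc[:, :8]
    df.columns = cols
    out = []
    for r in df.itertuples(index=False):
        out.append(
            HitRecord(
                query_id=r.qseqid,
                subject_id=r.sseqid,
                pident=float(r.pident),
                aln_length=int(float(r.length)),
                qlen=int(float(r.qlen)) if r.qlen not in (None, "", "NA") else None,
                slen=int(float(r.slen)) if r.slen not in (None, "", "NA") else None,
                evalue=float(r.evalue),
                bitscore=float(r.bitscore),
            )
        )
    return out


def read_cluster_table(path: str | Path) -> list[OrthologCluster]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"cluster_id", "species_id", "transcript_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    clusters: dict[str, set[tuple[str, str]]] = {}
    for r in df.itertuples(index=False):
        clusters.setdefault(r.cluster_id, set()).add((r.species_id, r.transcript_id))
    return [OrthologCluster(cid, mem) for cid, mem in sorted(clusters.items())]


def read_fasta_dir(path: str | Path) -> dict[str, TranscriptRecord]:
    """Read every ``*.fasta`` in a directory; filename stem = species id."""
    from Bio import SeqIO

    out: dict[str, TranscriptRecord] = {}
    for fp in sorted(Path(path).glob("*.fasta")):
        sp = fp.stem
        for rec in SeqIO.parse(str(fp), "fasta"):
            out[rec.id] = TranscriptRecord(sp, rec.id, str(rec.seq).upper())
    return out


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")


def read_phylip(path: str | Path) -> tuple[list[str], dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().split()
        ntax, length = int(header[0]), int(header[1])
        taxa, rows = [], {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows[name] = seq.strip()
    if len(taxa) != ntax or any(len(s) != length for s in rows.values()):
        raise ValueError(f"{path}: malformed relaxed PHYLIP")
    return taxa, rows


def write_supermatrix_fasta(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sm.taxa:
            fh.write(f">{t}\n{sm.rows[t]}\n")


def write_partition_file(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, s, e in sm.partitions:
            fh.write(f"DNA, {gid} = {s}-{e}\n")


def read_partition_file(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, rest = line.split(",", 1)
            name, span = rest.split("=")
            s, e = span.strip().split("-")
            out.append((name.strip(), int(s), int(e)))
    return out
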