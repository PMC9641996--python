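"""End-to-end pipeline: contaminants -> coverage filter -> representatives
-> conserved blocks -> SRH screen -> supermatrix, with a manifest that
makes reruns bit-reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .orthologs import (
    BlockSet,
    build_supermatrix,
    filter_clusters_by_coverage,
    flag_contaminants,
    read_cluster_table,
    read_fasta_dir,
    read_hit_table,
    select_blocks,
    select_representatives,
    write_partition_file,
    write_phylip,
    write_supermatrix_fasta,
)
from .srh import srh_filter_cluster, write_srh_report

log = logging.getLogger("gerrophylo")

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    clusters: str
    hits: str
    fasta_dir: str
    out_dir: str
    n_species: int
    contaminant_hits: str | None = None
    contaminant_db_kind: str = "general"
    min_frac: float = 0.8
    block_min_coverage: float = 0.5
    block_min_nt: int = 100
    block_table: str | None = None  # gene_id, start, end TSV; default: full gene
    srh_alpha: float = 0.05
    srh_positions: tuple[int, ...] = (1, 2)
    srh_correction: str = "none"
    codon_positions: tuple[int, ...] = (1, 2)
    chimera_rounds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_frac <= 1.0:
            raise ValueError("min_frac must be in (0, 1]")
        if not 0.0 < self.srh_alpha < 1.0:
            raise ValueError("srh_alpha must be in (0, 1)")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file mirroring the CLI flags."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("srh_positions", "codon_positions"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(path: str | None, what: str) -> None:
    if path is not None and not Path(path).exists():
        raise FileNotFoundError(f"missing input: {what} ({path})")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every matrix-building stage; returns the run directory."""
    t0 = time.time()
    for path, what in (
        (config.clusters, "cluster table"),
        (config.hits, "hit table"),
        (config.fasta_dir, "FASTA directory"),
        (config.contaminant_hits, "contaminant hit table"),
        (config.block_table, "block table"),
    ):
        _require(path, what)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts: dict[str, object] = {}
    transcripts = read_fasta_dir(config.fasta_dir)
    clusters = read_cluster_table(config.clusters)
    hits = read_hit_table(config.hits)
    counts["transcripts_in"] = len(transcripts)
    counts["clusters_in"] = len(clusters)

    # stage 1: contaminants
    contaminants: set[str] = set()
    if config.contaminant_hits:
        cont_hits = read_hit_table(config.contaminant_hits)
        contaminants = flag_contaminants(cont_hits, config.contaminant_db_kind)
    for cl in clusters:
        cl.members = {(sp, t) for sp, t in cl.members if t not in contaminants}
    hits = [
        h
        for h in hits
        if h.query_id not in contaminants and h.subject_id not in contaminants
    ]
    counts["contaminants_flagged"] = len(contaminants)
    log.info("flagged %d contaminant transcripts", len(contaminants))

    # stage 2: coverage filter
    kept = filter_clusters_by_coverage(clusters, config.n_species, config.min_frac)
    counts["clusters_after_coverage"] = len(kept)
    funnel = [
        {
            "cluster_id": cl.cluster_id,
            "n_species": len(cl.species),
            "decision": "keep" if cl in kept else "drop",
            "reason": "" if cl in kept else f"<{config.min_frac:.0%} species",
        }
        for cl in clusters
    ]

    # stage 3: representatives (with chimera splitting)
    lengths = {tid: rec.length for tid, rec in transcripts.items()}
    gene_alignments: dict[str, dict[str, str]] = {}
    for cl in kept:
        reps = select_representatives(
            cl, hits, rounds=config.chimera_rounds, lengths=lengths
        )
        aln = {}
        min_len = min(
            (len(transcripts[t].sequence) for t in reps.values() if t in transcripts),
            default=0,
        )
        min_len -= min_len % 3
        for sp, tid in reps.items():
            if tid in transcripts and min_len:
                aln[sp] = transcripts[tid].sequence[:min_len]
        if aln:
            gene_alignments[cl.cluster_id] = aln
    counts["genes_with_representatives"] = len(gene_alignments)
    genes_dir = out / "genes"
    genes_dir.mkdir(exist_ok=True)
    for gid, aln in gene_alignments.items():
        with open(genes_dir / f"{gid}.fasta", "w") as fh:
            for sp in sorted(aln):
                fh.write(f">{sp}\n{aln[sp]}\n")

    # stage 4: conserved blocks
    block_in: dict[str, list[tuple[int, int]]] = {}
    if config.block_table:
        import pandas as pd

        df = pd.read_csv(config.block_table, sep="\t", dtype=str)
        for r in df.itertuples(index=False):
            block_in.setdefault(r.gene_id, []).append((int(r.start), int(r.end)))
    gene_blocks: dict[str, list[tuple[int, int]]] = {}
    for gid, aln in gene_alignments.items():
        L = len(next(iter(aln.values())))
        blocks = sorted(block_in.get(gid, [(1, L)]))
        bs = BlockSet(gid, L, blocks)
        ok, kept_blocks = select_blocks(
            bs, config.block_min_coverage, config.block_min_nt
        )
        if ok:
            gene_blocks[gid] = kept_blocks
    counts["genes_after_block_rule"] = len(gene_blocks)

    # stage 5: SRH screen at the analysis codon positions
    srh_results = {}
    srh_pass: dict[str, list[tuple[int, int]]] = {}
    for gid in sorted(gene_blocks):
        res = srh_filter_cluster(
            gene_alignments[gid],
            positions=config.srh_positions,
            alpha=config.srh_alpha,
            correction=config.srh_correction,
        )
        srh_results[gid] = res
        if res.verdict == "pass":
            srh_pass[gid] = gene_blocks[gid]
    write_srh_report(srh_results, out / "srh_report.tsv")
    counts["genes_after_srh"] = len(srh_pass)

    # stage 6: supermatrix
    sm = build_supermatrix(
        {g: gene_alignments[g] for g in srh_pass},
        srh_pass,
        codon_positions=config.codon_positions,
    )
    counts["supermatrix_taxa"] = len(sm.taxa)
    counts["supermatrix_length"] = sm.length
    write_phylip(sm, out / "supermatrix.phy")
    write_supermatrix_fasta(sm, out / "supermatrix.fasta")
    write_partition_file(sm, out / "partitions.txt")
    with open(out / "filter_report.tsv", "w") as fh:
        fh.write("cluster_id\tn_species\tdecision\treason\n")
        for row in funnel:
            fh.write(
                f"{row['cluster_id']}\t{row['n_species']}\t"
                f"{row['decision']}\t{row['reason']}\n"
            )

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "counts": counts,
        "runtime_s": round(time.time() - t0, 3),
    }
    stable = {k: v for k, v in manifest.items() if k != "runtime_s"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(stable, fh, indent=1, sort_keys=True)
    log.info("pipeline finished in %.1fs: %s", time.time() - t0, counts)
    return out


def write_report(run_dir: str | Path) -> Path:
    """Consolidate a finished run directory into report.json."""
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    report: dict[str, object] = {"complete": True}
    if not manifest_path.exists():
        report["complete"] = False
        report["missing"] = ["manifest.json"]
    else:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        report["counts"] = manifest["counts"]
        report["config_hash"] = manifest["config_hash"]
    funnel = run / "filter_report.tsv"
    if funnel.exists():
        report["filter_funnel"] = funnel.read_text().splitlines()[1:]
    srh = run / "srh_report.tsv"
    if srh.exists():
        lines = srh.read_text().splitlines()[1:]
        verdicts = {}
        for ln in lines:
            parts = ln.split("\t")
            verdicts[parts[0]] = parts[-1]
        report["srh_verdicts"] = verdicts
    out_path = run / "report.json"
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return out_path
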