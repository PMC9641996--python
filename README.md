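# gerrophylo

Desk-scale re-implementation of a transcriptome-based phylogenomic
workflow for semi-aquatic bugs: building a filtered ortholog supermatrix
(contaminant removal, species-coverage filtering, representative
transcript selection with chimeric-cluster splitting, conserved-block
concatenation of codon positions 1+2, matched-pairs SRH symmetry
screening) and the downstream ancestral-character-state analyses
(Mk-model fitting with LRT/AICc model choice, marginal "pies",
stochastic character mapping, Sankoff parsimony, independent-transition
counting, Pagel's lambda, and Brownian-motion ancestral estimates with
confidence intervals). A synthetic-data generator with recorded ground
truth stands in for raw transcriptomes, so every stage is testable
offline.

## Package layout

| module | contents |
| --- | --- |
| `gerrophylo.simulate` | birth-death trees, discrete/continuous trait simulators with explicit histories, ortholog clusters (isoforms, paralogs, planted chimeras, contaminants) with hit tables, codon alignments with optional clade compositional shifts |
| `gerrophylo.orthologs` | contaminant flagging, greedy redundancy reduction, species-coverage filter, cumulative best-hit scores, two-list chimera division, representative selection, conserved-block rule, supermatrix construction + PHYLIP/FASTA/partition IO |
| `gerrophylo.srh` | Bowker / Stuart / internal symmetry tests and the per-cluster screen |
| `gerrophylo.discrete` | Mk likelihood (pruning), ER/SYM/ARD fitting, LRT/AICc model choice, marginal ancestral states, stochastic mapping (uniformization), Sankoff parsimony, transition counting |
| `gerrophylo.continuous` | lambda transform, BM likelihood, Pagel's lambda profile ML, GLS ancestral estimates with variances and 95% CIs |
| `gerrophylo.pipeline` / `gerrophylo.cli` | stage orchestration, manifests, reports, `gerrophylo` CLI |

## CLI

```bash
# generate a synthetic dataset with recorded truth
gerrophylo simulate --seed 1 --n-species 20 --n-clusters 50 --out data/

# clusters + hits -> filtered codon-1+2 supermatrix
gerrophylo matrix --clusters data/clusters.tsv --hits data/hits.tsv \
    --fasta-dir data/fasta --n-species 20 --min-frac 0.8 --out run/

# SRH screen over alignments
gerrophylo srh --aln-dir alns/ --positions 12 --alpha 0.05 --out srh.tsv

# discrete ancestral reconstruction (model choice, pies, maps, counts)
gerrophylo asr-discrete --tree tree.nwk --trait salinity.csv \
    --models ER,SYM,ARD --nsim 2000 --seed 42 --out asr/

# continuous: Pagel's lambda + BM ancestral states with CIs
gerrophylo asr-continuous --tree tree.nwk --trait legs.csv --out legs_anc.tsv

# consolidate a finished run directory
gerrophylo report run/
```

Exit codes: 0 ok, 2 input error, 3 numerical failure.

## Acceptance

Acceptance is property-based (likelihood/parsimony enumeration oracles,
closed forms, Monte-Carlo calibration and recovery experiments); each
criterion is one test in `tests/test_acceptance.py`. The report script
runs a seeded end-to-end self-check and emits the (empty) numeric target
object:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
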