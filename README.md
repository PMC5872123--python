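# smgcpan

Annotation-independent comparison of secondary metabolite biosynthetic gene
clusters (SMGCs) across closely related bacterial genomes.

Given per-genome cluster regions (GenBank, TSV or JSON dialects), a genome
metadata table and a newick phylogeny, the pipeline:

1. **orthology** — groups all cluster genes into ortholog groups by local
   protein alignment (Smith–Waterman, affine gaps, BLOSUM62), "maxbit"
   score normalization (`score(a,b) / max(selfscore(a), selfscore(b))`,
   cutoff 0.04) and Markov clustering (MCL, inflation 2.0);
2. **family_clustering** — reduces each cluster to its ortholog-group
   content and merges clusters at binary Jaccard dissimilarity ≤ 0.4 into
   non-redundant families (connected components), with a threshold-sweep
   diagnostic;
3. **pan_analysis** — presence/absence matrix, core (≥ 80% prevalence) /
   clade-core / accessory / strain-specific partition, occupancy spectra,
   within/between-clade sharing, per-class tallies with Welch t-tests and
   Bonferroni correction, count statistics, Kolmogorov–Smirnov spectrum
   comparison, and known-cluster coverage against a reference set
   (well-characterized at ≥ 70% gene hits);
4. **gainloss** — Fitch and Dollo parsimony reconstruction of per-family
   gain/loss events on the tree, plus a frequency heuristic flagging
   recent-acquisition (occupancy 1–3) and recent-deletion ("near core")
   candidates;
5. **synthetic_data** — a seeded simulator (Yule trees, two sister clades
   plus intermediate taxa, family gain/loss, gene turnover, sequence
   divergence) with full ground truth, and a deterministic fixture that
   reproduces the published pan-SMGC summary counts (310 families, 177
   strain-specific, 9 + 2 + 6 core decomposition).

Two alignment engines are provided: a pure-Python reference DP and
Biopython's C `PairwiseAligner` (default; identical scores). Alignment-based
orthology is quadratic in gene count and intended for genes within cluster
regions, not whole genomes; precomputed ortholog tables can be supplied to
bypass it.

## CLI

```sh
# synthetic dataset: clusters.tsv, metadata.tsv, tree.nwk, truth.json
smgcpan simulate --outdir data --seed 1 [--config run.yaml]

# orthology + families (+ GraphML/SIF networks for Cytoscape)
smgcpan cluster --clusters data/clusters.tsv --outdir clust

# pan partition, spectra, stats, gain/loss events
smgcpan pan --families clust/families.tsv --metadata data/metadata.tsv \
            --tree data/tree.nwk --outdir pan

# Jaccard threshold sweep
smgcpan sweep --ortholog-table clust/ortholog_table.tsv --out sweep.tsv

# deterministic paper-shaped fixture (matrix.tsv + metadata.tsv)
smgcpan fixture --outdir fix --seed 0
smgcpan pan --matrix fix/matrix.tsv --metadata fix/metadata.tsv --outdir panfix
```

All thresholds live in a YAML config (`orthology:`, `family:`, `pan:`,
`scoring:`, `simulation:` sections mirroring the dataclass fields); the
effective config is copied into every output directory. Outputs are plain
TSV/JSON, so any stage can be replaced by external tools.

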