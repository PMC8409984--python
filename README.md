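# regatlas

Analysis toolkit for regional gene-expression atlases (gene × sample TPM
matrices over brain regions and stem-cell reference samples):

- **synthetic**: atlas generator with planted ground truth — region-specific
  marker genes, co-expressed gene modules tied to region groups, a
  developmental-stage program, and gene lists planted to peak in designated
  region groups. Every downstream stage has a recovery test against this
  truth.
- **exprio**: TSV I/O for expression matrices, sample metadata, and gene
  lists; transcript→gene aggregation; replicate averaging; per-gene
  z-scaling; human→mouse symbol case normalization.
- **frequency**: per-gene regional frequency percentages (each gene's row
  sums to 100), per-list mean ± SEM summaries, top contributing genes per
  region, peak-region calls, and pairwise region comparisons (one-way ANOVA
  with pooled-variance contrasts) under the Benjamini–Krieger–Yekutieli
  two-stage FDR.
- **gsea**: from-scratch gene-set enrichment — signal-to-noise target-vs-rest
  ranking, weighted running-sum enrichment score, gene-set permutation null,
  NES, and per-list BH FDR with a positive-score significance flag.
- **modules**: co-expression modules three ways — WGCNA-style
  (soft-thresholded |correlation| adjacency, topological overlap matrix,
  average-linkage tree with static cut), hierarchical at fixed k, and
  k-means with elbow-based k selection — plus sample dendrograms, adjusted
  Rand agreement, and heatmap gene ordering (module number, then
  within-module leaf order).
- **overrep**: module composition percentages and the overrepresentation
  score `w / ((x/y)·z) − 1` (observed over size-proportional expectation,
  minus one).
- **pipeline/cli**: config-driven end-to-end runs with a checksummed
  manifest, and report generation.

## CLI

```sh
regatlas simulate --out-dir sim --seed 1            # synthetic atlas + truth
regatlas frequency --matrix sim/matrix.tsv --metadata sim/metadata.tsv \
    --lists sim/lists.tsv --out-dir freq
regatlas gsea --matrix sim/matrix.tsv --metadata sim/metadata.tsv \
    --lists sim/lists.tsv --level group --n-perm 1000 --seed 1 --out gsea.tsv
regatlas modules --matrix sim/matrix.tsv --metadata sim/metadata.tsv \
    --lists sim/lists.tsv --method wgcna --out-dir mod
regatlas overrep --assignment mod/assignment.tsv --lists sim/lists.tsv \
    --out overrep.tsv
```

Or one config-driven run (stages: simulate → frequency → gsea → modules →
overrep, deterministic under a fixed seed):

```sh
regatlas run --config examples/run.yaml --out-dir out --seed 1
regatlas report --run-dir out
```

A minimal config:

```yaml
seed: 1
simulate:
  n_genes: 400
  n_modules_planted: 5
  module_size: 30
gsea: {n_perm: 1000, level: group}
modules: {method: wgcna, cut_fraction: 0.95}
overrep: {formula: paper}
```

Explicit inputs instead of simulation: replace `simulate:` with
`inputs: {matrix: …, metadata: …, lists: …}`. All outputs are TSV/JSON/
Newick; the manifest records input checksums, parameters, and the seed.

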