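# tispec

Tissue-specificity scoring of bulk expression data and downstream
analysis of tissue-specific genes as drug targets.

Narrow expression in one tissue is a classic desideratum for drug
targets (fewer off-tissue side effects), and tissue-specific genes are
historically overrepresented among targets of marketed non-oncology
drugs.  `tispec` provides a tested, reusable implementation of that
analysis chain for anyone studying target landscapes: computational
biologists ranking candidate targets, and methodologists who want the
statistics reproducible end to end.

## The model

Starting from a gene × tissue table of mean expression (RPKM-like,
non-negative), expression is standardized twice ("double Z"):

1. across tissues within each gene: `z1 = (v − mean_row) / sd_row`
2. across genes within each tissue: `z = (z1 − mean_col) / sd_col`

so that all genes' scores share one scale.  A gene is **tissue-specific
at stringency x** (integer 2..10) when

```
Z_second_largest < (1/x) · Z_max,   Z_max > 0
```

where `Z_max` is the gene's highest per-tissue score and
`Z_second_largest` its second highest.  The definitions nest: a gene
specific at x is specific at every smaller x.

Around this classifier the package implements:

- **Enrichment scans** (`tispec.stats`): one-tailed Fisher exact tests
  of tissue-specific genes within drug-target categories across the
  stringency grid, with fold enrichment measured against the
  all-protein-coding background prevalence and Bonferroni adjustment.
- **Target catalog analyses** (`tispec.targets`): per-gene maximal
  clinical phase (1 < 2 < 3 < marketed; withdrawn flagged separately),
  global oncology status, target *reuse* (a marketed-drug target also
  hit by a phase 1–3 candidate drug), and first-approval-year
  comparisons with an exact, tie-aware rank-sum test.
- **Conservation comparisons** (`tispec.conservation`): fractions of
  genes lacking 1-to-1 orthologs, and Mann-Whitney comparisons of
  Ka/Ks, sequence identity and similarity on 1-to-1 orthologs (Ka/Ks
  restricted to mammalian species).
- **Network topology** (`tispec.network`): a confidence-weighted
  protein-interaction graph where the combined score *s* weights
  strength, eigenvector centrality and weighted k-shell, while
  `1 − s` is the edge length for betweenness and closeness
  ("least-uncertainty paths").  The weighted k-shell prunes on
  `k′ = round(√(degree · strength))`.
- **Opportunity mapping** (`tispec.opportunities`): exploration status,
  pLI/LOEUF loss-of-function classes, genetic evidence (OMIM or
  PTVesc), and disjoint UpSet-style druggability buckets.
- **Synthetic data** (`tispec.simulate`): seeded generators for all
  five input tables with planted, controllable signals, so every stage
  is testable without any download.

## Worked example

Simulate a small study (4,000 genes × 30 tissues, 5% of genes planted
with a fold-50 single-tissue peak) and run the whole pipeline:

```
$ cat run.yaml
sim:
  n_genes: 4000
  network_nodes: 600
$ tispec run --config run.yaml --simulate --seed 7 --outdir demo
pipeline complete: demo
```

`demo/calls.tsv` holds one row per gene with its peak tissue and the
stringencies it satisfies.  In this run 200 of 4,000 genes are
tissue-specific at x = 6 — exactly the planted set.  The enrichment
scan (`demo/enrichment.tsv`) recovers the planted 2.3× overrepresentation
of tissue-specific genes among marketed non-oncology drug targets:

```
                      group  a     fold            p    p_adj
non-oncology_phase_marketed 52 2.180294 1.464118e-08 0.000001
```

i.e. 52 of that group's targets are tissue-specific at x = 6, a
2.18-fold enrichment over the background prevalence.  The reuse
analysis on the same catalog:

```
$ tispec targets --drugs demo/fixtures/drugs.tsv --calls demo/calls.tsv \
    --x 6 --out targets.tsv
reuse at x=6: TS 18/61 (29.5%) vs non-TS 420/622 (67.5%), ratio 2.3, p = 8.6e-09
```

meaning tissue-specific targets of marketed drugs were reused by
candidate drugs 2.3 times less often than never-specific targets in
this simulation (the generator's planted reuse probabilities are 34.3%
vs 66.3%).  Other outputs: `table1.tsv`/`table2.tsv` (betweenness
medians and IQRs per gene group), `conservation.tsv` (ortholog coverage
and Ka/Ks comparisons), `opportunities.tsv` and `upset.tsv` (druggable,
unexplored tissue-specific genes), and `manifest.json` (input/output
checksums for reproducibility).

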