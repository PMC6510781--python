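# Methods

## Tissue-specificity scoring

The classifier operates on per-tissue *mean* expression (RPKM-like,
non-negative), not sample-level data; an optional helper
(`per_tissue_means`) aggregates a sample-level matrix by arithmetic
mean over all samples of a tissue.  Two standardization passes follow.
The first pass ("across tissues") centers and scales each gene's row,
turning expression into a within-gene profile; the second pass
("across genes") standardizes each tissue column of the pass-1 scores.
The second pass is column-wise rather than a global rescale: its
purpose is to put all genes' scores on one comparable scale, which a
global affine rescale of an already row-standardized matrix would not
change.  Both passes use the sample standard deviation (n−1) by
default; the convention is configurable (`ddof=0`) because it is
immaterial to the peak ratio after rescaling but must be pinned for
bit-reproducibility.  No log transform is applied before standardizing
(the criterion is defined on the linear scale); `log_transform=True`
exposes a `log2(v+1)` variant.

A gene is tissue-specific at integer stringency x ∈ [2, 10] when
`Z_second_largest < Z_max / x` with strict inequality and `Z_max > 0`.
Degenerate cases are resolved as follows:

- constant rows (zero variance) are flagged "flat", score 0, never
  specific;
- a zero-variance column after pass 1 is left centered at 0 with a
  warning;
- `Z_max ≤ 0` means no positive peak; the inequality direction would
  invert and break the nesting of stringencies, so such genes are
  defined non-specific;
- `Z_max = Z_second_largest` (ties) fails the strict inequality;
  the argmax tissue is the first in column order, deterministically.

These choices make the satisfied stringencies downward-closed, so each
gene carries a single `max_x` summarizing its entire profile.

## Enrichment statistics

Every categorical comparison is a one-tailed Fisher exact test on the
category-vs-complement 2×2 table, with the direction (enrichment or
depletion) fixed a priori per analysis and passed explicitly — never
inferred from the observed table.  Fold enrichment is reported against
the *full-universe* prevalence (category prevalence ÷ prevalence among
all genes), matching the convention of plotting category bars against
an all-protein-coding background line; the two conventions give the
same 1-decimal folds on the published tables.  Bonferroni family size
defaults to the number of tests emitted by the same scan and is
configurable per analysis, because the appropriate family depends on
what a study reports together.

Mann-Whitney comparisons use midranks for ties.  Below ~20,000
group-assignment combinations the two-sided p is computed exactly by
enumerating all assignments of the observed (possibly tied) ranks —
the exact conditional null distribution, valid under ties — and the
tie-corrected normal approximation above.  The approval-year
comparison always goes through the same exact tie-aware path, since
approval years are heavily tied small samples.

## Target catalog

Drugs carry a maximal clinical phase (1, 2, 3, marketed, withdrawn), an
indication class, and (for marketed/withdrawn) a first approval year.
Per-gene records take the maximum phase over drugs (1 < 2 < 3 <
marketed).  Withdrawn drugs were marketed once, so their targets keep
marketed-level status with a separate withdrawn flag; targets with only
withdrawn drugs can still be scanned as their own group.  The oncology
flag is global per protein — one oncology drug suffices — with
per-phase recomputation possible by filtering the drug list.  A
marketed-drug target is *reused* when at least one phase 1–3 drug also
targets it; the comparator group in the reuse analysis is targets
satisfying *no* stringency at all, not merely "not specific at this x".

## Conservation

Genes with 1-to-many or many-to-many orthologs count as lacking a
1-to-1 ortholog, as duplicated orthologs tend to diverge in function.
Metric comparisons (Ka/Ks, % identity, % similarity) are restricted to
1-to-1 ortholog records; Ka/Ks is additionally refused for species not
in the configured mammal list, because synonymous-site saturation at
larger evolutionary distances makes the ratio uninterpretable.
Duplicate 1-to-1 records per gene keep the first occurrence with a
warning.

## Network topology

Combined confidence scores (0–1000) are scaled to s ∈ (0, 1] and play a
dual role: s weights strength (Σ incident s), eigenvector centrality
and the weighted k-shell, while 1 − s is the edge length for
betweenness and closeness, making shortest paths least-uncertainty
paths.  Numerical contract, frozen:

- scores are clamped to ≤ 0.999 so edge lengths are strictly positive
  (a no-op for integer inputs capped at 999);
- betweenness is unnormalized raw pair counts, each unordered pair
  counted once, tied shortest paths splitting credit equally;
- closeness is (n−1)/Σd on the largest connected component;
- eigenvector centrality is the principal eigenvector of the
  s-weighted adjacency by power iteration on A + I (the shift keeps
  the same eigenvector but prevents oscillation on bipartite-like
  graphs), tolerance 1e-10, cap 10,000 iterations, unit L2 norm,
  nonnegative orientation;
- the weighted k-shell uses k′ = round(√(degree · strength)) with
  half-up rounding (the geometric mean of connectivity and summed
  confidence, exponents 1/1), and prunes cascade-within-level:
  at level ℓ all nodes with current k′ ≤ ℓ are removed, k′ recomputed
  after each wave until the level stabilizes, then ℓ increments.  With
  unit scores this reduces exactly to the classic k-core, which the
  test suite verifies on random graphs.

The five reported centralities are strength, eigenvector, weighted
k-shell, betweenness and closeness; closeness is included as the
standard second shortest-path measure alongside betweenness.  All are
computed on the largest connected component (ties between equal-size
components broken by smallest lexicographic node id).

## Opportunity mapping

"Explored" means targeted by any marketed or clinical-trial drug.
Druggability is the OR of five flags: Tchem development level,
secretion, a known ChEMBL compound, a solved structure, a drugged
protein family.  Overlaps are reported as *disjoint* UpSet buckets
(one count per observed flag combination) plus the marginal totals, so
genes qualifying under several flags are never double counted and no
precedence rule is needed.  pLI thresholds are ≤ 0.1 (tolerant) and
≥ 0.9 (intolerant), both boundaries inclusive; LOEUF is reported as
per-group distributions rather than thresholded.

## Synthetic data

The generators emulate the statistical structure of a genome-scale
human target landscape so the full pipeline runs with no downloads.
Defaults (the study conditions of the test suite):

- **Expression**: 20,000 genes × 30 tissues.  Per-gene baselines are
  log-normal across genes (meanlog 1, sdlog 1 — an RPKM-like dynamic
  range).  Across tissues a background gene fluctuates around its
  baseline with bounded symmetric multiplicative noise (cv 0.25,
  normal clipped at ±2σ).  The bound is deliberate: the peak criterion
  is scale-invariant, and any unbounded i.i.d. noise (even Gaussian)
  produces a few-percent rate of genuine-looking single-tissue peaks
  among background genes — but a single-tissue peak is precisely the
  planted signal, so a generator whose "null" genes carry real peaks
  has no null.  With the bound, null genes pass the x = 2 criterion at
  ~0.2–0.4%.  Planted genes (5% by default) get one uniformly chosen
  tissue multiplied by fold 50.
- **Annotations**: Bernoulli flags with base rates outside the planted
  set and base × relative-risk inside (OMIM 0.211 × 1.27, PTVesc
  0.104 × 1.5 — the published contingency geometry; essentiality,
  secretion, enzyme, and druggability flags at field-plausible rates);
  pLI from a tolerant/intolerant beta mixture, LOEUF log-normal, both
  shifted toward tolerance in the planted set; TDL multinomial.
- **Catalog**: phase-group sizes a few hundred targets each (matching
  the published group sizes), sampled disjointly so a gene's group is
  its maximal phase; planted-set sampling weight 2.3 for marketed
  non-oncology (and < 1 for phase 1) sets the overrepresentation;
  reuse probabilities 0.343 (planted) vs 0.663; withdrawn drugs reuse
  marketed targets with probability 0.95.  `catalog_scale` shrinks all
  groups proportionally for desk-scale runs.
- **Orthologs**: homology-type multinomial with no-1-to-1 rates 0.20
  (background) vs 0.30 (planted); Ka/Ks ~ Gamma(2, 0.07) (median
  ≈ 0.12, strong purifying selection) plus a +0.1 shift in the planted
  group; similarity constructed anti-correlated with Ka/Ks.
- **Network**: two preferential-attachment communities (Barabási–Albert,
  m = 3, 2,000 nodes total) joined only through planted bridge nodes.
  Bridges anchor on several below-median-degree nodes per side with
  uniform top-confidence edges, so inter-community traffic spreads
  across spokes and no community hub outranks the bridge itself.

A single root seed fans out to fixed per-table child seeds, so
regenerating one table never perturbs another and identical
config + seed reproduces byte-identical outputs.

What the generator does *not* emulate: GTEx sample-level count noise
and shared tissue factors (tissues are exchangeable here), correlated
annotation flags (enzymes are not enriched among secreted proteins,
etc.), multi-target drugs, STRING's per-channel evidence structure,
and degree-dependent annotation biases.  Passing tests therefore show
that the statistics recover signals of the planted form at the planted
magnitudes — not that real GTEx/ChEMBL/STRING data would yield the
published genome-scale counts, which require the original external
inputs and substantially more compute (the full STRING component has
19,574 nodes and 5.7 M edges).

## Problem sizes

The test suite runs the classifier recovery at 2,000 genes × 30
tissues, annotation and catalog recovery at the full 20,000-gene
default, network tests at 100–600 nodes, and the conservation
replication over 100 seeded generations of 1,500-gene tables — sizes
chosen so the whole suite completes on a laptop in well under a
minute while keeping every planted-effect check at a sample size where
the effect dominates its binomial noise.  `scripts/acceptance.py` uses
the same sizes.

## Known limitations

- The exact rank-sum enumeration switches to the normal approximation
  above ~20,000 combinations; borderline p-values near that switch are
  approximation-dependent.
- Betweenness on large graphs is exact (no sampling); the default
  2,000-node network takes seconds, but genome-scale graphs need
  hours.
- The generator's planted tissue-specific set is a single
  homogeneous class; real tissue-specificity is graded, so stringency
  scans on synthetic data flatten above the planted fold.
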