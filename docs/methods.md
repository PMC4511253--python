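# Methods

## Overview

`funlink` implements a three-stage procedure: (1) build one undirected,
raw-scored evidence network per data source; (2) calibrate each source's
scores into probabilities against a shared criterion — Gene Ontology
Biological Process (GO BP) term sharing — and fuse all sources with a
noisy-OR; (3) rank genes for a trait by a degree-of-association (DAG)
statistic over a reference gene set, with ROC/AUC characterization and
positive-predictive-value (PPV) candidate selection. Every stage is a pure
function over explicit in-memory containers; file I/O is TSV throughout.

## Component networks

* **Curated PPI** sources are consumed as pre-exported edge lists
  (`gene1 TAB gene2 TAB score`). Native database dump formats (PSI-MI TAB
  and kin) are deliberately out of scope; exporting to TSV is the contract.
* **Coexpression.** Experiments are combined into one consistent vector per
  gene: each gene row is z-scored within its experiment (population SD;
  only relative shape matters downstream) and rows are concatenated across
  experiments by gene id, with NaN blocks where a gene is absent or
  constant. Pearson correlation is computed over pairwise-complete samples
  (≥ `min_pairs` = 3 shared observations), and an edge is created iff
  **signed** r ≥ 0.7 — the threshold is on r, not |r|, so strong negative
  correlation yields no edge. The correlation doubles as the raw score.
* **Homology.** blastp hits (tabular outfmt 6) survive iff alignment length
  ≥ 50 % of the query length, percent identity ≥ 40 %, and e-value
  < 10⁻⁴; the raw score is −log₁₀(e-value), with e-value 0 clamped to
  10⁻¹⁸⁰ (score 180) to keep binning finite. outfmt 6 carries percent
  *identity*; where a similarity percentage is wanted instead, no standard
  tabular column exists, so identity is used. Reciprocal hits collapse to
  one edge keeping the larger score.
* **Shared domains.** Edge per protein pair with ≥ 1 common domain; the
  raw score is the number of shared domains.
* **Interologs.** A donor-organism edge (A, B, s) transfers to every target
  pair (a, b), a ≠ b, over the many-to-many ortholog groups of A and B,
  keeping the donor score s. Edges with an unmapped endpoint are skipped.
* **Annotation transfer.** Genes with *no* GO BP annotation receive the
  union of their orthologs' terms across donors; annotated genes are left
  untouched (a `merge_annotated` flag widens this to a union merge, off by
  default). Transfer never shrinks a term set.

Everywhere, duplicate edges within one source keep the **maximum** raw
score (idempotent, preserves the strongest evidence), self-edges are
discarded, and edges are stored once under the lexicographically sorted id
pair, which fixes iteration order — and hence float summation order — for
exact reproducibility.

## Calibration and integration

A source's score range is fitted on the edges whose both endpoints are
annotated: those are the only edges whose functional sharing is observable.
Scores below that fitted minimum can occur on unannotated-endpoint edges
and map to bin 0 with confidence 0 (outside the calibratable range); scores
at or above the maximum map to the top bin. The default bin count is 10; a
degenerate source (all scores equal) puts everything in bin 1.

Bin confidence is the sharing fraction with +1 smoothing, p = s/(m + 1) for
m edges of which s share a term, so p ∈ [0, m/(m+1)] is strictly below 1
and empty bins get 0. Sharing is "any common GO BP term": the per-function
index collapses to a per-(source, bin) confidence, which is how the
integrated confidences stay term-independent. Edges with an unannotated
endpoint are excluded from *estimating* p but still *receive* their bin's p
at integration time — otherwise most of a poorly annotated genome would be
unscorable.

Integration is a noisy-OR across the sources reporting each edge. It is
order-invariant, monotone (an extra source never lowers an edge), keeps
every r strictly in [0, 1), and reduces to the source's own bin confidence
for single-source edges. Provenance (the contributing source ids) is kept
per edge.

## Prioritization and evaluation

The reference subnet is the induced subgraph on the reference genes plus
their direct neighbors. Each gene i in scope gets sum_w = Σ r(i, j) over
reference neighbors j ≠ i, n_links = the count of such neighbors, and
DAG = sum_w × n_links. The link count P_ij is read as the 0/1 direct-edge
indicator (the natural reading for a simple graph; path-counting variants
were considered and rejected as speculative). Ranks are deterministic:
descending DAG, ties broken by gene id. Scoring scope defaults to the
subnet, matching the extraction step; `scope="all"` scores the whole
network, with zero scores retained.

Evaluation treats scored reference genes as positives and all other scored
genes as negatives. AUC is the midrank (Mann–Whitney) statistic; the ROC
polyline integrates to the same value by the trapezoid rule. A
leave-one-out mode rescoring each reference gene with itself withdrawn is
exposed (default on for evaluation); note that because the DAG sum already
excludes the i = j term, the recomputation is provably identical to the
plain score — it is kept as an explicit guard and verified by test rather
than assumed. PPV(t) is computed at every distinct score threshold, and the
selected threshold is the **lowest** score with PPV strictly > 0.5 — the
most permissive cut under which a selected gene is more likely than not a
true positive; candidates are the non-reference genes at or above it. For
very large universes a seeded negative-subsampling helper is provided.

## Synthetic benchmark

`simulate_benchmark` plants five 20-gene modules in a 500-gene universe.
Each of three sources emits a within-module pair with probability
p_within × reliability (defaults 0.3 × {0.9, 0.7, 0.5}) and any other pair
with p_between = 0.01. Raw scores are overlapping uniforms — U[0.5, 1] for
within-module edges, U[0, 0.7] for background — times a per-source scale
(1, 10, 100), so binning is informative but imperfect and the scales force
real calibration. Every gene gets one term from a 50-term background pool;
module members additionally carry their module's dedicated term with
probability 0.8. The reference set is a random half of module 1, the
held-out positives the other half, so end-to-end recovery is measured on
genes the pipeline never saw labelled. All randomness flows from one seed
through spawned NumPy generators.

The no-signal control sets p_within = p_between (0.02) with reliabilities
1.0, equalizing emission rates exactly. Score ranges and annotation
sharing keep their module structure there, so a faint residual association
between module membership and confidence remains and single-run recovery
AUC scatters around 0.5 (roughly 0.45–0.6 over seeds) rather than exactly
at it; the acceptance script averages five generator replicates to report
a stable value.

What the generator does *not* emulate: GO DAG structure (terms are flat
tokens), realistic expression noise or batch effects, genome-scale gene
counts, or annotation bias toward well-studied genes. Passing the
benchmark shows the machinery concentrates confidence on genuinely modular
structure under calibrated noise — not that any particular organism's
network is recovered.

`simulate_expression` uses a one-factor model (x = √ρ·f + √(1−ρ)·ε) so
within-block pairs have expected Pearson r = ρ exactly;
`simulate_blast_hits` constructs hits that pass all three homology filters
and decoys violating exactly one filter each, labelled so tests can assert
the filter boundary precisely.

## Numerical and design notes

* Scores are written with `repr` (shortest round-tripping decimal), so
  write→read is the identity on floats.
* The binning formula short-circuits S ≥ S_max to the top bin, which also
  guards the floor computation against overflow on pathologically narrow
  ranges.
* Problem sizes in tests (500-gene benchmarks, 100-graph oracle sweeps,
  500-replicate AUC nulls) were chosen to make the whole suite run in a few
  seconds while keeping binomial error bars far smaller than the asserted
  bands.
* A run's outputs embed parameters, seed and input digests as comment
  headers — never timestamps — so identical configurations produce
  byte-identical artifacts.

## Limitations

* Confidence calibration inherits every bias of the annotation corpus:
  sparsely annotated regions of the genome get their edge confidences from
  better-annotated edges in the same score bin.
* The DAG statistic only sees direct reference links; genes two steps from
  every reference gene score zero regardless of topology (diffusion-style
  propagation is out of scope).
* The published headline numbers of the original application (network size,
  genome coverage, specific AUCs and score thresholds) depend on 2012-era
  database snapshots and are not reconstructable from the method alone;
  this package reproduces the *method* and validates it on synthetic
  ground truth instead.
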