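# Methods

## Scope and data model

The pipeline's universal currency is a sparse cells × genes raw-count
matrix with per-cell sample and organ labels (`CellMatrix`). Gene
identity is by symbol; symbols differing in case are distinct genes.
All per-gene statistics are computed on the sparse structure (memory
proportional to non-zeros). Per-gene annotation supplies chromosome,
biotype (protein_coding / miRNA / other), a mitochondrial flag, exonic
length in bp, and a chrX-unique flag (on chrX with no chrY homolog);
which genome release defines the chrX-unique set is the user's choice,
expressed entirely through this table.

## Quality-control cascade

Stage order is fixed: minimum detected genes per cell → minimum cells
per sample → minimum coding/miRNA genes per cell → mitochondrial
fraction → per-sample detected-gene outliers → optional core-gene
restriction → optional rare-annotated-type filter. Conventions:

- A gene is *detected* in a cell iff its count is > 0 — the same
  convention the zero-rate statistic uses.
- Threshold wording is honoured literally: "fewer than 200", "less than
  7" and "fewer than 3" remove strictly below, so retention is ≥ the
  threshold; "exceeding 15%" and "exceeding 3 standard deviations"
  remove strictly above, so retention is ≤ the threshold.
- The sample-level census runs after cell-level removal, so "cells per
  sample" counts survivors.
- The outlier rule's population is each sample's own cells; the mean and
  SD are those of the sample's detected-gene counts (population SD,
  ddof 0 — the rule is a within-population trim, not an estimate of a
  larger population), and only the upper tail is trimmed. Samples with
  fewer than two cells skip the stage.
- Cells with zero total counts are removed at the mitochondrial stage
  (their fraction is undefined; they carry no information either way).
- The core gene list has no intrinsic definition here and defaults to
  "no restriction"; when supplied, the gene axis becomes the
  intersection in matrix order, and an empty intersection is an error.

Defaults: 200 genes/cell, 3 cells/sample, 7 coding-or-miRNA genes/cell,
15% mitochondrial fraction, 3 SD, 20 cells/annotated type. The cascade
is idempotent on its own output and the `QCReport` attrition chain is
validated (before[k+1] = before[k] − removed[k]).

The 200-gene rule is applied per cell, and the per-sample floor is 3
cells (where sources disagree between 3 and 4, the procedural
description wins); both are configuration fields.

## Pseudo-bulk and FPKM

Pseudo-bulk sums raw counts over a grouping (sample, organ, or explicit
cluster labels); total mass is conserved exactly. FPKM uses the standard
definition FPKM = 10⁹ · c / (L · C) with L the user-supplied exonic
length (bp) and C the group's total counts; groups with zero depth get
an all-zero row plus a warning rather than NaNs. The per-gene CV across
groups uses the sample SD (ddof 1), conventional for a
coefficient of variation across a small number of samples; genes with
zero mean receive a +inf sentinel so they sort last in any stability
ranking. Pseudo-cells pool a seeded random partition of each cluster
into groups of 100 cells; a remainder pool is kept iff it holds at least
half the pool size (the remainder rule is a package decision — dropping
all remainders wastes up to pool_size − 1 cells per cluster, keeping all
of them creates arbitrarily shallow profiles).

## Sex inference

Both ratios are computed on per-sample pseudo-bulk FPKM (the same unit
the downstream correction tool consumes), with sums over annotation-
defined gene sets. Zero denominators define a 0 ratio: a corpus with no
chrY output should classify female, not error. The classifier is a total
function on [0, ∞)² via fixed branch precedence — male first, then
(human) mixed before female, (mouse) female before mixed, then unknown —
and "between a and b" is the open interval between the two printed
constants; the inclusive endpoints belong to the ≥/≤ branches that cite
them, so every boundary point has exactly one label (e.g. mouse
Y-Ratio = 0.000065 is male). NaN ratios yield "unknown" with a warning.

Thresholds ship as calibrated presets (human male_y 0.001188,
male_x 0.000070, band_y 0.000106, female_x_min 0.000001; mouse
male_y 0.000065, male_x 0.000008, female_x 0.000555, low_y 0.000004) and
are overridable. `SexClassifier.fit` offers a simple re-calibration:
grid search of the primary male threshold (and the coupled band floor)
over observed ratio quantiles, maximizing accuracy against trusted
labels — intended for labeled sex-specific-organ samples; the original
refinement procedure is not fully specified, so this helper is
deliberately minimal.

## Stable-expression genes

Zero-rate is computed over all post-QC cells of the corpus; the CV over
per-sample pseudo-bulk FPKM groups. Both statistics are ranked
ascending, +inf CV last, every tie broken lexicographically by symbol;
the combined score is the *sum of the two ranks*, re-ranked with the
same tie-break. Sum-of-ranks is the simplest symmetric combination that
is deterministic, permutation-invariant and monotone in both inputs; the
exact combination rule is otherwise an open choice. The SEG set size
equals the housekeeping reference size after dropping reference symbols
absent from the matrix (with a warning). The headline overlap fractions
reported for atlas-scale corpora (~50M cells per species) are not
reproducible at desk scale; the package's tests instead assert exact
recovery of planted stable genes on synthetic corpora.

## Organ-specific genes

The zero-rate table is computed per organ over post-QC cells; organs
with fewer than 50 cells are excluded (a floor added to avoid degenerate
zero-rates from tiny organs — not part of the published rule,
configurable). A gene is expressed in an organ iff its zero-rate there
is ≤ 0.90; OSGs are genes expressed in 1..2 organs, the focal organ
counted among the two, and are assigned to every organ where expressed.
Genes expressed nowhere are not OSGs (vacuous specificity excluded).

## Gene-set evaluation

Per repeat, a shared random subsample of cells is drawn; per gene set,
counts are depth-normalized (cell totals over all genes scaled to the
corpus median total), log1p-transformed, embedded into the top
min(20, n_features) principal components, clustered with k-means
(k-means++ seeding, best of 10 starts), and scored with the
Calinski-Harabasz index and silhouette in the embedding. The common
embedding dimension is essential: k-means can carve compact clusters out
of pure noise far more easily in 20 dimensions than in 1,000, so indices
computed in each set's raw feature space reward small gene sets for
their dimension, not their information. CH uses the standard
[B/(k−1)]/[W/(n−k)] with a +inf sentinel when every cluster has zero
scatter; silhouette scores singleton-cluster points 0. Both indices are
checked against independent brute-force direct-formula oracles to 1e-9
relative tolerance in the tests. Defaults: 20 repeats, subsample 500
cells, Euclidean distance throughout. k-means is used as the
self-contained, seedable clustering method; graph-based clustering is
out of scope.

Accuracy, recall and precision follow the usual confusion-matrix
definitions; a metric with a zero denominator is reported as absent
(None), never propagated as NaN.

## AI-ready encoding

Gene medians are computed over strictly positive counts only — including
zeros would collapse most medians to 0 and break the normalization.
Per cell, expressed genes are sorted by count/median descending, ties by
symbol ascending, zero-count genes excluded; truncation is an optional
parameter (default none — token budgets belong to the consumer).
Vocabulary ids are frequency-ordered, then symbol-ordered, so exports
are byte-deterministic.

## Synthetic corpus

The generator emulates: zero-inflated counts (shifted negative binomial:
1 + Poisson mixed over a Gamma rate, applied to a per-cell detected gene
set), cell-type cluster structure (per-(type, gene) lognormal mean
factors over the whole background, σ = 1.3 — signal in count magnitudes,
spread across the transcriptome), per-sample cell-type proportions
(Dirichlet α = 5, so pseudo-bulk varies across samples), sex-dependent
chrY output (males detect SRY plus ~70% of chrY genes per cell; females
none), planted stable genes (always detected, mean 20, type-uniform),
planted organ-specific genes (detected in 60% of own-organ cells, absent
elsewhere), a housekeeping-like reference list (half planted stable
genes, half type-uniform but dropout-prone background genes — what a
bulk assay would nominate), mitochondrial counts scaled to a target
fraction (clean component ~N(0.05, 0.02) clipped; violators uniform in
0.20–0.35), and a violation roster with low-complexity cells, a 2-cell
sample, near-zero-coding cells, high-mito cells and detected-gene
outliers.

Detection uses a *bounded-spread* scheme: each clean cell detects a
uniformly sampled background set whose size is uniform within ±5% of
n_background · (1 − dropout_rate), plus fixed-size draws from the
special gene groups. Marginally the mean per-gene zero-rate equals the
configured dropout rate (0.65 by default; the ~80%-zeros regime of real
corpora is reachable by raising it), but the spread of detected-gene
counts is bounded, so no clean cell can breach the mean + 3·SD outlier
cut under any draw — which is what makes the planted violation roster
recoverable exactly and the QC cascade idempotent. Features of real data
deliberately not emulated: batch effects, ambient RNA, doublets,
gene-gene correlation beyond cell-type structure, heavy-tailed library
sizes. Passing tests therefore demonstrate correctness of the decision
rules and statistics, not robustness to those artefacts.

Default conditions: 20 samples × 100 cells over 4 organs plus one
2-cell sample (2,002 cells), 1,000 genes (20 stable, 10 OSGs per organ,
5 mitochondrial, SRY + 10 chrY, 30 chrX of which 20 chrX-unique,
894 background), 4 cell types, 5 + 2 + 3 + 5 + 5 planted violations.
These sizes keep every end-to-end check fast while leaving wide margins
between planted structure and noise; all are configuration fields.

## Known limitations

- The sex classifier presets are the published constants; they are not
  re-derivable from synthetic data alone, and the `fit` re-calibration
  explores only the primary male threshold.
- FPKM requires exonic lengths for every gene in the matrix; there is no
  fallback length.
- OSG calling treats organs symmetrically; it does not model nested or
  overlapping tissues.
- The evaluation module compares gene sets on one corpus at a time; no
  statistical test between score distributions is provided.
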