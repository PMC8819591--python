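# Methods

This note documents the models, defaults and numerical conventions of
`raacdip`, and what the synthetic benchmark does and does not show.

## Sequence canonicalization

Inputs are uppercased; alignment gaps (`-`, `.`) and one terminal `*`
are stripped. Ambiguity codes map to their chemically nearest standard
residue (B→D, Z→E, U→C, J→L, O→K); X and any other character are
removed with a logged warning. Every downstream descriptor is defined
only over the 20 standard residues, so unresolvable positions cannot be
represented; dropping them is deterministic and preserves all usable
counts. Class labels come from per-file flags or a 2-column id/label
TSV — never from FASTA headers, which vary too much across sources to
parse reliably.

## Reduction schemes

A `ReductionScheme` is an ordered partition of the 20 residues with one
representative letter per cluster (disjoint, covering, distinct
representatives, each representative a member of its cluster). The
dash-delimited spec string takes the first letter of each token as
representative unless overridden with `MEMBERS:REP`. The built-in
5-cluster scheme groups polar/small (G), aromatic (F), aliphatic (V)
residues plus the singletons C and W; reduction is a per-residue table
lookup, hence length-preserving and idempotent on reduced strings. No
library of alternative published schemes is bundled — the toolkit's
results use one scheme, and user schemes are a one-string input.

## Gapped dipeptides

For gap λ, the pair (a, b) is counted at every position i with
seq[i] = a and seq[i+λ+1] = b; a length-L sequence yields exactly
max(0, L−λ−1) pairs. Frequencies divide by that total; sequences with
L ≤ λ+1 have no pairs and all frequencies are defined as 0 (a
degenerate case, not an error). Canonical feature names put the λ
asterisks between the letters (`F*C`); the trailing-star style (`FC*`)
is accepted as an alias because it is common in the applied literature.
The matrix column order is fixed — per gap, alphabet² row-major, then
AC, then CC — so feature indices are reproducible across runs.

Raw counts are exposed alongside frequencies: the two-feature
interpretability analysis works on counts, because integer count
thresholds ("value ≤ 5") are how such scatter plots are read, while
the classifiers consume length-normalized frequencies.

## ACC descriptors

Auto covariance AC(j, g) and cross covariance CC(j, k, g) are lagged
covariances of per-residue property profiles, divided by L−g, for lags
g = 1..maxlag and ordered property pairs. Defaults: three classic
properties — Kyte–Doolittle hydrophobicity, Hopp–Woods hydrophilicity,
side-chain mass — each standardized to mean 0, variance 1 over the 20
residues (ddof = 0), with maxlag = 2. That yields 3·2 + 3·2·2 = 18
features, completing the 93-dimensional default descriptor. The
property table is data-driven (any TSV of 20 rows × p columns), so the
triple is a replaceable default, chosen as the standard hydropathy /
hydrophilicity / bulk trio rather than a fitted quantity. ACC is
computed on the original, unreduced sequence: the properties are
per-residue quantities and reduction would discard exactly the
within-cluster variation ACC is meant to capture. Sequences must be
longer than maxlag; shorter input is an error rather than a silent
zero.

## MRMD ranking

Relevance is |Pearson correlation| between a feature column and the 0/1
class vector (0 for zero-variance columns). Distance is the mean
pairwise distance between standardized feature columns, with Euclidean,
cosine and generalized-Tanimoto (x·y / (|x|² + |y|² − x·y)) metrics;
standardization first makes dipeptide frequencies and ACC values
commensurable. The combined score is w_r·relevance + w_d·(distance /
max distance) with default weights (1, 1): the raw Euclidean distance
between standardized n-sample columns grows like √(2n) and would
otherwise dominate the bounded relevance term, so the distance term is
normalized to [0, 1] across features. Ranking sorts by descending score
with ties broken by original column index (deterministic).

Subset selection evaluates nested ranking prefixes (top-1 … top-k_max,
default k_max = 30) with a cross-validated accuracy callback and keeps
the smallest prefix within `tolerance` (default 0.005) of the best
prefix accuracy — the smallest model whose accuracy is
indistinguishable from the best at roughly one sample of the benchmark.

## Trees, forest, cross-validation

The tree is C4.5-family: binary numeric splits at midpoints of
consecutive distinct sorted values, chosen by maximum gain ratio
(information gain / split information); ties resolve to the earlier
feature, then the lower threshold. Zero-gain splits are admissible —
necessary for parity-structured data (XOR), where no single split is
informative but depth-2 trees separate perfectly; termination is
guaranteed because every split strictly shrinks the node, and growth
also stops on purity, min_leaf (default 2) or max_depth. Leaves predict
the majority class with ties to the negative class. No post-pruning is
applied; min_leaf is the only regularizer, so the tree family is
"unpruned C4.5-style" rather than a bit-compatible clone of any
particular toolkit.

The forest bags these trees on bootstrap resamples with per-split
feature subsampling (mtry = round(√p)), majority vote with ties to
negative, and out-of-bag accuracy tracking; a single numpy generator
seeded once makes it fully reproducible.

Cross-validation is stratified: within each class, indices are shuffled
by the seeded generator and split into k near-equal chunks, with
chunk-to-fold assignment rotated per class to balance fold sizes. Each
sample is predicted exactly once; metrics come from pooled confusion
counts, with any 0/0 ratio defined as 0 with a warning.

## Greedy minimization

Backward elimination removes, at each step, the feature whose removal
maximizes the evaluator's accuracy (ties: the lower-MRMD-score feature,
then the later column), stopping when the best post-removal accuracy
would fall more than `tolerance` below the best seen, or at
`min_features`. The pipeline default is tolerance = ∞ with
min_features = 2, i.e. run all the way down to a pair — the
minimal-model regime the toolkit is built to study. Greedy single-step
elimination is a deterministic formalization of manual
"drop-one-feature" model shrinking; forward selection is provided as a
cross-check. No optimality claim is made beyond the greedy horizon.

## Two-feature threshold rules

`fit_rule` exhaustively searches integer threshold pairs over the
observed count ranges (plus a sentinel below each minimum so pure
single-axis rules are representable). For each pair, the four quadrants
of the count plane take their training-majority class — optimal for
that pair — making the family closed under class complement: swapping
the classes returns the same thresholds with inverted quadrant labels.
Tied or empty quadrants are labeled positive on the high-x side and
negative otherwise, matching the convention that the positive class
lives at high x. Threshold ties prefer smaller values. The search is
O(|x-values| · |y-values|) with vectorized counting, exact by
construction.

## The synthetic benchmark

The generator emulates the data shape of a two-class protein study:
109 positives vs 119 negatives, lengths uniform on 100–500 residues,
i.i.d. background residues drawn from the database-average amino-acid
composition of curated protein databases (C ≈ 1.4%, W ≈ 1.1%,
L ≈ 9.7%, …). Positives receive, with probability 0.98, the conserved
motif `ISNVTREDAGTYTC` written at 1 + Poisson(2) non-overlapping random
positions — multi-domain proteins carry one copy of a domain motif per
domain, and each copy contributes exactly one F-gap-C (λ=1) count.
Negatives receive a Poisson number of decoy trigrams (G-cluster letter,
background letter, C) calibrated to enrich their G-gap-C (λ=1) rate
1.5× over its background expectation. A manifest records every motif
insertion, giving an exact ground truth for scanning and recovery
tests.

The realistic background matters: under it, background F-gap-C pairs
are rare (≈0.3 per sequence), so motif copies dominate the positive
class's F*C counts and the planted marker is recoverable by the full
pipeline — the benchmark's defining property, verified by the
end-to-end tests (final pair contains `F*C`; 10-fold CV accuracy of
the two-feature tree ≥ 0.85; permuted labels fall to chance). Under a
uniform background, cysteine would be 3.6× more frequent than in real
proteins and the same signal drowns in composition noise.

What the benchmark does **not** emulate: real domain architecture
(ordered V/C domains, disulfide patterns), residue autocorrelation and
low-complexity regions, homology between samples, motif degeneracy
(every inserted copy is exact), and class-conditional length
distributions. Passing the recovery tests therefore demonstrates the
pipeline's correctness and sensitivity under its stated statistical
assumptions, not performance on curated immunoglobulin data; accuracy
figures on the benchmark are properties of the generator, comparable
only to themselves.

## Problem sizes and determinism

Default analysis sizes — 228 sequences, 93 features, k_max 30, 10-fold
CV — complete in well under a minute on one core; the oracle-equivalence
tests use ~1,000 random small instances per kernel, sized so the whole
suite stays interactive. One integer seed per entry point drives every
stochastic component (generation, fold shuffles, bootstraps,
permutation controls); per-stage seeds are derived from it with a
seeded generator, so artifacts are bit-reproducible from (inputs,
seed).

## Known limitations

- MRMD weighting and metric follow the documented defaults; no claim
  is made that they match any particular historical implementation.
- The tree is unpruned; on very noisy data its CV accuracy is
  pessimistic relative to pruned C4.5 variants.
- Hamming-tolerant motif scanning handles substitutions only, not
  indels.
- `backward_eliminate` cost is quadratic in the starting feature count
  times one cross-validation per candidate; it is intended for the
  MRMD-selected subset (tens of features), not the full matrix.
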