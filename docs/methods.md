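# Methods

## Event model and coordinate conventions

An alternative 5′ donor event is specified by three 1-based genomic
coordinates on the host gene's strand: `sds1` and `sds2`, the first intronic
base under the upstream (exclusion) and downstream (inclusion) donor, and
`sas`, the last intronic base at the shared acceptor. On the transcribed
strand `sds2` lies strictly downstream of `sds1` and the acceptor downstream
of both; on minus-strand genes this means genomically decreasing
coordinates, and the donor-side boundary of a junction record is its
`intron_end`. The internal convention is the STAR `SJ.out.tab` dialect
(1-based, intron-inclusive ends); the generic table reader converts 0-based
half-open (BED-style) starts by adding 1. BED/bedGraph outputs are 0-based
half-open.

The packaged GN[N/S]K event fixture preserves the biology of the human *KIT*
event — plus strand, two GT donors 12 nt (four codons) apart — but its
coordinates are synthetic placeholders inside the *KIT* locus window, not a
genome-validated annotation; analyses of real alignments should pass the
event coordinates for their genome build.

Junction counting defaults to uniquely mapping reads (`SJ.out.tab` column 7)
with an opt-in `unique_plus_multi` mode, since junction tables produced
under permissive multimapping settings do not record which count fed
downstream summaries. Records whose coordinates are malformed are skipped
with a warning; records on other chromosomes or with a mismatched acceptor
are classified OTHER, never errors.

## In-ex ratio

`(inclusion − exclusion)/(inclusion + exclusion)`, in [−1, 1]; NaN (never 0)
when both counts are zero — such samples carry no information about donor
choice and are removed by the ≥ 3-read filter anyway. The statistic is
antisymmetric under swapping the counts and invariant under scaling both, and
round-trips bit-exactly through the per-sample TSV (ratios are written with
full `repr` precision).

## Cohort filters and distribution comparison

Samples enter the cohort when target-gene TPM ≥ 1 **and**
inclusion + exclusion ≥ 3, both thresholds inclusive. The CNS flag derives
from the tissue category via a packaged lookup (brain, forebrain, midbrain,
hindbrain, spinal cord, neural tube, cerebellum, cerebral cortex, …),
overridable per call — category nomenclature varies between metadata
sources.

Tissue distributions are compared on the **raw per-sample ratios**;
histograms (unit-area, bin width 0.1 over [−1, 1]) are presentation only.
The p-Wasserstein distance is computed exactly from the merged breakpoints of
the two empirical quantile functions; for p = 1 and equal sizes this is the
mean absolute difference of sorted values. The implementation supports
general p ≥ 1 and is validated against both `scipy.stats.wasserstein_distance`
and a transport-LP oracle.

Complete-linkage agglomerative clustering is implemented in-package rather
than via `scipy.cluster.hierarchy` because the dendrogram must be
deterministic under ties: among minimal-distance pairs the lexicographically
smallest label pair merges first. Merge heights are cross-checked against
scipy in the tests. The dendrogram serializes to an ultrametric Newick
string (branch length = half the height difference, so leaf depths equal
half the merge height).

## Exact Wilcoxon rank-sum and effect size

The two-sample contrast uses midranks for ties. In exact mode the null
distribution of the first sample's rank sum is enumerated with the shift
algorithm over doubled midranks (doubling makes tied midranks integral), a
dynamic program over (number of chosen ranks, rank sum) counting all
C(N, n_x) equally likely subsets in double precision. The two-sided p-value
is the central one, `min(1, 2·min(P(S ≤ s), P(S ≥ s)))`. The standardized
statistic uses the tie-corrected null moments

    E[S] = n_x (N+1)/2,
    Var[S] = n_x n_y / (N (N−1)) · (Σ r_i² − N ((N+1)/2)²),

and the effect size is r = |Z|/√N. `auto` mode (the default) switches to the
tie-corrected normal approximation (no continuity correction) above N = 200
pooled observations, where the exact enumeration stops being worth its
memory; the p-values of interest at that scale are far below the resolution
at which the two methods differ. With all pooled values identical the test
degenerates to p = 1, r = 0.

Because r is rank-based it is invariant under monotone transformation of the
pooled data; this and the agreement of exact p with full subset enumeration
(N ≤ 12, with ties) are property-tested.

## Correlation ranking and pre-ranked GSEA

Per-gene Pearson correlation with the in-ex ratio is computed vectorized
over a sample × gene TPM matrix (≥ 3 overlapping samples required);
zero-variance genes score 0 and are flagged rather than dropped, keeping the
ranked universe equal to the matrix columns. Score ties are broken by gene
id so the ranking is deterministic. The full ranked list is used by default;
an optional top/bottom-k truncation (`RankedGeneList.truncate`) is exposed
for workflows that restrict to the extreme tails, since published
descriptions of such pipelines often leave the cutoff unstated.

The enrichment score is the weighted Kolmogorov–Smirnov running sum
(weight p = 1): +|score|ᵖ/Σ_members|score|ᵖ at member positions,
−1/(N − N_members) elsewhere; ES is the extremum of largest magnitude. With
weight 0 this is the classic KS statistic on ranks (tested). Sets are
filtered to 20–500 members *within the ranked universe*, inclusive.

The permutation scheme is gene-label permutation — random member sets of the
same effective size — because only a ranked list enters pre-ranked GSEA. One
null of `n_perm` (default 1000) permutation ES values is drawn per distinct
set size, derived deterministically from the user seed (default 1111), so
results are bitwise reproducible and independent of set iteration order.
NES = ES / mean(|ES_perm| of the same sign), the original GSEA convention.
The empirical p-value is the +1-smoothed magnitude tail over **all**
permutations, `(1 + #{|ES_perm| ≥ |ES|})/(1 + n_perm)`: this estimator is
exactly uniform under the null (observed and permuted ES are exchangeable)
and attains the floor 1/(n_perm + 1) for a maximally enriched set, whereas a
same-sign-only denominator can neither reach that floor nor stay uniform.
BH adjustment runs across sets; `p_adjusted < 0.01` flags significance.

## YCAY cluster scoring

YCAY (Y ∈ {C, U}) sites are matched greedily left-to-right without overlap
(search resumes at match end), case-insensitively, with T ≡ U; characters
outside {A, C, G, T, U, N} raise an error naming the position. Within each
45-nt window (stride 1 nt) the inter-motif gaps g (bases between motif end
and next motif start, so "≤ 2" means 0–2 intervening bases) drive the score:

* gaps ≥ 7 separate clusters — an isolated motif contributes 0, and a motif
  beyond a ≥ 7 gap can still anchor the next group;
* within a cluster, motifs group greedily left-to-right into disjoint
  groups: triples score 8 (both gaps ≤ 2) or 4 (one ≤ 2, one 3–6);
  remaining pairs score 2 (gap ≤ 2) or 1 (gap 3–6).

A triple with gaps (3–6, 3–6) is absent from the published pattern table; it
is scored as its leading pair (1), continuing from the third motif, and the
case is logged at DEBUG. Group disjointness matters: scoring a tight
triple's trailing pair again would give 10 where the published table says 8.
The per-window raw total is log₁₀-transformed; raw 0 maps to log 0 (not −∞)
to keep tracks plottable, and the raw field disambiguates raw = 1 windows.
Raw ≥ 4 ⇔ log ≥ 0.602, so the 0.6 display threshold separates conserved
triple-motif clusters from at-most-two-motif windows. Window scores are
stored at the window start; positional pooling is left to presentation.
Scanning is strand-explicit: the provided (sense) string is scanned as-is.

GU-rich stretches are maximal runs of ≥ 4 consecutive G/U.

## Synthetic data: what it emulates and what it does not

Defaults are the stock study-like conditions used throughout the tests: two
CNS tissues at inclusion probability 0.7 and five non-CNS tissues at 0.2
(50 samples per class), junction depth negative-binomial with mean 100 and
dispersion 5 (overdispersed like real junction coverage; dispersion → ∞
recovers Poisson), target-gene TPM ~ N(30, 10) clipped at 0, and a
200-gene panel (30 positive-slope "CNS-like" genes, 30 negative-slope, 140
null; TPM = baseline + slope · inex + Gaussian noise, negative draws clipped
with a logged count). Sequence plans plant a tight triple (expected raw 8),
a mixed triple (4), a tight pair (2) and one 6-nt GU run on a background
drawn from {A, C, G} with rejection rules that make it provably YCAY-free
and GU-run-free; planted elements are padded with forced `AA` so no motif
spans an element/background boundary, and truth tables are derived from the
pattern table independently of the scanner.

The generator reproduces the *statistical* structure the method assumes —
binomial donor choice at fixed per-tissue probability, linear
expression-ratio coupling, isolated motif clusters. It does **not** emulate
mapping bias, overdispersion of donor choice within a tissue, library-size
effects on TPM, correlated gene modules, or motif occurrences embedded in
realistic sequence composition. Passing tests therefore demonstrate
correctness of the computations and recoverability of planted structure, not
performance on real tissue atlases.

All randomness flows from a single integer seed (expression and sequence
streams are derived sub-seeds), and repeated runs are byte-identical.

## Problem sizes

The test suite and acceptance script run at desk scale: cohorts of 100
samples (depth 100), 500 transport-LP comparisons at ≤ 6 points per side,
full rank-sum enumeration at N ≤ 12, 100-seed parameter-recovery sweeps,
1000-window motif-scanner/oracle comparisons and GSEA with 1000
permutations over a 200-gene universe — sizes chosen so the planted effects
are comfortably detectable while the whole suite completes in a few minutes
on one CPU.

## Known limitations

* The event must be user-specified; the package does not discover
  alternative-donor events de novo.
* Exact Wilcoxon memory grows as O(n_x · N²) in the doubled-rank DP; the
  N = 200 auto-switch keeps this modest.
* GSEA p-values are permutation-based with a 1/(n_perm + 1) floor; there is
  no multilevel refinement of very small p-values.
* The CNS category lookup is a heuristic over tissue-category names; supply
  an explicit `is_cns` column or a custom category set when metadata uses a
  different nomenclature.
* Real-data acceptance checks depend on a user-supplied per-sample table
  (`data/sample_info.tsv`); they report their absence as a failure rather
  than passing vacuously.
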