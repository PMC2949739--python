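# Methods

This note records the statistical models, conventions and numerical choices
behind `hapld`, and what the synthetic-data calibration does and does not
demonstrate.

## Input model and site filter

The unit of analysis is a gap-aligned multi-FASTA of phased haplotypes for
one gene in one species. Coordinates are 0-based aligned columns and all
distances are aligned bp, so alignment insertions count toward distance.
Columns are classified once and the classification drives everything
downstream:

- *monomorphic* — fewer than two states over {A,C,G,T};
- *usable_biallelic* — exactly two nucleotide states, no gap, no N in any
  haplotype: only these enter LD analysis;
- *excluded_gap*, *excluded_ambiguous*, *excluded_multiallelic* otherwise.

S (segregating sites) counts every column with ≥ 2 nucleotide states,
including excluded ones, so S ≥ k (usable sites). N is treated like a gap:
it excludes the column from LD rather than being imputed. A
`drop_singletons` flag additionally removes usable sites whose minor allele
occurs once; it is off by default so pair counts reflect all usable sites.

## Diversity

π is the mean over all C(n,2) sequence pairs of (differences ÷ compared
columns), comparing a column only when both sequences carry an unambiguous
nucleotide; no multiple-hit correction is applied, matching the uncorrected
"Pi" convention of standard polymorphism software. Synonymous and
non-synonymous diversity follow Nei & Gojobori (1986): per-codon synonymous
site counts with stop-creating changes excluded from both numerator and
denominator, differences counted along all orderings of the differing
codon positions with equal weights, pathways through stop codons excluded
(all pathways used as a fallback when every one crosses a stop), and codons
containing any gap/N in either sequence of a pair skipped entirely. p_s and
p_n are per-pair ratios averaged over pairs; because the synonymous-site
denominator is small, π_s may legitimately exceed π_total.

## Pairwise LD and significance

For two usable sites the 2×2 haplotype table labels "A"/"B" as the
alphabetically first state at each site (deterministic; r² and D′ are
invariant to the labeling, D changes sign only). D = p_AB − p_A p_B,
D′ = |D|/D_max with D_max = min(p_A p_b, p_a p_B) for D > 0 and
min(p_A p_B, p_a p_b) otherwise, r = D/√(p_A p_a p_B p_b), r² = r².
Significance uses the two-tailed Fisher exact test under the
probability-mass convention (sum of margin-fixed tables with point
probability ≤ the observed one); a tail-doubling variant sits behind a
flag. The Bonferroni family is the k(k−1)/2 tests within one gene ×
species dataset, threshold α/n_pairs with α = 0.05 by default. The r²
standard deviation uses ddof = 1.

Haploblocks are maximal runs of consecutive usable sites whose within-run
pairwise r² all reach a threshold (default 0.8), reported with spans in bp.
This is a deliberate simplification of confidence-interval-based block
callers: it operates directly on the r² statistic the rest of the pipeline
uses.

## LD decay

Parametric: the Hill–Weir equilibrium approximation of E[r²] at scaled
recombination distance C = ρ·d with a sample-size adjustment (see README
for the expression). Its C=0 value (≈ 0.46–0.48 for typical n) is a hard
ceiling, and its large-C limit is the 1/n sampling floor, not zero.
ρ (per bp) is estimated by least squares: a 61-point log-grid scan over
ρ ∈ [1e−6, 1] seeds a Levenberg–Marquardt refinement in log ρ. Estimates
pinned at the grid boundary are reported as `boundary` and optimizer
failures as `failed`, both with `converged=False` and a reason — datasets
whose mean r² exceeds the ceiling cannot be fitted and this is a valid,
returned outcome. The Sved form 1/(1+C) is available via
`model="sved"`.

The pairs entering the parametric fit are restricted to sites with minor
allele frequency ≥ 0.1 (minor count ≥ ⌈0.1·n⌉). Rare alleles bound r² far
below 1 at any distance, which otherwise inflates ρ̂ several-fold; the MAF
restriction is the standard practice for decay fitting. Pair counts,
significance tables and the nonparametric fit always use the unfiltered
usable pairs.

Nonparametric: a penalized regression on a cubic B-spline basis with
uniform, unclamped knots over the observed distance range and a
second-order difference penalty on the coefficients (P-spline). Uniform
knots put straight lines exactly in the penalty null space, so a linear
trend is reproduced without shrinkage and the infinite-penalty limit equals
ordinary linear regression. The basis dimension is min(10, max(4, distinct
distances − 1)) — the lower bound of 4 is what a cubic basis needs. The
smoothing parameter minimizes the GCV score n·RSS/(n − edf)² over a
49-point log-spaced grid scaled by tr(BᵀB)/tr(P). Tied distances are kept
as separate observations, the curve is never evaluated outside
[min d, max d], and ≥ 4 distinct distances are required.

`distance_at_threshold` reports the smallest grid distance where a fitted
curve first drops below a threshold (e.g. r² = 0.3), with an explicit
not-reached status when it never does within the data range.

## Segment comparison

Each alignment is cut into 4 consecutive segments of near-equal length
(remainder columns to the leftmost segments); a pair contributes to a
segment only if both sites lie inside it, and a segment with no
within-segment pair is NA (dropped, never imputed). Segment means pooled
by gene (up to 4 × 7 = 28 values) or by species (up to 4 × 4 = 16) are
compared pairwise with the two-sided Wilcoxon rank-sum test: exact
enumeration when the combined sample is ≤ 20 with no ties, otherwise the
normal approximation with tie and continuity correction, with the method
used reported. A coarser variant takes one whole-sequence mean r² per
dataset. The unpaired test is used because the pooled lists have unequal,
NA-trimmed compositions. No multiple-testing correction is applied across
group pairs by default. Treating the 4 segment means as independent is an
approximation — pairs near segment boundaries share genealogy — and the
procedure is implemented as specified without endorsing independence.

## Synthetic data

The generator implements Hudson's back-in-time coalescent with
recombination: time in units of 2N generations, pairwise coalescence rate
1, per-lineage recombination rate (ρ/2) × ancestral span, breakpoints
uniform; material that reaches its MRCA is dropped so the walk terminates.
Mutations fall on the resulting edges at rate θ/2 per bp per unit branch
length. Under the default infinite-sites model each mutation occupies a
fresh column (ancestral A, derived C), so E[S] = θL·Σ_{i<n} 1/i and
E[π] = θ hold exactly; a finite-sites mode (recurrent hits on a random
background, producing occasional multiallelic columns) and a per-cell gap
injection rate exist to exercise the exclusion filters, and an exponential
growth mode rescales the coalescence intensity by e^{βt} backward in time
(its tested signature is the singleton-inflated frequency spectrum).

The default study design mirrors the 4-gene × 7-taxon field layout:
aligned lengths 1108/1238/834/735 bp, per-gene θ equal to the observed
per-site diversity of each fragment (0.0253/0.0247/0.0099/0.0159),
haplotype counts twice the number of individuals (10–32), and ρ = 0.02/bp —
chosen once so the simulated decay matches the reported regime (expected
r² crossing 0.3 within ~100–150 bp and most pairs below 0.3). One cell
(REL2 × *An. bwambae*) is simulated with θ = 0 so the degenerate
"0 pairs / NA" path is always exercised. What passing the simulated-study
checks shows: the pipeline's statistics, filters and fits behave correctly
under neutral, panmictic, constant-size (or simply growing) conditions.
What it does not show: behavior under selection, population structure,
gene conversion, chromosomal inversions, sequencing/phasing error or
alignment ambiguity, none of which the generator emulates.

## Problem sizes used in the automated checks

The test suite and the acceptance script run the full 28-dataset simulated
study end to end, 200 replicates for the Watterson/π calibration
(n=10, L=1000, θ=0.01), a 3 × 20-replicate ρ-recovery ladder
(0.005/0.02/0.08 at n=32, L=1000, θ=0.01, median ρ̂ monotone and the middle
level recovered within 50%), 2000 null Wilcoxon comparisons for the
empirical test size, and 10,000 random 2×2 tables against the 0/1
correlation oracle plus full hypergeometric enumeration for tables of
n ≤ 32. These sizes give stable medians and 3–4 standard-error margins for
the stochastic checks while keeping a full run in the low minutes on one
core.

## Known limitations

- ρ̂ from the Hill–Weir fit is a method-of-moments-style estimate with
  substantial replicate-to-replicate spread; it is reported with
  convergence status, not with a confidence interval.
- The exact Fisher and Wilcoxon conventions (probability-mass two-tailing;
  exact-vs-asymptotic switch at combined n = 20) are stated choices;
  other software's counts can differ at the margin.
- The haploblock rule is r²-threshold-based, not the D′ confidence-interval
  rule of classical block callers.
- Synonymous-site classification assumes in-frame, stop-free coding
  annotations; frame shifts within a CDS interval are not modeled beyond
  the per-interval frame offset.
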