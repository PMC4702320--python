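# Methods

## Model

A donor-site candidate is a GT di-nucleotide with `exon_flank` bases
upstream and `intron_flank` bases downstream (default −3 ~ +6, i.e. a
9 bp modeled core; the GT itself is excised because it is invariant and
carries no information). Two class-conditional tables are estimated from
aligned training motifs, one from true sites (TSS), one from GT-bearing
non-sites (FSS):

    p(s_i | t_j) = (n_ij(s,t) + α) / (n_j(t) + 4α),   i ≠ j,

where n_j(t) and n_ij(s,t) are single and joint base counts and α is a
Laplace-style pseudocount. The observed indicator of the motif's own base
at position i is 1 (and 0 for the three other bases), so the absolute
error of predicting position i from all other positions sums to

    SAE_i = 2 Σ_{j≠i} (1 − p(s_i|t_j)) ∈ [0, 2(P−1)],
    SAE_ap = Σ_i SAE_i = 2P(P−1) − 2 Σ_i Σ_{j≠i} p(s_i|t_j) ∈ [0, 2P(P−1)].

The decision statistic is dSAE = SAE_ap under the TSS table minus SAE_ap
under the FSS table, computed literally as that difference (an algebraic
expansion that drops the sign of the probability sums circulates in
derivations of this statistic; the literal difference is the form whose
extremes and anti-symmetry behave correctly, and it is what this package
computes). The rule is dSAE < ε → TSS, dSAE ≥ ε → FSS, with the boundary
assigned to FSS. Reported scores are −dSAE so that higher means more
TSS-like.

The association measure used for window selection is
a_ij(s,t) = n_ij(s,t)/√(n_i(s)·n_j(t)) between positions and the
multinomial indicator correlation within a position; assembled into a
4P × 4P unit matrix (unit u = 4(pos−1) + rank, base order A, T, G, C) it
is exported as TSV and optionally rendered as a heat map. Window size
remains a user parameter: the matrix is the evidence, not an automatic
selector.

## Threshold estimation

A stratified 60% sample of each class is drawn (seeded), split into
k = 10 folds with per-class sizes differing by at most one. For each
fold, SAE tables are fitted on the other nine folds and the held-out
dSAE values are computed; the fold's threshold is the value where
sensitivity (fraction of TSS with dSAE < c) equals specificity (fraction
of FSS with dSAE ≥ c). ε is the mean of the ten crossings.

Candidate thresholds are the midpoints between consecutive sorted unique
pooled dSAE values; the candidate minimising |sensitivity − specificity|
is retained, ties averaged. Midpoints (rather than the observed values
themselves) make the symmetric two-mass case resolve to the interval
midpoint — e.g. TSS scores all at −10 and FSS all at +10 give exactly 0 —
and make class-swapping negate the threshold. Since sensitivity −
specificity is non-decreasing in c, the optimal region is a single
interval and the chosen midpoint approximates its centre; a fine-grid
sweep agrees to within half the local score gap.

Because both rates are class-conditional, duplicating FSS motifs (or
changing the TSS:FSS ratio) with folds fixed leaves every per-fold
crossing unchanged; re-estimation under a different ratio changes ε only
through fold composition.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `exon_flank`, `intron_flank` | 3, 6 | window geometry around GT (bases) |
| `pseudocount` α (SAE) | 0 | count smoothing; 0 = exact ratios, raises on a base unseen at some position; use >0 for small N |
| `alpha` (WMM/MM1) | 0.5 | baseline smoothing (baselines are routinely fit on small sets) |
| `epsilon` ε | estimated | decision threshold on dSAE |
| `threshold_fraction` | 0.6 | share of training data used for threshold estimation |
| `threshold_folds` | 10 | folds in the crossing procedure |

SAE's α defaults to 0 because the conditional tables are then exactly the
training count ratios; the hard error on undefined conditionals is
deliberate — silently smoothing would change the statistic. Tests and
small-data examples use α = 0.5.

## Baselines

WMM scores Σ_i log2(p_i^TSS(x_i)/p_i^FSS(x_i)); MM1 scores the log2
ratio of inhomogeneous first-order chain likelihoods (initial
distribution at position 1, position-specific transition rows).
Both are trained on the same TSS/FSS sets as the SAE model, with the FSS
model as the denominator, so that all three methods see identical data.
External implementations of these scorers use different background models
and score conventions; values are not comparable across tools, only
ranking behaviour is.

## Evaluation

ROC points come from sweeping every distinct score as a threshold
(positive at score ≥ threshold; tied scores share one vertex, which makes
the trapezoidal area exactly the Mann–Whitney pairwise statistic with
ties counted ½). The AUC standard error is the Hanley–McNeil formula with
Q1 = θ/(2−θ) and Q2 = 2θ²/(1+θ); it vanishes as θ → 1. PR curves
interpolate between achievable (TP, FP) points by increasing FP linearly
with TP at the local skew (FP_B−FP_A)/(TP_B−TP_A); AUC-PR is the
trapezoid over the interpolated curve, anchored at recall 0 with the
precision of the first achievable point (so that perfect separation
yields exactly 1). Cross-validation pools held-out scores across folds
for the curves (fold-averaged curves are an alternative; pooling is what
is implemented and reported) and reports per-fold sensitivity/specificity
at each fold model's own threshold.

## Synthetic data

The generator draws TSS motifs position-wise from a donor-like profile
(consensus strength ~0.6–0.75 at signal positions, loosely shaped after
the (C/A)AG|gt|(A/G)AGT pattern; deliberately generic, not fitted to any
dataset) and then injects pairwise couplings: with probability λ the base
at position j is overwritten by a fixed mapping of the base at position
i. This is the simplest mechanism giving tunable, analytically checkable
pairwise dependence — the association at a coupled pair increases
monotonically with λ, and identity-mapping couplings on uniform profiles
leave all marginals uniform, isolating the dependency signal
(`matched_marginal_spec`), which is the regime where the SAE score
separates classes while position-independent scorers stay at chance.
FSS motifs are i.i.d. draws from one background composition.

What the generator does **not** emulate: the empirical composition of
real false sites (which share genomic background with true sites),
higher-than-pairwise dependencies, compositional heterogeneity along
genes, and masked or ambiguous bases. Passing tests therefore demonstrate
that the implementation computes the intended statistics and that the
method detects planted pairwise structure — not field performance on real
splice-site datasets, which must be measured on data such as curated
human splice-site collections.

Default study sizes used in the test suite: 400–600 motifs per class for
training, 300 per class held out, coupling strength 0.6–0.8; planted-gene
runs use 30 genes of 400 bp with one strong-consensus site each
(consensus sharpened by cubing the profile). These sizes give stable
seeded behaviour with comfortable margins.

## Numerical choices and edge cases

- Association 0/0 (a base absent at a position): defined as 0 with a
  logged sparsity warning — the numerator is necessarily 0.
- Within-position association with a base fixed in all N motifs: the
  formula divides by zero; the cell is NaN, exported as a blank.
- Matrix export uses 17-significant-digit formatting and round-trip float
  parsing, so TSV round-trips are bit-exact.
- Threshold ties: averaged; a degenerate fold whose pooled scores are all
  equal returns that value.
- Candidate windows containing non-ACGT characters are skipped and
  counted; strict loaders reject them (the probability model is defined
  over {A, T, G, C} only). Only the forward strand is scanned.
- Stratified folds use one shuffled split per class (`array_split`), so
  per-class fold sizes differ by at most one.

## Known limitations

- No acceptor (3′) site model; no maximum-entropy or dependency-
  decomposition scorers (the package compares against WMM/MM1 only).
- dSAE scores are not calibrated probabilities.
- Exact-duplicate removal and Hamming identity assume fixed-length
  aligned windows; there is no clustering-based redundancy reduction.
- ε estimation requires every fold to contain both classes; very small
  or extremely imbalanced training sets need fewer folds or a larger
  fraction.
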