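# Methods

## The problem

Synonymous codons are used unevenly, and the usage of a gene's codons
co-varies with how much protein the cell makes from it. `codonlens`
quantifies that relationship at the resolution of individual codons and
turns it into a sequence-only predictor of protein abundance. The package
works from two inputs: in-frame coding sequences (CDS) and a matched
table of protein copies per cell (e.g. LC-MS/MS quantification, replicate
columns averaged).

## Codon Expression Index (CEI)

For each of the 61 sense codons c, let p_kc be the codon's fraction of
gene k's sense codons and e_k the gene's protein abundance. The index is
the Z-score of the Kendall rank correlation between the two arrays:

    tau_c = 2 / (K(K-1)) * sum_{j<k} sgn(p_jc - p_kc) * sgn(e_j - e_k)
    Z_c   = 3 tau_c sqrt(K(K-1)) / sqrt(2(2K+5))

This is **tau-a**: tied pairs contribute zero to the numerator and the
denominator is the full pair count. General-purpose statistics routines
default to the tie-corrected tau-b, which differs whenever frequencies
tie (they often do — rare codons are absent from many genes), so the
implementation recovers the concordant-minus-discordant count from
SciPy's tau-b statistic and the tie counts, and an O(K²) brute-force
oracle in the test suite guards against a silent substitution of tau-b.

Z_c is the number of null standard deviations tau_c sits from
independence. |Z| > 3 is reported as the significance boundary; it never
censors index values. The boundary is calibrated by a shuffle null:
permuting the expression vector (seeded; default one permutation,
configurable upward) and recomputing Z for every codon. With ties the
null Z is very slightly under-dispersed relative to N(0, 1), so the
boundary is mildly conservative per codon; note that the *maximum* over
61 null Z-values still exceeds 3 in roughly a fifth of shuffles — the
boundary is a per-codon statement, not a family-wise one.

The same machinery applied to the 3721 ordered pairs of sense codons
(overlapping adjacent in-frame pairs; a gene of l codons yields l − 1)
gives the codon-pair index (CPEI). Pairs unseen in a training set get
Z = 0 and an "unobserved" flag, and are skipped (denominator
renormalised) when scoring genes.

## Codon Productivity (CP)

    A_c = sum_k e_k n_kc     N_c = sum_k n_kc     CP_c = A_c / N_c

where n_kc is codon c's count in gene k. CP_c is the count-weighted mean
expression of the genes a codon occurs in — the average number of
amino-acid copies the cell produces per occurrence of the codon — and is
therefore bounded by the observed expression range. Codons with N_c = 0
are left undefined (never imputed) and skipped in gene scoring. Although
CP is sometimes described in terms of tRNA availability, the definition
contains no tRNA term; it is implemented exactly as above.

## Expression predictors (CEIS / CPS / CPEIS) and the CAI baseline

A gene's score is the mean index value over its codon occurrences,
C_k = sum_i v(c_i) / l. Scores are mapped to log abundance by ordinary
least squares, P_k = a C_k + b, against log(e_k + 1). The log is
**natural**: the +1 offset keeps sub-single-copy genes non-negative, and
the conventional bin edges (log 2 ↔ ~6 copies, log 3 ↔ ~19, log 4 ↔ ~53,
log 10 ↔ ~38,000 copies per cell) are consistent with ln and no other
common base.

Evaluation is interleaved 11-fold cross-validation: genes sorted by
decreasing expression, gene i (1-based) of the sorted order assigned to
test fold (i − 1) mod 11, so every fold spans the full expression range
and every gene is tested exactly once. Index values and regression
coefficients come from the training fold only. Out-of-fold predictions
are pooled and scored by Pearson r against the actual log values;
`stratified_accuracy` recomputes r over genes above each log threshold.

Because Pearson r is invariant under a common affine map, the rescaling
step cannot change the reported accuracy: applying any single affine map
to the pooled predictions leaves r unchanged to machine precision. The
per-fold fitted coefficients (a_j, b_j) differ slightly between folds, so
running the cross-validation with the rescaling disabled moves the pooled
r by a correspondingly tiny amount (observed ~1e-4 at K = 1000); the two
statements are distinguished in the tests. The regression is kept for
interpretability — predictions come back on the copies-per-cell scale via
exp(P) − 1, clamped at 0.

The CAI comparator is self-contained: relative adaptiveness
w_c = count_c / max synonymous count from a reference set pooled over the
top floor(K_train/4) (minimum 2) highest-expressed training genes of each
fold; codons unseen in the reference get a pseudo-weight of
0.5 / max-count so the geometric mean (computed in log space) never
collapses to zero; single-codon amino acids contribute w = 1 and stop
codons are never scored. CAI goes through the same CV harness, including
the (accuracy-neutral) regression step, for head-to-head comparability.

## Expression classes

`split_into_classes` sorts genes by decreasing expression and cuts the
list into contiguous equal blocks (remainder to the earliest classes;
ties broken by stable input order — equivalent to a median-based split
for even K). Each class's codon distribution pools counts over the class
and normalises to sum 1, so long genes weigh proportionally more.
`distribution_correlation` compares class distributions by Pearson r.

## Synthetic data: what it emulates and what it does not

The generator produces matched CDS + abundance datasets with *known*
per-codon effects, so every pipeline stage is testable without external
downloads:

- Each gene draws a latent expression propensity u ~ Uniform(0, 1) and a
  uniform amino-acid backbone of length Uniform{50..500} codons
  (realistic for bacterial CDS lengths, median ~270).
- Within each synonym group of size m, codons are chosen with a **linear
  tilt** p_c = (1 + tilt·u·w_c)/m, with planted weights w summing to zero
  within each group (default tilt 0.9). The linear form — rather than a
  softmax — is deliberate: it keeps every zero-weight codon's expected
  share exactly independent of u, so null codons are genuinely null;
  a softmax tilt would leak signal into them through the normalisation.
  Planting at the synonymous-choice level keeps amino-acid composition
  independent of expression, isolating the codon-usage signal.
- log(e + 1) = intercept + effect_scale · (gene's realised mean planted
  weight) + Normal(0, noise_sd), then e = exp(·) − 1 clamped at 0.
  `effect_scale` defaults to the value mapping the expected mean weight
  at u = 1 onto the top of `expression_range` (default 0–38,022 copies
  per cell, the span quantitative proteomics reports for *E. coli*);
  noise_sd defaults to 1.0 on the log scale.
- The "full" preset plants +1 and −1 on the first two codons
  (alphabetically) of every multi-codon synonym group; remaining
  synonyms, and single-codon amino acids, are zero-effect. The "pair"
  preset adds ±1 weights on eight specific adjacent pairs of
  codon-neutral codons, tilting the sequential codon draw, to exercise
  the pair index.

Limitations worth keeping in mind: amino-acid usage is uniform (real
proteomes are not), codon effects are additive on the log scale with a
single latent axis, there is no mRNA-structure, tRNA-pool or
position-dependent effect, and no attempt to match a real organism's
codon frequencies. Passing tests on this generator demonstrate that the
estimators recover planted monotone codon-level signal at realistic K and
noise — not that codon usage causally explains any particular organism's
expression. One second-order artefact is intrinsic to the construction:
because expression depends on the *realised* mean weight, a gene where a
zero-weight codon happens to be drawn often has slightly fewer net-positive
draws, giving null codons a weak negative correlation with expression;
at K = 1000 the induced |Z| exceeds 3 for well under 5% of null codons.

## Numerical and degenerate-input choices

- Terminal stop codons are stripped before counting; internal in-frame
  stops are hard errors naming the gene and 1-based codon position;
  codons with non-ACGT letters are skipped with a logged warning.
- Duplicate gene identifiers are removed entirely by the dataset filter
  ("single copy" rule); zero means exactly e = 0.
- Constant vectors: tau-a of a constant vector is 0 by definition (all
  sign products vanish); Pearson r and the regression raise on
  zero-variance input, naming the fold inside cross-validation.
- Row normalisation tolerances are 1e-9; frozen expected values in tests
  are asserted at 1e-12 where closed-form.
- All randomness (generator, shuffles, permutations) flows through
  explicit integer seeds via `numpy.random.default_rng`; identical
  config + seed reproduces datasets byte-for-byte through the writers.

## Problem sizes

The test suite and the acceptance script run at K = 1000 genes (the
generator default) for calibration, recovery and prediction checks, with
smaller K for the pair index (3721 columns) and CLI round-trips; these
sizes give stable statistics (null Z sd ≈ 1, CV r stable to ~0.01)
while keeping a full run to well under a minute of compute.
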