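# Methods

This note records the models the package implements, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter when reproducing
results.

## Markers and diversity

Markers are dominant biallelic band scores (1 = band present, 0 =
absent, NA = missing). The allele frequency of a marker within a group
is taken as the band-presence frequency *p* among non-missing calls
directly; no Hardy–Weinberg back-correction (q = √absence) is applied,
because the entire downstream analysis operates on band states, not
inferred genotypes. Nei gene diversity is `H = 1 − p² − (1−p)² =
2p(1−p)`, bounded by 0.5 for a biallelic locus.

Scope aggregation (chromosome, genome, overall) is the **unweighted
mean of per-marker H** over markers in scope. Markers whose calls are
all missing within a group are excluded from that group's means;
unmapped markers contribute only to the overall scope. The genome of a
chromosome is the trailing A/B letter of its label. Diversity uses all
markers; the <5% missingness filter applies only to association scans.

`ΔGD = 1 − H_subsp/H_wc` is computed from full-precision H. Published
tables that print H to two decimals can therefore show ΔGD cells that
disagree with the rounded ratio by one unit in the second decimal; the
acceptance checks only use cells that are consistent under two-decimal
rounding.

A marker is *monomorphic* (fixed) within a group iff at least one call
is present and all non-missing calls are equal; fixation at 0 and at 1
both count, and overlap counts between subspecies are on marker
identity regardless of the fixed state (two subspecies fixed for
opposite states still share the marker).

## LD decay

LD between two markers is the Pearson correlation *r* of the 0/1
columns over pairwise-complete accessions, with `R² = r²` used for all
thresholding. Pairs on the same known chromosome are *syntenic* (with
cM distance on a single consensus map — positions are absolute within
a chromosome, so no 0/1-base convention arises), pairs on different
known chromosomes are *unlinked*, and pairs involving an unmapped
marker are excluded from both classes. Pairs with fewer than 20
complete accessions, or a constant column within the complete subset,
are skipped and counted as non-evaluable. The full ordered grid
including self-pairs (m²) is reported for pair-count bookkeeping;
statistics are computed once per unordered pair.

Permutation significance permutes one column across accessions;
`p = (1 + #{R²_perm ≥ R²_obs})/(n_perm + 1)` with 1,000 permutations by
default. Because binary columns make the permutation statistic a
function of the 2×2 joint counts only, the null distribution is
discrete and the p-values are *super-uniform* (atoms, notably at 1);
they are valid but conservative, and the test suite asserts
super-uniformity rather than exact uniformity.

The critical R² treats √R² of unlinked pairs as approximately normal
and takes the parametric 95th percentile `(mean + 1.6449·sd)²`; with
fewer than 30 unlinked pairs it falls back to the empirical 95th
percentile with a warning.

The extent of LD is the first downward crossing of the critical R² by
a loess fit of syntenic R² on distance, linearly interpolated on a
0.1 cM grid. The smoother is a locally weighted polynomial (tricube
weights on the span-fraction nearest neighbours, degree 2, 3 bisquare
robustness iterations, span 0.5 — all configurable). A curve starting
below the baseline gives extent 0; a curve that never crosses is
flagged not-estimable and returned. A single collection-wide extent is
reported; per-chromosome curves can be obtained by subsetting the pair
table.

## Augmented-design BLUPs

Each environment is fitted separately with

    y = X·beta + Z_row·u_row + Z_col·u_col + Z_acc·u_acc + e,

where X holds the intercept and check contrasts (checks are fixed:
they are the replicated material), and row, column and accession
effects are independent random effects. The REML criterion is
maximized over the four log-variances by Nelder–Mead (criterion
tolerance 1e-8, at most 500 iterations); a component whose
standardized log-variance falls below −12 is reported as a boundary
zero. Traits with zero variance return all-zero components and
constant predictions rather than erroring; non-convergence is flagged
on the result, not raised.

BLUPs are solved at the optimum from the fitted covariance
(equivalently Henderson's mixed-model equations, which the tests use
as an independent oracle). The reported accession value is
**intercept + accession BLUP** — comparable across accessions, with
check effects excluded from the prediction; no additional per-block
check adjustment is applied. Prediction-error variances accompany each
value. Equivariance holds: adding a constant to all plots shifts only
the intercept, scaling by c scales all variance components by c².

## Association

Markers with missing fraction strictly below 5% enter the scan. For a
response (per-environment accession values for quantitative traits;
one-vs-rest class indicators with ≥5 members for qualitative traits,
since the scan needs a numeric response) the scan fits
`response ~ intercept + Q[ ,1..K−1] + marker` on complete cases and
tests the marker by the extra-sum-of-squares F test with (1, n−K−1)
degrees of freedom; the marker's partial R² is
`(SSE_red − SSE_full)/SSE_red`. The last Q column is dropped because Q
rows sum to one and would be collinear with the intercept. Markers
collinear with Q (projected residual norm below 1e-10 of the marker
norm) return NA with a diagnostic; markers monomorphic in the sample
are skipped.

Declaration follows the two-stage rule: scan P < 0.0005 in at least
one environment, confirmed by Pearson χ² (no continuity correction)
at P < 0.01 within at least one subspecies for qualitative traits, or
by within-subspecies simple regressions at P < 0.05 whose significant
cells cover more than one distinct environment **or** more than one
distinct subspecies for quantitative traits. All thresholds are strict
inequalities; p exactly at a threshold is non-significant.
Bonferroni-adjusted scan p-values (`min(1, p·m)`, m = markers tested)
are reported alongside the raw values but do not enter the declaration.

**Measured operating characteristic.** With 532 post-filter markers
and two environments at the raw scan threshold, about
532 × 2 × 0.0005 ≈ 0.5 false scan hits are expected per null dataset,
and because the confirmation regressions reuse the same data that
produced the hit (and any heritable background is shared across
environments), roughly half of those hits confirm. The measured
probability of at least one declared association for a null trait is
therefore ≈ 0.2, not the nominal ≤ 0.05; the corresponding acceptance
check is left failing by design rather than weakening the declared
thresholds. Users who need family-wise control should gate on the
reported Bonferroni-adjusted scan p instead of the raw p.

For a declared marker fixed in some subspecies, the concordance check
asks whether the fixed state matches the phenotype: from the
segregating subspecies it determines which band state associates with
the higher trait value (or which majority class), and the fixed
subspecies is concordant iff its own trait mean is closer to that
state's mean (or its dominant class matches). Subspecies without trait
data are not evaluable.

## Trait statistics

Carbon isotope composition is `δ¹³C (‰) = (R_grain/R_standard − 1)·1000`
and discrimination `Δ¹³C = (δ_a − δ_s)/(1 + δ_s/1000)` with air
δ_a = −8 ‰ by default. The denominator divides δ_s by 1000 because
both deltas are expressed in per mil; this is the only reading that
maps grain values near −25 ‰ to plant-material discrimination near
17 ‰. The transform is strictly decreasing in δ_s.

The subspecies × environment ANOVA uses Type II sums of squares
(via statsmodels), appropriate for the severely unbalanced subspecies
sizes; with an empty cell the interaction is dropped with a warning.
Either plot data or per-environment predicted values may be supplied;
the pipeline uses the predicted values. Trait correlations are
pairwise-complete with a per-variable Shapiro–Wilk gate at α = 0.05:
Pearson when both variables pass, Spearman otherwise, with the method
recorded per cell.

## Synthetic collections and trials

The generator emulates the *structure* of a landrace collection, not
any particular dataset:

* 183 accessions (132/38/13 by default) in 9 populations allocated to
  subspecies by largest remainder, membership jittered into a Q matrix
  by a Dirichlet with concentration 50 (the analysis takes Q as given
  and imperfect);
* 749 markers spread evenly over 14 chromosomes (1A–7B, 150 cM each)
  with sorted uniform positions; 329/749 retain their map entry;
* band frequencies drawn hierarchically (collection → subspecies,
  Beta concentration 8 → population, concentration 30), giving
  realistic differentiation between subspecies;
* LD from a first-order Markov copying process along each chromosome:
  an accession copies the previous marker's state with probability
  `exp(−d/τ)` (τ = 5 cM by default), else draws fresh — one parameter,
  monotone decay, independent across chromosomes;
* per-subspecies monomorphic sets planted at the observed fractions
  (11, 80 and 265 of 749) by fixing all of that subspecies'
  population frequencies; small subspecies fix further markers by
  sampling chance, so realized counts exceed the planted ones, as in
  real collections — the ledger records the realized status;
* missingness planted marker-wise: 217/749 markers receive ≥5%
  missing calls (failing the association filter by construction), the
  rest stay below 5%, so exactly 532 markers pass by default;
* augmented trials on a 19 × 12 grid (228 plots = 183 entries once
  each + 45 plots of 4 checks) — the full-size entry count with
  enough row and column levels that their variances are identifiable;
  plot values are `μ_env + subspecies×environment shift + genetic
  value + row + col + error` with defaults σ²_row = σ²_col = 0.5,
  σ²_acc = 1.0, σ²_e = 0.5 (spatial heterogeneity comparable to the
  residual, the situation augmented designs are designed for);
* planted marker effects scaled to a target plot-level R² within the
  segregating subspecies (`β² = R²/(1−R²) · σ²_rest / Var(x)`);
  qualitative traits threshold a latent normal driven by the planted
  marker into multinomial classes.

Every stochastic component uses its own child stream of the mandatory
seed, so outputs are bitwise reproducible across platforms.

The **truth ledger** records realized quantities measured on the
simulated data — monomorphic status, missingness, per-environment QTL
R², and the realized variances of the drawn row/column/accession/
residual effects. Recovery tests compare estimates against these
realized values: with only 12–19 row/column levels the realized
variance of the drawn effects differs from the configured value by
irreducible χ² draw noise (relative sd ≈ √(2/q)), which no estimator
can remove, so the configured value is the wrong recovery reference at
this design size.

What the generator does **not** emulate: coalescent genealogies,
selection or drift dynamics, genotype-calling error beyond random
missingness, spatially correlated field trends (AR1×AR1), eco-
geographic structure within subspecies, or the exact diversity level
of any real panel (the default collection's overall H ≈ 0.44).
Passing tests therefore establish internal correctness and calibration
of the estimators under this model, not agreement with any particular
field dataset.

## Problem sizes used by the automated checks

The test suite runs the estimator-oracle comparisons on ≤60-observation
instances (tolerance 1e-8), null calibration of the declaration
pipeline on 200 seeded full-size collections with accession-level
responses (two environments), declaration power on 100 seeded
collections with a planted R² = 0.3 effect (counting runs whose
realized R² reaches 0.25 in both environments), LD-extent recovery on
20 seeded decay curves against the analytic noise-free crossing
(±20%), and REML recovery on 50 seeded trials at the default layout
(median relative error < 30% per component against the realized
variances). Null-calibration and power runs score each accession's
plot value directly rather than re-fitting REML per run: the property
under test is the scan → confirm → declare machinery, and REML
recovery is checked separately.

## Known limitations

* The declaration rule does not control family-wise error at the
  default scale (see the measured operating characteristic above).
* The REML optimizer is derivative-free; with four components and
  near-boundary optima it can require most of its 500-iteration
  budget, and flags rather than polishes marginal convergence.
* Qualitative traits enter the scan as one-vs-rest indicators fitted
  by least squares, not by a multinomial likelihood.
* The loess extent is reported collection-wide; chromosome-specific
  extents from ~50 pairs each are noisy and left to the user.
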