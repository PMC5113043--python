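# durmap

Diversity, linkage-disequilibrium and marker–trait-association analysis
for structured collections of dominant biallelic markers (DArT-style
band presence/absence scores), built around the analysis workflow used
for tetraploid-wheat landrace panels: a whole collection subdivided into
subspecies of very unequal size (e.g. 132 *durum* / 38 *turgidum* /
13 *dicoccon*), genotyped with a few hundred markers, and phenotyped in
unreplicated augmented field designs across several environments.

The package is aimed at plant-genetic-resources researchers who want a
tested, reproducible version of this pipeline together with a synthetic
data generator that emulates the collection's statistical structure, so
every stage can be exercised and calibrated without access to the
original genotypes.

## What it computes

* **Diversity** — per-marker band frequency *p*, Nei gene diversity
  `H = 2p(1−p)`, aggregated per chromosome / genome / overall for the
  whole collection and each subspecies; relative diversity loss
  `ΔGD = 1 − H_subsp / H_wc`; per-subspecies monomorphic-marker scans
  with state-agnostic overlap counts.
* **LD decay** — pairwise allele-frequency correlation *r* and
  `R² = r²` over pairwise-complete accessions; permutation p-values
  (`p = (1 + #{R²_perm ≥ R²_obs}) / (n_perm + 1)`); a critical R² from
  the unlinked-pair distribution (√R² treated as normal, parametric
  95th percentile `(mean + 1.6449·sd)²`); the extent of LD as the
  distance where a loess fit of syntenic R² vs cM falls to that
  baseline.
* **Augmented-design BLUPs** — per-environment REML fit of
  `y = checks (fixed) + row + col + accession + error` with accession
  predictions from the mixed-model equations.
* **Association** — GLM-Q scan (`response ~ intercept + Q + marker`,
  extra-sum-of-squares F test, markers with <5% missing calls),
  Bonferroni-adjusted p reported alongside, and declaration of
  marker–trait associations only when the scan (P < 0.0005) is
  confirmed by χ² (P < 0.01, qualitative traits) or by per-subspecies
  regressions significant (P < 0.05) in more than one environment or
  subspecies; concordance checks of fixed allele states against
  subspecies phenotypes.
* **Trait statistics** — carbon isotope discrimination
  `Δ¹³C = (δ_a − δ_s)/(1 + δ_s/1000)` with `δ¹³C = (R_grain/R_std − 1)·1000`;
  unbalanced subspecies × environment ANOVA (Type II SS); trait
  correlations with a Shapiro–Wilk gate choosing Pearson or Spearman.
* **Synthetic collections** — a seeded generator producing the marker
  matrix (Markov-copying LD along a cM map, hierarchical population
  frequencies, planted monomorphic sets, marker-wise missingness), the
  Q matrix, augmented trials with planted marker effects, and a truth
  ledger of realized quantities for recovery testing.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/03_ld_decay.py` generates the default 183-accession,
749-marker collection and prints:

```
ordered pair grid (incl. self pairs): 108241
evaluated unordered pairs: 53954
median R^2: 0.00456
critical R^2 (unlinked 95th pct): 0.0365
LD extent: 15.2 cM (estimable=True)
```

329 mapped markers give the 329² = 108,241 ordered pair grid (the
bookkeeping convention; statistics use each unordered pair once); the
critical R² is what unlinked pairs produce by chance, and syntenic
pairs closer than the extent carry LD beyond it. Similarly,
`python examples/05_association.py` plants a marker effect with target
R² 0.3 in *durum* and shows the scan + confirmation machinery declaring
it (and a neighbour in LD with it):

```
planted marker: mk0201 (realized R^2 C/N: 0.27/0.31)
declared: mk0201 (NA) via scan+regression [durum/C, durum/N, turgidum/C, turgidum/N]
```

A thin command-line interface wires the stages into a pipeline:

```bash
durmap run --out out/ --seed 1          # simulate → blup → diversity → ld → associate → stats
durmap simulate --out out/ --seed 1     # any single stage re-runs from its on-disk inputs
```

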