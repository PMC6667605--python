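# Methods

## Scope and model

`saltscreen` analyses replicated screening trials in which a panel of
genotypes is grown under three salinity levels (control, moderate ≈ EC 6
dS m⁻¹, high ≈ EC 12 dS m⁻¹) in a randomized complete block design and
scored on shoot, root and physiological traits.  The statistical object
is the per-genotype retention ratio of each trait under stress; all
downstream quantities (cumulative indices, tolerance bands, PCA
classification) are functions of those ratios.

Assumptions worth stating explicitly:

* **Replicate means first.**  Ratios are formed from replicate means,
  not per-replicate, so a genotype needs a strictly positive control
  mean for every index trait.  A zero or missing control mean is an
  error, never silently imputed.
* **Ratios are taken as-is.**  The same ratio applies to every trait,
  including those (chlorophyll, nitrogen balance index) that *rise*
  under moderate stress — a ratio above 1 simply adds more than 1 to the
  cumulative index.  No trait inversion is attempted for responses where
  a decrease could be adaptive.
* **Sample SD for bands.**  The tolerance bands use the *n − 1* standard
  deviation over genotypes.  On the packaged 74-genotype reference
  screen this reproduces the printed sensitive ceiling (min 25.15 +
  0.5 × SD 2.780 = 26.54) to the printed precision.
* **Interval closure.**  Bands are closed above: sensitive is
  TSSRI ≤ b1, each middle class is (b_k, b_{k+1}], and the high class is
  unbounded above (the reference screen's top genotype, at 39.87,
  exceeds the nominal min + 3.5 SD ceiling yet is classified high).

## Trait sets

Three presets select which variables enter an analysis:

* `eq3-20` — the 20-trait index set (shoot: PH, TN, LA, LW, SW, TW;
  root: RW, LRL, TRL, SA, AD, RV, RN, TP, FR, CR; fluorescence: F0, FM,
  FV, Fv/Fm).  Default for the response-index pipeline.
* `pca-22` — the 22-variable PCA set, which adds the pigment indices
  (CH, FLV, ANT, NBI) and drops FV and RN.
* `all-24` — everything in the default registry.

The 20-trait and 22-variable lists genuinely differ (the index
definition excludes the pigment traits, the PCA includes them); both are
kept as first-class presets rather than reconciled, and the trait set of
every function is overridable by an explicit code list.

## Reference fixtures

`saltscreen.datasets` packages the published 74-genotype rice screen:
per-genotype TSSRI values and first-two-PC scores, each with the
tolerance column it was printed under.  Two internal inconsistencies of
the source tables are preserved rather than corrected: one genotype
(26.75) is printed in the sensitive column although it exceeds the
printed sensitive ceiling of 26.54, and one (32.16) is printed as
moderate although it exceeds the moderate ceiling of 32.10.  Strict
application of the stated interval rule therefore gives 7 sensitive and
27 low genotypes (matching the published summary counts) rather than the
8/26 of the printed columns.  A few genotype labels repeat in the source
tables; rows are positional, not keyed by label.

## Statistics

* **RCBD ANOVA.**  Fixed-effects two-factor decomposition with
  replicate as block and genotype crossed with salinity, computed in
  closed form on the balanced data cube (the design guarantees balance;
  unbalanced input is rejected with a pointer to the missing-cell
  report).  The trial language "main factor / sub-main factor" could
  also describe a split-plot layout, but no sub-plot error term is ever
  reported for these screens, so a single pooled error is used.  F
  ratios use the pooled error mean square; star codes are *** / ** / *
  for p < 0.001 / 0.01 / 0.05, else NS.  When every observation is equal
  the F ratio is reported as not computable (NaN) with stars NS.
* **Fisher's protected LSD.**  LSD = t(1 − α/2, df_error)·√(2·MSE/r).
  Pairs are compared only when the protecting omnibus F-test for the
  factor is significant at α; otherwise no pair is flagged and the
  result records that comparisons were withheld.
* **Quantiles.**  All percentile statistics (box summaries: Q1/Q3 box,
  5th/95th whiskers, outliers outside the whiskers) use
  linear-interpolation quantiles.  The rule is pinned because box
  figures must be reproducible; Q1 and the 5th percentile are kept
  distinct even though screening figure captions sometimes conflate
  them.
* **Regression.**  Ordinary least squares; R² = 1 − SS_res/SS_tot.
  Constant y returns R² = 0 by convention; constant x is an error.

## PCA classification

Columns of the genotype × trait combined-index matrix (moderate + high
ratio per trait; a mean-of-two variant is available behind
`combine="mean"`) are standardised with the sample SD, and the
correlation matrix is eigendecomposed.  Identities enforced and tested:
eigenvalue sum = trait count, orthonormal loadings, diagonal score
covariance, exact reconstruction of the standardised matrix.

Eigenvectors have no intrinsic sign, so components are oriented
deterministically: PC1 so the summed loading of root-category traits is
positive (root vigour points right — tolerant genotypes, which retain
root growth, then score positive), PC2 so the anthocyanin loading is
positive; components without an applicable anchor make their
largest-magnitude loading positive, ties broken by trait order.  With
fewer genotypes than traits the trailing null-space axes remain
arbitrary; only components with non-degenerate eigenvalues are
identified, which covers the two the quadrant rule uses.  Quadrant
classes come from score signs with zeros assigned to the non-negative
(tolerant) side; on the packaged reference scores the rule reproduces
every printed group membership and the 19/20/16/19 group sizes.

The agreement report cross-tabulates SSRI bands against PCA quadrants.
The two methods share a label vocabulary but not cut-points — bands are
relative to the panel minimum, quadrants to the panel mean — so overall
agreement well below 1 is expected even when both rank genotypes
identically; the extreme-class agreement (restricted to genotypes the
band method calls sensitive or high) is the more meaningful summary.

## Synthetic trials

The generator emulates the screening design (default 74 genotypes × 3
levels × 4 replicates, ~24 traits) with a multiplicative model:

```
value = baseline_t · G_g · retention_t(s, τ_g) · block_rep · noise
```

with latent tolerance τ_g ~ Uniform(0, 1), genotype size effect G_g and
all noise lognormal with mean 1, and retention
`1 − δ_t(s)·(1 − κ·τ_g)` for monotone-declining traits (κ = 0.8 by
default).  Hump-shaped traits (chlorophyll, nitrogen balance index,
anthocyanins) carry a uniform moderate-level boost — encoded as a
negative δ_mod, deliberately not τ-modulated so the expected TSSRI stays
monotone in τ.  Count traits (TN, TP, FR, CR) are rounded to integers
last, after noise.

Calibration: baselines equal the published control-level population
means where printed (total root length 5968.3 cm, leaf area 721.1 cm²,
chlorophyll 21.4 µg cm⁻², root forks 108 884.8, …), and suppression
fractions are the printed relative declines (δ_high up to ≈ 0.63 for
root volume).  Because tolerant genotypes escape part of the
suppression, the realized stressed-population mean is somewhat milder
than the printed one; the control mean is the calibrated quantity
(verified within 5% by a 20-seed Monte-Carlo test).  Traits whose means
were never published (dry weights, fluorescence, flavonoids, RN, the
control-level plant height) use stated assumptions chosen to be
field-realistic, with replicate CVs of 0.05–0.20 by trait class; these
are assumptions, not estimates.

Randomness is organised as one master seed spawning an independent child
stream per genotype plus one for block effects, so enlarging a trial
leaves existing genotypes' data bit-identical.

What the generator does *not* emulate: spatial heterogeneity within
blocks, genotype × block interaction, seedling mortality, trait-trait
correlation beyond what the shared size effect and shared tolerance
induce, and measurement-device artefacts.  Tests passing on synthetic
trials therefore show the pipeline recovers a latent tolerance under the
model's assumptions — not that any particular real panel satisfies them.

## Problem sizes used in tests

The default suite simulates trials at the design size (74 × 3 × 4) for
the recovery checks (100 seeds), uses 1000 small (6 × 3 × 4) pure-noise
trials for the ANOVA type-I calibration, and toy designs up to 5 × 3 × 4
for the brute-force ANOVA oracle; the whole suite runs in well under a
minute on one CPU.

## Known limitations

* Only the two-factor fixed-effects RCBD is provided; no mixed or
  split-plot models.
* No alternative tolerance indices (STI, SSI, TOL) and no rotation of
  the PCA solution.
* The published per-replicate raw data behind the reference screen were
  never released, so quantities that depend on them (the printed PCA
  variance fractions, the printed index-regression R² values, the full
  per-genotype trait-mean tables) cannot be recomputed; they guided the
  generator's calibration targets instead.
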