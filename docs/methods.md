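# Methods

## Statistical model

The package performs two-sample Mendelian randomization with variants from
one gene region used jointly as instruments.  Let β̂_Xj and β̂_Yj be the
marginal association estimates of variant j with the exposure and the
outcome, estimated in non-overlapping samples, and let ρ be the signed LD
correlation matrix of the variants (allele-aligned to the exposure effect
alleles).  The working model is the zero-intercept regression

    β̂_Yj = θ β̂_Xj + ε_j,   Var(ε) = Σ,   Σ_{j1 j2} = se_Yj1 · se_Yj2 · ρ_{j1 j2},

whose GLS solution generalizes the inverse-variance weighted estimator to
correlated instruments.  Assumptions inherited from this framework:

* **Relevance and strength.** Standard errors are computed with the
  exposure associations treated as fixed (the "fixed denominator" or NOME
  convention).  This is first-order accurate when instruments are strongly
  associated with the exposure; with weak instruments θ̂ attenuates toward
  zero and coverage degrades.  With the default synthetic scenario
  (|β̂_X|/se_X ≈ 7) the attenuation is ≈2% of θ, visible as a mean estimate
  of ≈0.191–0.195 when the true θ is 0.2 — within the Monte-Carlo
  uncertainty bands the tests use, and documented here rather than
  corrected, because correcting it requires individual-level data.
* **No pleiotropy.** The estimator assumes every instrument acts on the
  outcome only through the exposure.  It is *not* robust to directional
  pleiotropy: the simulation suite demonstrates (deliberately) that
  pleiotropic effects under a null θ inflate the false-positive rate.
  Specificity must come from the biology of the chosen gene region, not
  from the statistics.
* **Two-sample independence.** Exposure and outcome errors are drawn
  independently; sample overlap would correlate them and is not modelled.

Which standard errors enter Σ is a genuine ambiguity in the field's usage;
this package uses the **outcome** standard errors (the established
generalized-IVW weighting).  `CorrelatedIVW(weights="exposure_se")` swaps
in the exposure standard errors for sensitivity analysis only.

## Principal-components stabilization

Fine-mapped regions contain near-duplicate variants, making Σ numerically
singular.  `CorrelatedIVW` refuses to fit when the condition number of Σ
exceeds 1e8 — an explicit, actionable error rather than a silently unstable
estimate.  `PCStabilizedIVW` then forms the weighted matrix

    Psi_{j1 j2} = β̂_Xj1 β̂_Xj2 ρ_{j1 j2} / (se_Yj1 se_Yj2),

eigendecomposes it, clamps negative eigenvalues (an artefact of LD matrices
estimated in external reference panels) to zero at relative tolerance
1e-10, keeps the smallest number k of leading components whose eigenvalue
sum reaches `variance_kept` (default 0.99) of the total, and applies the
GLS formula to the projected data (ΛᵀX, ΛᵀY, ΛᵀΣΛ).  Properties relied on
by the tests: with `variance_kept = 1` on full-rank input the projection is
an orthogonal change of basis and the estimate is identical to plain GLS;
with perfectly duplicated variants the leading component recovers exactly
the duplicate-free estimate.  The β/se weighting of Psi concentrates the
retained components on the directions that carry estimation weight; an
unweighted mode (`weighted=False`, PCA of ρ itself) is available for
comparison.

## Harmonization and QC

Effect alleles are aligned across exposure, outcome and LD inputs by
variant id; swapped alleles negate the outcome beta and reflect the allele
frequency, and LD rows/columns are sign-flipped to the exposure effect
allele (an involution, so eigenvalues — and hence selection and estimation —
are unaffected by orientation).  Palindromic variants (A/T, C/G) are strand
ambiguous: they are dropped when the minor allele frequency is within 0.08
of 0.5 in either dataset, and otherwise oriented by allele frequency.  The
0.08 band is the conservative convention for two-sample designs; every drop
and flip is logged so alternative policies can be replayed.

QC filters use strict inequalities at their thresholds (MAF < 0.01, call
rate < 0.95, Hardy-Weinberg p < 0.001 from the 1-df chi-square
goodness-of-fit test, info score < 0.6), so boundary values survive.  A
missing info score is treated as a genotyped variant (info = 1) with a
warning.  The confounder screen drops variants associated with any
supplied confounder trait below alpha / (n_variants × n_traits); the
denominator is logged.  Drop reasons follow a fixed priority order (maf,
call_rate, hwe, info) so QC reports are byte-reproducible.

## Instrument selection

Stepwise selection visits variants in ascending exposure p-value (ties
break by genomic position then variant id) and keeps a candidate iff its
squared correlation with *every* previously kept variant is below `r2_max`
(default 0.4) — i.e. pruning is against the whole selected set, which
guarantees low pairwise correlation throughout.  Because r² is the square
of the signed correlation, allele orientation cannot change the outcome.
The conditional-list mode restricts a fixed externally derived score to the
variants available for a given outcome, preserving list order and logging
absentees.

## Power

Power uses the standard normal approximation for summary-data MR: the
non-centrality is |θ|·√(n·r²_GX·K(1−K)) for a binary outcome with case
fraction K (|θ|·√(n·r²_GX) for a continuous outcome in SD units), and
power at two-sided level α is Φ(ncp − z_{1−α/2}).  The one-tailed
approximation means power(θ=0) = α/2, matching the convention of the
online calculators used for MR design.  The formula treats the instruments
as a single fixed score: exposure-side noise and the efficiency loss from
residual LD both act to reduce the effective r²_GX, so analytic power is
mildly optimistic for weak instruments.  The acceptance suite verifies the
approximation against simulated rejection rates of the full
simulate-and-estimate cycle to within ±0.02.

## Synthetic data generator

`mrld.simulate` draws summary statistics directly at the summary level:
β̂_X ~ MVN(β_X, D_X ρ D_X) and independently β̂_Y ~ MVN(θβ_X + pleiotropy,
D_Y ρ D_Y), with D the diagonal standard-error matrices.  This is the
minimal generative model under which the analysis model is correctly
specified, and it keeps a full simulation study to a few seconds.

Default scenario (chosen once, to emulate a fine-mapped
testosterone-associated autosomal gene region):

| parameter | default | rationale |
|---|---|---|
| n_variants | 20 | a pruned region-level instrument set |
| LD | AR(1), ρ = 0.5 | moderate within-region correlation decaying with distance |
| β_X | \|N(0.18, 0.05²)\| per allele, SD units | a lead variant explaining ≈1% of exposure variance at 2p(1−p) ≈ 0.32 |
| se_X | 0.025 | an exposure GWAS of ≈3200 individuals |
| se_Y | 0.05 | a consortium-scale binary outcome, log-odds scale |
| eaf | U(0.1, 0.9) | common variants, non-palindromic allele pairs |

True effects are materialized once per study (`resolve_config`) and held
fixed across replicates, so coverage and bias have their usual frequentist
meaning.  Per-replicate seeds derive from one master seed through
`numpy.random.SeedSequence`; all outputs are bit-reproducible per seed.

What the generator does **not** emulate: winner's-curse selection of
instruments, sample overlap between exposure and outcome GWAS, LD matrices
estimated with error in an external panel, allele-frequency differences
between cohorts, strand mislabelling, or individual-level genotype
structure.  Passing calibration tests therefore demonstrates correctness of
the estimator under its own assumptions, not robustness to these real-data
complications.

## Numerical choices

* GLS solves via Cholesky factorization, never an explicit inverse; the
  explicit-inverse implementation exists only as an independent oracle in
  the test suite.
* Condition-number gate for Σ: 1e8.  LD file tolerances: asymmetry and
  diagonal deviation ≤ 1e-6 (symmetrized as (M+Mᵀ)/2 below, error above);
  |r| clipped to 1.
* The 97.5% normal quantile is fixed at 1.959964 so printed 95% CIs
  round-trip bit-stably.
* Stated p-values inconsistent with |β/se| raise a warning, not an error,
  because published tables round.
* Simulation-study problem sizes (2000 replicates for type-I error, 1000
  for coverage, 5000 for power comparisons) put Monte-Carlo standard errors
  near 0.005–0.007 on rates, comfortably inside the asserted bands while
  keeping a full run to a few seconds.

## Known limitations

* No pleiotropy-robust estimators (MR-Egger, weighted median/mode) and no
  heterogeneity decomposition — out of scope by design.
* Cohort pooling is fixed-effect inverse-variance pooling of region-level
  estimates; pooling at the variant level (harmonizing a combined outcome
  dataset) is the alternative when per-cohort variant sets differ, and both
  routes are available through the API.
* The analytic power module's single-score approximation understates the
  required sample size for weakly instrumented exposures.
* Exact-test Hardy-Weinberg checking is not implemented; the chi-square
  test is adequate at the p < 0.001 threshold in well-powered samples.
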