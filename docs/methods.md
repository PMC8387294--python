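# Methods

This note documents the statistical models behind `fhrmr`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Isotope-dilution quantitation

Each protein is represented by one Glu-C proteotypic peptide monitored
with three SRM transitions in light (endogenous) and heavy (stable-isotope
standard) form.  Quantitation is single-point isotope dilution: the
endogenous concentration is the light/heavy peak-area ratio of the
quantifier transition multiplied by the plasma-equivalent spike
concentration of the standard.  Because light and heavy co-elute in the
same injection, the ratio is independent of the injected volume; the
`injected_plasma_equiv_ul` field of the spike scheme is retained as
bookkeeping only and is configurable (the stated protocol volumes imply
0.4 uL per injection while the data processing assumed 0.8 uL, so the
value is deliberately not hard-coded).

The spike concentration is

    C_spike [nM] = (stock / dilution_factor * spike_uL / plasma_uL) * 1e6 / M

with stock in ng/uL and M the monoisotopic mass (Da) of the heavy,
Cys-alkylated peptide.  Masses come from summed residue masses plus water,
one alkylation adduct per cysteine (carbamidomethyl, +57.02146 Da, since
iodoacetamide is the alkylating agent in the protocol; configurable), and
the heavy-label shifts K +8.01420, R +10.00827, F/Y +10.02728 Da.  Two of
the seven standards (the FHR-3 and FHR-5 peptides) carry two labelled
residues, so `PeptideSpec` holds a list of labels rather than a single
one.  With the bundled stocks and the 5+195 uL dilution / 2 uL spike /
5 uL plasma scheme, the computed spike concentrations match the published
list (500, 5, 32.75, 86.75, 21.68, 41.5, 27.5 nM) within 1%.

Operational conventions, chosen where the protocol is silent:

* The quantifier is the transition with the largest summed heavy signal
  per peptide per batch, recomputed per batch.
* Qualifier concordance requires both qualifier light/heavy ratios within
  30% relative deviation of the quantifier ratio (default; configurable).
* Concentration at or above the LLOQ counts as quantifiable (boundary
  inclusive); below-LLOQ values are retained and flagged, never imputed.
* A missing heavy standard yields a flagged missing value, never a silent
  zero.  Batch %CV is sample SD / mean * 100 (ddof = 1); a zero mean gives
  a flagged NaN.
* No between-batch normalization is applied.

## Case-control association

Concentrations are transformed towards normality with a fixed per-protein
map — square root for FH, FHR-2, FHR-3, FHR-4; natural log for FHL-1 and
FHR-5; identity for FHR-1.  Natural rather than base-10 log is used; the
per-SD odds ratio is invariant to this choice.  The case-control
difference on the transformed scale is a covariate-adjusted OLS Wald test
(sex, age, PC1, PC2).  The logistic odds ratio per SD of log concentration
standardises by the SD of the pooled analysis sample (cases + controls,
complete cases per protein) and uses Wald confidence intervals.  Missing
or non-positive concentrations are dropped per protein (complete-case).
Perfect separation or non-convergence raises rather than returning silent
estimates.

## pQTL scans, LD and clumping

The scan regresses the transformed concentration on each variant's
minor-allele dosage (0..2) plus covariates.  Covariates are projected out
of trait and dosages once (Frisch-Waugh-Lovell), making the per-variant
fits a single matrix product; estimates, SEs and p-values are identical to
a full per-variant OLS refit (tested against statsmodels).  Variant QC
keeps MAF >= 1% and, for imputed variants, imputation R² >= 0.3, both
boundaries inclusive.  Monomorphic variants are skipped with a log entry.

LD between two biallelic loci is computed from unphased genotypes by EM
over the double-heterozygote phase ambiguity (start from linkage
equilibrium, up to 50 iterations or log-likelihood change < 1e-10),
yielding D, D′ = |D|/D_max and r² = D²/(p_A p_a p_B p_b).  When phase is
unambiguous this equals the squared Pearson correlation of dosages, which
is also the composite-LD measure used for clumping against a dosage
reference panel.  Clumping is greedy: repeatedly take the smallest-p
variant below 5e-8 and discard everything with r² >= the cutoff (0.001
default, 0.01 supported); ties break by position then variant id; missing
LD pairs are treated as independent and logged.

## Mendelian randomization

Instrument strength is reported as the proportion of exposure variance
explained, recovered from the exposure p-value and sample size by
inverting the single-predictor Wald test: F is the upper-tail F(1, n−2)
quantile of p and R² = F/(F + n − 2).  The quantile is computed through
the Student-t relation F = t², which stays finite to p ≈ 1e-300; direct
F-quantile inversion overflows below p ≈ 1e-16.  When a p-value has
underflowed to zero in a scan, the equivalent t-ratio route (β/SE)² is
used instead.

Each instrument contributes the Wald ratio θ_j = β_Y,j / β_X,j with
first-order delta SE σ_Y,j/|β_X,j| (the second-order term is omitted,
matching common summary-data practice; the SE choice is configurable at
the call level by adjusting inputs).  Fixed-effect IVW pools with weights
w_j = SE_j⁻²; the pooled SE is (Σw)^(−1/2); a single instrument reduces
exactly to its Wald ratio.  Heterogeneity is Cochran's Q = Σw_j(θ_j−θ)²
with df = k−1 and I² = max(0, (Q−df)/Q)·100.  Confidence intervals are
Wald at 95% (z = 1.96) on the log-OR scale.

Harmonization aligns the outcome beta to the exposure's effect allele,
negating it when the allele pair is swapped; palindromic variants with
MAF > 0.42 are dropped with a warning since strand cannot be resolved from
labels.  The one-sample design estimates exposure associations in controls
only (justifiable when disease prevalence is low) and outcome associations
from the cohort's covariate-adjusted logistic GWAS; the two-sample design
takes outcome associations from an external summary-statistics table.
MR odds ratios are per unit of the transformed exposure, which is the
scale on which the bundled worked example reproduces the published FHR-3
estimate.  A protein with no genome-wide-significant instrument is
reported as "no instrument" rather than an estimate.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with defaults set to the targeted study's conditions: 352 cases / 252
controls; sex ~ Bernoulli(0.42), age ~ Normal(74.5, 8), PCs ~ Normal(0,1)
with null covariate effects; one cis pQTL per FHR protein with variance
explained 0.53/0.44/0.35/0.25/0.15 (FHR-1..5) and none for FH or FHL-1;
per-SD-of-log disease odds ratios 1.01/1.35/1.81/1.66/1.54/1.27/1.38;
SRM noise CV 15% (the mid-range of the published batch CVs, 9.7-21%).

* **Genotypes**: haplotypes from a latent-Gaussian threshold model — within
  an LD block all latents share a common factor with loading sqrt(ρ), and
  an allele is carried when the latent falls below the MAF quantile; two
  haplotypes pair into a diploid dosage, so HWE holds marginally.  This
  produces tunable r²/D′ without a coalescent simulator.  A separate
  `genome_seed` can pin the variant-MAF draw so replicate cohorts share one
  genetic architecture while resampling individuals — necessary whenever a
  recovery experiment compares replicate estimates against a single
  reference estimand, because for the non-log proteins the MR estimand
  depends on the MAF through the curvature of the disease model in the
  concentration.
* **Proteins**: transformed value = intercept + Σβ·(dosage − 2·MAF) +
  covariate terms + Normal noise, back-transformed to nM (negative values
  truncated at zero and counted).  Intercepts match the published control
  means; the per-protein marginal SDs on the transform scale (2.85, 0.27,
  14.2, 1.35, 1.98, 2.05, 0.32 for FH, FHL-1, FHR-1..5) were derived from
  the published control-group confidence intervals and describe the
  *measured* concentration.  The variance budget SD² = genetic +
  biological + assay is honoured: allele effects follow from the target R²
  (β = sqrt(R²·SD²/(2·MAF·(1−MAF)))) and biological noise receives the
  remainder net of the assay variance implied by the SRM noise CV (exact
  on the log scale, second-moment delta otherwise).  The causal variant
  therefore explains the target share of the measured concentration
  variance — the quantity published instrument strengths refer to.
* **Disease**: status ~ Bernoulli(logit⁻¹(intercept + Σγ_p z_p)) with z_p
  the log concentration standardised by analytic population moments
  (delta-method for the sqrt/identity proteins), so the per-SD log-OR γ_p
  is a well-defined population parameter.  The baseline intercept −2.2
  gives ~10% prevalence, in the range reported for advanced AMD in elderly
  populations; individuals are drawn in chunks until the requested case
  and control counts are met.
* **SRM peaks**: heavy areas around a nominal intensity with fixed relative
  transition intensities (1.0/0.6/0.3); the light/heavy ratio carries a
  shared mean-one lognormal factor with the configured CV plus a small
  per-transition jitter (CV/10) so transitions stay concordant; an optional
  corruption rate triples one qualifier's light area to exercise the
  qualifier check.

What the generator does **not** emulate: realistic recombination maps or
allele-frequency spectra, population stratification that confounds,
pleiotropy, genotyping/imputation error, missing data patterns,
batch-level drift or retention-time artefacts.  Passing recovery tests
therefore demonstrate correctness of the estimators under the assumed
models, not robustness to these real-data complications.

## Parameter-recovery methodology

The cohort-scale acceptance checks compare 200-replicate means against a
*plug-in estimand*: the same generative configuration and the same
estimator evaluated at 100x the sample size.  This is deliberate — the
raw generative parameters are not the estimands of a case-control design:
the per-SD OR standardises by the analysis-sample SD (slightly inflated by
case oversampling), the outcome logistic slope is attenuated by
non-collapsibility when several proteins affect risk jointly, and controls
are selected on the outcome.  Comparing small-n means against the large-n
plug-in isolates implementation error from these design effects; the
comparison tolerance combines the Monte-Carlo SE of the replicate mean
with the plug-in's own SE (3·sqrt(MC SE² + SE²)).  A separate isolated
configuration — a single log-scale protein carrying the only disease
effect — additionally checks the closed-form estimand γ/σ_log, which is
exact there.  Instrument-strength recovery uses a sampling band
(within ±0.10 of target in >= 90% of replicates) because the small-sample
expectation of R̂² has no usable closed form.  Type-I error of the scan
and of the Wald-ratio test is checked against [0.03, 0.07] at α = 0.05
under null simulations.

Problem sizes used by the test suite (200 replicates at 352/252; the
plug-in at 35,200/25,200; 2,000-variant null scans) were chosen so the
Monte-Carlo error is small relative to the effects being verified while
the whole suite stays comfortably runnable on a laptop.

## Known limitations

* The delta-method moments used to define the disease model for sqrt- and
  identity-transformed proteins are approximations; the generative per-SD
  log-OR is exact only for the log-transformed proteins.
* LD estimation assumes HWE within and between loci for the EM step.
* Harmonization handles strand only through allele labels; analyses should
  avoid strand-ambiguous variants beyond the MAF-0.42 palindrome rule.
* The Wald-ratio SE ignores uncertainty in the exposure association
  (first-order); with the instrument strengths involved here (F >> 30) the
  second-order correction is negligible.
* One-sample MR with overlapping exposure/outcome samples carries
  weak-instrument bias toward the observational association; instruments
  here are strong, and the recovery tests quantify the residual effect.
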