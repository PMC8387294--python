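# fhrmr

From targeted mass-spectrometry peak areas of the complement factor-H
protein family to Mendelian-randomization estimates of their effects on
disease risk.

Age-related macular degeneration (AMD) has its strongest common genetic
association at the *CFH* locus, which encodes complement factor H (FH), its
splice variant FHL-1, and the five factor-H-related proteins FHR-1..FHR-5.
Because these proteins are highly homologous, immunoassays struggle to
separate them; a stable-isotope-dilution LC-SRM-MS assay on Glu-C
proteotypic peptides can quantify all seven simultaneously in plasma.
`fhrmr` implements the full downstream analysis chain for such a study, for
biostatisticians and genetic epidemiologists working with case-control
proteogenomic data:

1. **`fhrmr.srm`** — single-point isotope-dilution quantitation.  For the
   quantifier transition (the one with the largest heavy-standard signal),
   the endogenous plasma concentration is

   *C* = (light area / heavy area) x *C*<sub>spike</sub>,

   where *C*<sub>spike</sub> is the plasma-equivalent concentration of the
   spiked heavy peptide, computed from its stock concentration, the
   dilution/spiking volumes and its monoisotopic mass (heavy labels and
   carbamidomethyl-Cys included).  The two remaining transitions act as
   qualifiers; LLOQ flags and batch %CV complete the QC.
2. **`fhrmr.assoc`** — case-control association: per-protein normalising
   transforms (sqrt / natural log / identity), covariate-adjusted linear
   Wald tests (sex, age, two genetic PCs), odds ratios per SD of log
   concentration from logistic models, and the control-only Pearson
   correlation matrix.
3. **`fhrmr.gwas`** — per-variant pQTL scans of transformed concentrations
   on minor-allele dosages (MAF >= 1%, imputation R² >= 0.3), EM-based
   haplotype LD (D, D′, r²), and greedy p-value clumping at r² < 0.001.
4. **`fhrmr.mr`** — per-instrument Wald ratios θ<sub>j</sub> =
   β<sub>Y,j</sub>/β<sub>X,j</sub> with delta-method SE
   σ<sub>Y,j</sub>/|β<sub>X,j</sub>|, pooled by fixed-effect
   inverse-variance weighting; Cochran's Q and I² heterogeneity; instrument
   strength R² = F/(F + n − 2) recovered from the exposure p-value; one- and
   two-sample designs with allele harmonization.
5. **`fhrmr.simulate`** — seeded synthetic cohorts (LD-blocked genotypes,
   cis-pQTL-driven protein concentrations, logistic case-control disease,
   noisy SRM transition reports) so the whole pipeline is testable without
   access to individual-level data.

`fhrmr.reference` bundles the seven heavy-standard peptides with their
stock concentrations, the published spiking scheme, and the published
instrument-level summary statistics of the FHR proteins for worked
examples.

## Worked example

FHR-3 is the one protein with multiple (seven) instruments — one *cis*
pQTL at the *CFH* locus and six *trans* signals.  Pooling their Wald
ratios against the case-control outcome associations:

```python
from fhrmr.reference import load_fhr_instruments
from fhrmr.mr import mr_from_summary

df = load_fhr_instruments()
f3 = df[df.protein == "FHR-3"]
exposure = f3.rename(columns={"beta_exp": "beta", "se_exp": "se", "p_exp": "p", "n_exp": "n"})[
    ["variant_id", "effect_allele", "other_allele", "beta", "se", "p", "n", "maf"]]
outcome = f3.rename(columns={"beta_cc": "beta", "se_cc": "se"})[
    ["variant_id", "effect_allele", "other_allele", "beta", "se"]]
est = mr_from_summary(exposure, outcome, protein="FHR-3", design="one-sample")
print(f"{est.protein} ({est.method}, {est.sample_design}), {est.n_iv} instruments")
print(f"OR per transformed unit: {est.or_point:.2f} (95% CI {est.or_ci95[0]:.2f}-{est.or_ci95[1]:.2f})")
print(f"heterogeneity: Q = {est.q_stat:.2f} on {est.df} df, I2 = {est.i2_percent:.0f}%")
print(f"instrument R2: {[round(r, 2) for r in est.iv_r2]}")
```

prints

```
FHR-3 (ivw, one-sample), 7 instruments
OR per transformed unit: 0.99 (95% CI 0.93-1.06)
heterogeneity: Q = 5.08 on 6 df, I2 = 0%
instrument R2: [0.35, 0.16, 0.14, 0.12, 0.12, 0.12, 0.11]
```

The genetically proxied FHR-3 concentration shows no effect on disease
risk (OR per unit of the square-root-transformed concentration 0.99, CI
spanning 1) despite FHR-3 being elevated in cases observationally — the
signature of confounding or reverse causation — and the seven
single-instrument estimates are mutually consistent (I² = 0%).

## Command line

```sh
fhrmr simulate --seed 7 --out cohort/        # synthetic study: VCF + CSVs + truth
fhrmr quantify --transitions cohort/transitions.csv --out conc.csv
fhrmr assoc --pheno cohort/phenotypes.csv --conc conc.csv --out assoc.csv
fhrmr gwas --vcf cohort/genotypes.vcf --trait FHR-3 --pheno cohort/phenotypes.csv \
      --conc conc.csv --out fhr3.tsv
fhrmr clump --stats fhr3.tsv --vcf cohort/genotypes.vcf --r2 0.001
fhrmr mr --exposure exp.tsv --outcome out.tsv --design one-sample
```

The transition-report dialect expected by `quantify` is a long CSV with
columns `sample_id, batch, peptide, transition_id, isotope{light|heavy},
area, rt_min` — the column layout of a Skyline transition-results export
after renaming.

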