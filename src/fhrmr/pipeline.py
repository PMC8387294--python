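"""End-to-end wiring: measured peak areas -> concentrations -> association,
pQTL scans, clumping and one-sample Mendelian randomization.

Convenience layer used by the command-line interface and by the
parameter-recovery tests; every step is the corresponding module function.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, gwas, mr
from .reference import DEFAULT_SCHEME, PEPTIDE_STANDARDS
from .srm import quantify_samples

__all__ = ["quantify_cohort", "exposure_scans", "one_sample_mr", "analyze_cohort"]

COVARIATES = ["sex", "age", "pc1", "pc2"]


def quantify_cohort(transitions: pd.DataFrame, peptide_specs=PEPTIDE_STANDARDS,
                    scheme=DEFAULT_SCHEME) -> pd.DataFrame:
    """SRM transition report -> wide sample x protein concentration table."""
    conc = quantify_samples(transitions, peptide_specs, scheme)
    wide = conc.pivot_table(index="sample_id", columns="protein", values="conc_nM", aggfunc="first")
    wide.columns.name = None
    return wide.reset_index()


def exposure_scans(pheno: pd.DataFrame, conc_wide: pd.DataFrame, variants,
                   controls_only: bool = True) -> dict:
    """Per-protein pQTL GWAS of transformed concentrations (controls only by
    default, matching the one-sample MR design)."""
    merged = pheno.merge(conc_wide, on="sample_id", how="inner")
    if controls_only:
        merged = merged[merged["status"] == 0]
    idx = merged.index.to_numpy()
    cov = merged[COVARIATES].to_numpy(dtype=float)
    sub_variants = [
        gwas.VariantRecord(
            variant_id=v.variant_id, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
            dosages=np.asarray(v.dosages, dtype=float)[idx], maf=v.maf,
            imputation_r2=v.imputation_r2, genotyped=v.genotyped,
        )
        for v in variants
    ]
    scans = {}
    for protein in [c for c in conc_wide.columns if c in assoc.TRANSFORMS]:
        y = assoc.transform_concentration(protein, merged[protein].to_numpy())
        scans[protein] = gwas.gwas_scan(y, sub_variants, cov)
    return scans


def one_sample_mr(pheno: pd.DataFrame, conc_wide: pd.DataFrame, variants,
                  p_threshold: float = gwas.GENOME_WIDE_P, r2_clump: float = 0.001,
                  maf_min: float = 0.01, rsq_min: float = 0.3) -> dict:
    """One-sample design: exposure associations in controls, outcome
    associations from the cohort's covariate-adjusted logistic GWAS."""
    kept, _ = gwas.filter_variants(variants, maf_min=maf_min, rsq_min=rsq_min)
    scans = exposure_scans(pheno, conc_wide, kept, controls_only=True)
    controls = pheno["status"].to_numpy() == 0
    ld = gwas.dosage_ld_source([
        gwas.VariantRecord(
            variant_id=v.variant_id, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
            dosages=np.asarray(v.dosages, dtype=float)[controls], maf=v.maf,
        )
        for v in kept
    ])
    index_ids = {
        protein: gwas.clump(stats_df, ld, p_threshold=p_threshold, r2_cutoff=r2_clump)
        for protein, stats_df in scans.items()
    }
    # outcome logistic fits only for the variants actually instrumenting a protein
    needed = set().union(*index_ids.values()) if index_ids else set()
    cov = pheno[COVARIATES].to_numpy(dtype=float)
    outcome = gwas.logistic_gwas(
        pheno["status"].to_numpy(), [v for v in kept if v.variant_id in needed], cov
    )
    results = {}
    for protein, stats_df in scans.items():
        ids = index_ids[protein]
        if not ids:
            results[protein] = mr.MREstimate(protein=protein, method="none",
                                             sample_design="one-sample")
            continue
        exp = stats_df[stats_df["variant_id"].isin(ids)]
        results[protein] = mr.mr_from_summary(exp, outcome, protein=protein,
                                              design="one-sample")
    return results


def analyze_cohort(pheno: pd.DataFrame, transitions: pd.DataFrame, variants,
                   r2_clump: float = 0.001) -> dict:
    """quantify -> case-control association -> pQTL scan -> clump -> MR.

    Returns the measured concentration table, the per-protein association
    table (transform-scale beta and per-SD OR), and the one-sample MR
    estimates.
    """
    conc_wide = quantify_cohort(transitions)
    assoc_table = assoc.association_table(pheno, conc_wide.melt(
        id_vars="sample_id", var_name="protein", value_name="conc_nM"))
    mr_results = one_sample_mr(pheno, conc_wide, variants)
    return {"conc": conc_wide, "association": assoc_table, "mr": mr_results}
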