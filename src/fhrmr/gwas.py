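"""Per-variant pQTL scans, linkage-disequilibrium statistics, and clumping.

The scan regresses a transformed protein concentration on each variant's
minor-allele dosage with sex, age and two principal components as
covariates, reporting the Wald test per variant.  Computationally the
covariates are projected out of both the trait and every dosage vector
first (Frisch-Waugh-Lovell), which makes the per-variant fits a single
matrix product while returning estimates identical to a full OLS refit.

LD between two biallelic loci is computed from unphased genotypes by an
EM estimate of the four haplotype frequencies (the double-heterozygote
phase ambiguity is the only missing information), yielding D, D' and r2.
Greedy p-value clumping then selects mutually independent index variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "LDResult",
    "filter_variants",
    "gwas_scan",
    "logistic_gwas",
    "ld_stats",
    "ld_r2_dosage",
    "dosage_ld_source",
    "clump",
    "read_vcf",
    "write_vcf",
]

GENOME_WIDE_P = 5e-8


@dataclass
class VariantRecord:
    """A biallelic variant with per-sample minor-allele dosages in [0, 2].

    ``imputation_r2`` is the imputation quality (1.0 and ``genotyped=True``
    for directly typed variants).  ``effect allele`` is the alt (minor)
    allele, matching 0/1/2 minor-allele dosage coding.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    dosages: np.ndarray
    maf: float = float("nan")
    imputation_r2: float = 1.0
    genotyped: bool = True

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if np.isnan(self.maf):
            freq = float(np.mean(self.dosages)) / 2.0
            self.maf = min(freq, 1.0 - freq)
        if not 0 <= self.maf <= 0.5:
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside [0, 0.5]")
        if not 0 <= self.imputation_r2 <= 1:
            raise ValueError(f"{self.variant_id}: imputation r2 outside [0, 1]")


@dataclass(frozen=True)
class LDResult:
    variant_a: str
    variant_b: str
    r2: float
    dprime: float
    d: float


def filter_variants(records, maf_min: float = 0.01, rsq_min: float = 0.3):
    """Variant QC: keep MAF >= ``maf_min`` and, for imputed variants,
    imputation R2 >= ``rsq_min`` (both boundaries inclusive).  Returns the
    retained records and counts removed per criterion."""
    kept, n_maf, n_rsq = [], 0, 0
    for rec in records:
        if rec.maf < maf_min:
            n_maf += 1
        elif not rec.genotyped and rec.imputation_r2 < rsq_min:
            n_rsq += 1
        else:
            kept.append(rec)
    counts = {"removed_maf": n_maf, "removed_imputation_r2": n_rsq, "kept": len(kept)}
    log.info("variant filter: %s", counts)
    return kept, counts


def gwas_scan(trait, variants, covariates=None) -> pd.DataFrame:
    """OLS Wald scan of a (transformed) trait over variants.

    ``variants`` is a list of VariantRecord; ``covariates`` an (n, k) array
    or DataFrame.  Complete cases on trait and covariates are used; each
    variant's dosage is the predictor of a model with intercept and
    covariates.  Monomorphic variants are skipped with a log entry.
    Returns variant_id, chrom, pos, effect_allele, beta, se, p, n, maf.
    """
    y = np.asarray(trait, dtype=float)
    n_all = len(y)
    parts = [np.ones((n_all, 1))]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        parts.append(cov.reshape(n_all, -1))
    C = np.hstack(parts)
    keep = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    y, C = y[keep], C[keep]
    n = len(y)
    G = np.column_stack([np.asarray(v.dosages, dtype=float)[keep] for v in variants])

    # residualise trait and dosages on the covariate block (FWL)
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gss = np.einsum("ij,ij->j", G_r, G_r)
    mono = gss <= 1e-12 * n
    for v, is_mono in zip(variants, mono):
        if is_mono:
            log.info("monomorphic variant %s skipped", v.variant_id)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (G_r.T @ y_r) / gss
        rss = y_r @ y_r - beta**2 * gss
        dof = n - C.shape[1] - 1
        se = np.sqrt(np.maximum(rss, 0.0) / dof / gss)
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    out = pd.DataFrame({
        "variant_id": [v.variant_id for v in variants],
        "chrom": [v.chrom for v in variants],
        "pos": [v.pos for v in variants],
        "effect_allele": [v.alt for v in variants],
        "other_allele": [v.ref for v in variants],
        "beta": beta, "se": se, "p": p, "n": n,
        "maf": [v.maf for v in variants],
    })
    return out[~mono].reset_index(drop=True)


def logistic_gwas(status, variants, covariates=None) -> pd.DataFrame:
    """Per-variant logistic regression of case status on dosage (log-OR
    scale), covariate adjusted; the outcome arm of a one-sample design."""
    from .assoc import logistic_assoc

    rows = []
    for v in variants:
        if np.var(v.dosages) <= 1e-12:
            log.info("monomorphic variant %s skipped", v.variant_id)
            continue
        res = logistic_assoc(status, v.dosages, covariates)
        rows.append({
            "variant_id": v.variant_id, "chrom": v.chrom, "pos": v.pos,
            "effect_allele": v.alt, "other_allele": v.ref,
            "beta": res.beta, "se": res.se, "p": res.p, "n": res.n_used, "maf": v.maf,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def _em_haplotype_freqs(ga, gb, max_iter: int = 50, tol: float = 1e-10):
    """EM estimate of the (AB, Ab, aB, ab) haplotype frequencies from
    unphased genotype counts at two biallelic loci (A/B = allele coded 1)."""
    ga = np.round(np.asarray(ga, dtype=float)).astype(int)
    gb = np.round(np.asarray(gb, dtype=float)).astype(int)
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga == i) & (gb == j))
    n_hap = 2.0 * counts.sum()
    # start from linkage equilibrium
    pa = (counts * np.arange(3)[:, None]).sum() / n_hap
    pb = (counts * np.arange(3)[None, :]).sum() / n_hap
    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    ll_old = -np.inf
    n_dh = counts[1, 1]  # double heterozygotes: phase unknown
    for _ in range(max_iter):
        # expected haplotype counts; only (1,1) genotypes are ambiguous
        denom = f[0] * f[3] + f[1] * f[2]
        x = f[0] * f[3] / denom if denom > 0 else 0.5
        hap = np.zeros(4)
        hap[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + x * n_dh
        hap[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + (1 - x) * n_dh
        hap[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2] + (1 - x) * n_dh
        hap[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + x * n_dh
        f = hap / n_hap
        with np.errstate(divide="ignore"):
            ll = float(
                np.sum(counts * np.log(np.clip(_genotype_probs(f), 1e-300, None)))
            )
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return f


def _genotype_probs(f):
    """3x3 genotype-pair probabilities under HWE given haplotype freqs."""
    pAB, pAb, paB, pab = f
    probs = np.zeros((3, 3))
    probs[2, 2] = pAB**2
    probs[2, 1] = 2 * pAB * pAb
    probs[2, 0] = pAb**2
    probs[1, 2] = 2 * pAB * paB
    probs[1, 1] = 2 * (pAB * pab + pAb * paB)
    probs[1, 0] = 2 * pAb * pab
    probs[0, 2] = paB**2
    probs[0, 1] = 2 * paB * pab
    probs[0, 0] = pab**2
    return probs


def ld_stats(variant_a: VariantRecord, variant_b: VariantRecord) -> LDResult:
    """D, D' and r2 between two variants from unphased genotypes.

    Haplotype frequencies are estimated by EM over the double-heterozygote
    ambiguity (50 iterations or log-likelihood change < 1e-10).  Raises on
    monomorphic input, where LD is undefined.
    """
    ga, gb = variant_a.dosages, variant_b.dosages
    if np.var(ga) <= 1e-12 or np.var(gb) <= 1e-12:
        raise ValueError("LD undefined for a monomorphic variant")
    f = _em_haplotype_freqs(ga, gb)
    pAB = f[0]
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    d = pAB - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = d**2 / denom if denom > 0 else 0.0
    return LDResult(variant_a.variant_id, variant_b.variant_id, float(min(r2, 1.0)),
                    float(min(dprime, 1.0)), float(d))


def ld_r2_dosage(ga, gb) -> float:
    """Squared Pearson correlation of dosages: the composite-LD r2 used for
    clumping (equals the haplotype r2 when phase is unambiguous)."""
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    if np.var(ga) <= 1e-12 or np.var(gb) <= 1e-12:
        raise ValueError("LD undefined for a monomorphic variant")
    return float(np.corrcoef(ga, gb)[0, 1] ** 2)


def dosage_ld_source(variants):
    """An ``ld(id_a, id_b) -> r2`` callable backed by a reference panel's
    dosage vectors, for use with :func:`clump`."""
    table = {v.variant_id: np.asarray(v.dosages, dtype=float) for v in variants}

    def ld(a: str, b: str):
        if a not in table or b not in table:
            return None
        try:
            return ld_r2_dosage(table[a], table[b])
        except ValueError:
            return None

    return ld


def clump(stats_df: pd.DataFrame, ld, p_threshold: float = GENOME_WIDE_P,
          r2_cutoff: float = 0.001) -> list:
    """Greedy p-value clumping.

    Repeatedly take the remaining variant with the smallest p below
    ``p_threshold`` as an index variant and discard every variant with
    r2 >= ``r2_cutoff`` to it.  ``ld`` is a callable ``(id_a, id_b) -> r2``
    (None for unavailable pairs, treated as independent and logged) or a
    square DataFrame of r2.  Ties in p are broken by genomic position,
    then variant id.  Returns index variant ids in selection order.
    """
    if isinstance(ld, pd.DataFrame):
        mat = ld

        def ld_fn(a, b):
            if a in mat.index and b in mat.columns:
                return float(mat.loc[a, b])
            return None
    else:
        ld_fn = ld

    df = stats_df[stats_df["p"] < p_threshold].copy()
    sort_cols = [c for c in ("p", "pos", "variant_id") if c in df.columns]
    df = df.sort_values(sort_cols, kind="mergesort")
    remaining = list(df["variant_id"])
    index_variants = []
    while remaining:
        top = remaining.pop(0)
        index_variants.append(top)
        still = []
        for vid in remaining:
            r2 = ld_fn(top, vid)
            if r2 is None:
                log.warning("no LD for pair (%s, %s); treated as independent", top, vid)
                still.append(vid)
            elif r2 < r2_cutoff:
                still.append(vid)
        remaining = still
    return index_variants


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path) -> list:
    """Read variants from a VCF into VariantRecords.

    Dosage comes from the DS FORMAT field when present, else from GT allele
    counts.  MAF and imputation quality come from the INFO fields MAF and
    R2 when present (a variant is treated as genotyped when INFO/TYPED is
    set or no R2 is given).
    """
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    for var in vcf:
        fmts = var.FORMAT
        if "DS" in fmts:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            ds = np.where(gts < 0, np.nan, gts).sum(axis=1).astype(float)
        info = dict(var.INFO)
        r2 = float(info.get("R2", 1.0))
        genotyped = bool(info.get("TYPED", "R2" not in info))
        maf = float(info["MAF"]) if "MAF" in info else float("nan")
        records.append(VariantRecord(
            variant_id=var.ID or f"{var.CHROM}:{var.POS}",
            chrom=str(var.CHROM), pos=int(var.POS),
            ref=var.REF, alt=var.ALT[0] if var.ALT else ".",
            dosages=ds, maf=maf, imputation_r2=r2, genotyped=genotyped,
        ))
    return records


def write_vcf(variants, sample_ids, path):
    """Write VariantRecords as an uncompressed VCF with DS dosages."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the alt allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, sample_ids)) + "\n")
        for v in sorted(variants, key=lambda r: (str(r.chrom), r.pos)):
            info = f"MAF={v.maf:.6g};R2={v.imputation_r2:.6g}"
            if v.genotyped:
                info += ";TYPED"
            ds = "\t".join(f"{d:.3f}" for d in v.dosages)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tDS\t{ds}\n")
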