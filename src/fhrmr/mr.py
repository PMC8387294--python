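"""Mendelian randomization of protein concentrations on disease risk.

Each genetic instrument contributes a Wald ratio: its log-OR association
with disease divided by its association with the (transformed) protein
concentration, with a first-order delta-method standard error.  Multiple
instruments are pooled by fixed-effect inverse-variance weighting, with
Cochran's Q and I2 quantifying heterogeneity among the single-instrument
estimates.  Instrument strength is summarised as the proportion of protein
variance explained, recovered from the exposure p-value and sample size by
inverting the F statistic of the exposure regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "InstrumentEstimate",
    "MREstimate",
    "WeakInstrumentError",
    "iv_strength_r2",
    "wald_ratio",
    "ivw_fixed",
    "heterogeneity",
    "harmonize",
    "run_mr",
    "mr_from_summary",
]

Z95 = 1.959963984540054
GENOME_WIDE_P = 5e-8
PALINDROMIC_MAF_MAX = 0.42

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class WeakInstrumentError(ValueError):
    """Exposure association is zero: the Wald ratio is undefined."""


@dataclass(frozen=True)
class InstrumentEstimate:
    """Harmonized per-instrument summary statistics.

    ``bx``/``sx`` are the exposure association (transformed protein scale),
    ``by``/``sy`` the outcome association (log-OR scale), both referring to
    the same effect allele.
    """

    variant_id: str
    bx: float
    sx: float
    by: float
    sy: float
    cis_trans: str = ""
    p_exposure: float = float("nan")
    n_exposure: int = 0
    effect_allele: str = ""

    def __post_init__(self):
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError(f"{self.variant_id}: standard errors must be > 0")


@dataclass(frozen=True)
class MREstimate:
    protein: str
    method: str  # "wald" | "ivw" | "none"
    theta: float = float("nan")
    se: float = float("nan")
    or_point: float = float("nan")
    or_ci95: tuple = (float("nan"), float("nan"))
    q_stat: float = float("nan")
    df: int = 0
    i2_percent: float = float("nan")
    n_iv: int = 0
    sample_design: str = ""
    instruments: tuple = ()
    iv_r2: tuple = ()

    @property
    def p(self) -> float:
        if not np.isfinite(self.theta):
            return float("nan")
        return float(2.0 * stats.norm.sf(abs(self.theta) / self.se))


def iv_strength_r2(p_exposure: float, n: int) -> float:
    """Proportion of trait variance explained by an instrument, from its
    exposure p-value and sample size.

    The two-sided p of a single-predictor Wald test maps to an F statistic
    with (1, n-2) df; R2 = F / (F + n - 2).  The quantile is obtained via
    the Student-t relation F = t^2, which stays finite down to p ~ 1e-300
    where the direct F inversion overflows.
    """
    if not 0 < p_exposure <= 1:
        raise ValueError("p_exposure must be in (0, 1]")
    if n <= 2:
        raise ValueError("n must exceed 2")
    t = stats.t.isf(p_exposure / 2.0, n - 2)
    f = t * t
    if not math.isfinite(f):
        raise ValueError("p too small to invert at double precision")
    return float(f / (f + n - 2))


def wald_ratio(iv: InstrumentEstimate):
    """Single-instrument causal estimate: theta = by / bx with the
    first-order delta-method SE, sy / |bx|."""
    if iv.bx == 0:
        raise WeakInstrumentError(f"{iv.variant_id}: exposure beta is zero")
    return iv.by / iv.bx, iv.sy / abs(iv.bx)


def heterogeneity(ivs, pooled_theta: float):
    """Cochran's Q over single-instrument Wald ratios, with df = k - 1 and
    I2 = max(0, (Q - df) / Q) * 100.  Requires >= 2 instruments."""
    if len(ivs) < 2:
        return float("nan"), 0, float("nan")
    thetas, ses = zip(*(wald_ratio(iv) for iv in ivs))
    w = 1.0 / np.asarray(ses) ** 2
    q = float(np.sum(w * (np.asarray(thetas) - pooled_theta) ** 2))
    df = len(ivs) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, i2


def ivw_fixed(ivs, protein: str = "", design: str = "") -> MREstimate:
    """Fixed-effect inverse-variance weighted pooling of Wald ratios.

    Weights are the inverse squared delta-method SEs; the pooled SE is
    (sum of weights)^(-1/2).  A single instrument reduces exactly to its
    Wald ratio.  The OR CI is exp(theta +/- 1.96 se).
    """
    ivs = list(ivs)
    if not ivs:
        raise ValueError("need at least one instrument")
    thetas, ses = zip(*(wald_ratio(iv) for iv in ivs))
    w = 1.0 / np.asarray(ses) ** 2
    theta = float(np.sum(w * np.asarray(thetas)) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q, df, i2 = heterogeneity(ivs, theta)
    return MREstimate(
        protein=protein,
        method="ivw" if len(ivs) > 1 else "wald",
        theta=theta, se=se,
        or_point=float(np.exp(theta)),
        or_ci95=(float(np.exp(theta - Z95 * se)), float(np.exp(theta + Z95 * se))),
        q_stat=q, df=df, i2_percent=i2,
        n_iv=len(ivs), sample_design=design, instruments=tuple(ivs),
        iv_r2=tuple(_instrument_r2(iv) for iv in ivs),
    )


def _instrument_r2(iv: InstrumentEstimate) -> float:
    """Per-instrument variance explained.  Inverts the exposure p-value
    when representable; when p has underflowed to zero the equivalent
    t-ratio route F = (bx/sx)^2 is used instead."""
    if iv.n_exposure <= 2:
        return float("nan")
    if np.isfinite(iv.p_exposure) and 0 < iv.p_exposure <= 1:
        return iv_strength_r2(iv.p_exposure, iv.n_exposure)
    f = (iv.bx / iv.sx) ** 2
    return float(f / (f + iv.n_exposure - 2))


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(exp_row: dict, out_row: dict):
    """Align an outcome association to the exposure's effect allele.

    Rows need effect_allele/other_allele and beta; the outcome beta is
    negated when its alleles are swapped relative to the exposure.
    Palindromic variants with MAF > 0.42 are dropped (returns None) since
    the strand cannot be resolved from allele labels.  Returns the aligned
    outcome beta or None when the variant must be dropped.
    """
    ea_x, oa_x = exp_row["effect_allele"].upper(), exp_row["other_allele"].upper()
    ea_y, oa_y = out_row["effect_allele"].upper(), out_row["other_allele"].upper()
    maf = exp_row.get("maf", float("nan"))
    if _is_palindromic(ea_x, oa_x) and (not np.isfinite(maf) or maf > PALINDROMIC_MAF_MAX):
        log.warning("palindromic variant %s with MAF %.3g dropped", exp_row.get("variant_id"), maf)
        return None
    if (ea_y, oa_y) == (ea_x, oa_x):
        return float(out_row["beta"])
    if (ea_y, oa_y) == (oa_x, ea_x):
        return -float(out_row["beta"])
    log.warning("allele mismatch for %s; variant dropped", exp_row.get("variant_id"))
    return None


def mr_from_summary(exposure: pd.DataFrame, outcome: pd.DataFrame, protein: str = "",
                    design: str = "") -> MREstimate:
    """Build harmonized instruments from exposure and outcome summary-stat
    frames (joined on variant_id) and pool them.

    Expected columns: variant_id, effect_allele, other_allele, beta, se
    (exposure also p, n; optional maf, cis_trans).
    """
    out_by_id = outcome.set_index("variant_id")
    ivs = []
    for row in exposure.to_dict("records"):
        vid = row["variant_id"]
        if vid not in out_by_id.index:
            log.warning("no outcome stats for instrument %s; dropped", vid)
            continue
        orow = out_by_id.loc[vid].to_dict()
        orow.setdefault("effect_allele", row["effect_allele"])
        orow.setdefault("other_allele", row["other_allele"])
        by = harmonize(row, orow)
        if by is None:
            continue
        ivs.append(InstrumentEstimate(
            variant_id=vid, bx=float(row["beta"]), sx=float(row["se"]),
            by=by, sy=float(orow["se"]),
            cis_trans=str(row.get("cis_trans", "")),
            p_exposure=float(row.get("p", float("nan"))),
            n_exposure=int(row.get("n", 0)),
            effect_allele=row["effect_allele"],
        ))
    if not ivs:
        return MREstimate(protein=protein, method="none", sample_design=design)
    return ivw_fixed(ivs, protein=protein, design=design)


def run_mr(exposure_stats: dict, outcome_stats: pd.DataFrame, ld,
           design: str = "one-sample", p_threshold: float = GENOME_WIDE_P,
           r2_clump: float = 0.001) -> dict:
    """Full per-protein MR: clump each exposure GWAS to independent
    genome-wide-significant instruments, harmonize against the outcome
    stats, and pool.

    ``exposure_stats`` maps protein -> summary-stat DataFrame (gwas_scan
    format); ``outcome_stats`` is a single DataFrame on the log-OR scale
    (one-sample: the cohort's case-control scan; two-sample: external
    summary statistics).  ``ld`` is passed to :func:`fhrmr.gwas.clump`.
    Proteins with no significant instrument yield method="none".
    """
    from .gwas import clump

    results = {}
    for protein, stats_df in exposure_stats.items():
        index_ids = clump(stats_df, ld, p_threshold=p_threshold, r2_cutoff=r2_clump)
        if not index_ids:
            results[protein] = MREstimate(protein=protein, method="none", sample_design=design)
            continue
        exp = stats_df[stats_df["variant_id"].isin(index_ids)]
        results[protein] = mr_from_summary(exp, outcome_stats, protein=protein, design=design)
    return results
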