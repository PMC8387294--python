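"""Synthetic cohorts with the statistical structure the pipeline assumes.

Generates, from one seeded configuration: LD-blocked genotypes (a
latent-Gaussian threshold haplotype model with equicorrelation rho within
a block), protein concentrations driven by cis pQTL effects plus Gaussian
noise on each protein's normalising transform scale, case-control disease
status from a logistic model on standardised log concentrations, and noisy
light/heavy SRM transition peak areas.  The realised causal parameters are
returned as a SimTruth for parameter-recovery tests.

Defaults mirror the AMD case-control study the pipeline targets: 352
cases / 252 controls; sex ~ Bernoulli(0.42), age ~ Normal(74.5, 8),
PC1/PC2 ~ Normal(0, 1); one cis pQTL per FHR protein with variance
explained 0.53/0.44/0.35/0.25/0.15 (FHR-1..FHR-5) and none for FH or
FHL-1; per-SD-of-log disease odds ratios 1.01/1.35/1.81/1.66/1.54/1.27/
1.38 (FH, FHL-1, FHR-1..5); SRM noise CV 15%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .assoc import TRANSFORMS
from .gwas import VariantRecord, write_vcf
from .reference import CONTROL_MEAN_NM, DEFAULT_SCHEME, PEPTIDE_STANDARDS, PROTEINS
from .srm import compute_spike_concentration

__all__ = [
    "LDBlock",
    "PqtlEffect",
    "SimConfig",
    "SimTruth",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_proteins",
    "simulate_case_control",
    "simulate_srm_peaks",
    "simulate_cohort",
    "write_cohort",
]

#: Marginal SD of each protein on its transform scale, chosen to match the
#: published control-group concentration spread (CI half-width * sqrt(n)).
MARGINAL_SD_TRANSFORMED = {
    "FH": 2.85,
    "FHL-1": 0.27,
    "FHR-1": 14.2,
    "FHR-2": 1.35,
    "FHR-3": 1.98,
    "FHR-4": 2.05,
    "FHR-5": 0.32,
}

#: Published per-SD-of-log odds ratios of advanced disease (case-control).
DEFAULT_OR_PER_SD = {
    "FH": 1.01,
    "FHL-1": 1.35,
    "FHR-1": 1.81,
    "FHR-2": 1.66,
    "FHR-3": 1.54,
    "FHR-4": 1.27,
    "FHR-5": 1.38,
}

#: Published instrument-strength R2 of the cis pQTL per FHR protein.
DEFAULT_PQTL_R2 = {"FHR-1": 0.53, "FHR-2": 0.44, "FHR-3": 0.35, "FHR-4": 0.25, "FHR-5": 0.15}


@dataclass(frozen=True)
class LDBlock:
    name: str
    n_variants: int
    rho: float
    chrom: str = "1"

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError(f"block {self.name}: rho must be in [0, 1)")
        if self.n_variants < 1:
            raise ValueError(f"block {self.name}: need >= 1 variant")


@dataclass(frozen=True)
class PqtlEffect:
    """A causal variant -> protein effect.  Either ``beta`` (transform-scale
    slope per allele) or ``r2`` (target variance explained, from which beta
    is derived given the protein's marginal SD) must be set."""

    variant_id: str
    protein: str
    beta: float = float("nan")
    r2: float = float("nan")


def _default_blocks():
    blocks = [LDBlock(name=p, n_variants=4, rho=0.8, chrom="1") for p in DEFAULT_PQTL_R2]
    blocks += [LDBlock(name=f"null{i}", n_variants=4, rho=0.5, chrom=str(i + 2)) for i in (0, 1)]
    return tuple(blocks)


def _default_pqtl():
    return tuple(
        PqtlEffect(variant_id=f"sim_{p}_1", protein=p, r2=r2) for p, r2 in DEFAULT_PQTL_R2.items()
    )


@dataclass(frozen=True)
class SimConfig:
    """Full generative configuration.  ``seed`` is mandatory; every output
    is a pure function of (config, seed)."""

    seed: int
    genome_seed: int = None  # fixes the variant MAF draw; defaults to seed
    n_cases: int = 352
    n_controls: int = 252
    blocks: tuple = field(default_factory=_default_blocks)
    maf_range: tuple = (0.1, 0.5)
    pqtl: tuple = field(default_factory=_default_pqtl)
    marginal_sd: tuple = tuple(sorted(MARGINAL_SD_TRANSFORMED.items()))
    or_per_sd: tuple = tuple(sorted(DEFAULT_OR_PER_SD.items()))
    covariate_effects: tuple = ()  # (protein, (b_sex, b_age, b_pc1, b_pc2))
    disease_intercept: float = -2.2
    sex_p: float = 0.42
    age_mean: float = 74.5
    age_sd: float = 8.0
    srm_noise_cv: float = 0.15
    corrupt_qualifier_rate: float = 0.0
    heavy_area: float = 5e6
    chunk_size: int = 2048
    max_chunks: int = 200

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


@dataclass
class SimTruth:
    """Realised causal parameters, stored for recovery tests."""

    variant_maf: dict
    pqtl_beta: dict            # protein -> {variant_id: beta}
    noise_sd: dict             # protein -> transform-scale noise SD
    intercept: dict            # protein -> transform-scale intercept
    total_sd: dict             # protein -> transform-scale marginal SD
    log_mu: dict               # protein -> analytic mean of log concentration
    log_sd: dict               # protein -> analytic SD of log concentration
    gamma_per_sd_log: dict     # protein -> disease log-OR per SD of log conc
    theta_transformed: dict    # protein -> implied log-OR per transform unit
    disease_intercept: float = float("nan")
    prevalence: float = float("nan")


@dataclass
class SimulatedCohort:
    config: SimConfig
    pheno: pd.DataFrame        # sample_id, status, sex, age, pc1, pc2
    conc: pd.DataFrame         # sample_id x protein, true nM
    variants: list             # VariantRecord with cohort dosages
    transitions: pd.DataFrame  # SRM transition report (long format)
    truth: SimTruth


# ---------------------------------------------------------------------------
# genotypes


def _build_variant_defs(config: SimConfig, rng):
    """Assign each variant an id, position and MAF (uniform in maf_range)."""
    defs = []
    for b, block in enumerate(config.blocks):
        base_pos = 196_000_000 + b * 1_000_000 if block.chrom == "1" else 50_000_000
        for j in range(block.n_variants):
            defs.append({
                "variant_id": f"sim_{block.name}_{j + 1}",
                "block": block.name,
                "rho": block.rho,
                "chrom": block.chrom,
                "pos": base_pos + j * 5_000,
                "maf": float(rng.uniform(*config.maf_range)),
            })
    return defs


def simulate_genotypes(variant_defs, n_samples: int, rng) -> np.ndarray:
    """Diploid dosages (n_samples x n_variants) from the latent-Gaussian
    threshold haplotype model: within a block, haplotype latents share a
    common factor with loading sqrt(rho); an allele is carried when the
    latent falls below the MAF quantile.  Haplotypes are paired at random
    (two per individual), so HWE holds marginally."""
    n_hap = 2 * n_samples
    cols = []
    by_block = {}
    for d in variant_defs:
        by_block.setdefault(d["block"], []).append(d)
    for block_defs in by_block.values():
        rho = block_defs[0]["rho"]
        u = rng.standard_normal(n_hap)[:, None]
        eps = rng.standard_normal((n_hap, len(block_defs)))
        z = np.sqrt(rho) * u + np.sqrt(1 - rho) * eps
        thresh = ndtri([d["maf"] for d in block_defs])
        alleles = (z < thresh).astype(np.int8)
        cols.append(alleles)
    haps = np.hstack(cols)
    return (haps[0::2] + haps[1::2]).astype(float)


# ---------------------------------------------------------------------------
# proteins


def _as_dict(pairs):
    return dict(pairs)


def _assay_variance_transform_scale(protein, intercept, marginal_sd, cv):
    """Variance contributed by the multiplicative assay noise (CV ``cv`` on
    the concentration) on the protein's transform scale: exact for the log
    transform, second-moment delta approximation otherwise."""
    if cv <= 0:
        return 0.0
    kind = TRANSFORMS[protein]
    if kind == "log":
        return float(np.log1p(cv**2))
    second_moment = intercept**2 + marginal_sd**2  # E[t^2] on the transform scale
    if kind == "sqrt":
        return (cv / 2.0) ** 2 * second_moment  # d sqrt(c) = sqrt(c)/2 * dc/c
    return cv**2 * second_moment


def _resolve_effects(config: SimConfig, variant_defs):
    """Per-protein causal betas and biological noise SDs.

    ``marginal_sd`` describes the *measured* trait: the budget
    SD^2 = genetic + biological + assay is honoured by deriving allele
    effects from the target r2 (beta = sqrt(r2 * SD^2 / (2 maf (1-maf))))
    and assigning the remainder, net of the assay variance implied by
    ``srm_noise_cv``, to biological noise.  The causal variant then
    explains r2 of the measured-concentration variance, matching how
    published instrument strengths are computed from assay data.
    """
    maf = {d["variant_id"]: d["maf"] for d in variant_defs}
    sd = _as_dict(config.marginal_sd)
    intercepts = _transform_intercepts()
    betas = {p: {} for p in PROTEINS}
    explained = dict.fromkeys(PROTEINS, 0.0)
    for eff in config.pqtl:
        if eff.variant_id not in maf:
            raise ValueError(f"pqtl effect references unknown variant {eff.variant_id}")
        v = 2 * maf[eff.variant_id] * (1 - maf[eff.variant_id])
        if np.isfinite(eff.beta):
            beta = eff.beta
        elif np.isfinite(eff.r2):
            beta = np.sqrt(eff.r2 * sd[eff.protein] ** 2 / v)
        else:
            raise ValueError(f"pqtl effect for {eff.protein} needs beta or r2")
        betas[eff.protein][eff.variant_id] = float(beta)
        explained[eff.protein] += beta**2 * v
    noise_sd = {}
    for p in PROTEINS:
        assay = _assay_variance_transform_scale(p, intercepts[p], sd[p], config.srm_noise_cv)
        resid = sd[p] ** 2 - explained[p] - assay
        if resid <= 0:
            raise ValueError(f"{p}: genetic plus assay variance exceeds the marginal variance")
        noise_sd[p] = float(np.sqrt(resid))
    return betas, noise_sd


def _transform_intercepts():
    """Transform-scale intercepts matching the published control means."""
    out = {}
    for p, mean_nm in CONTROL_MEAN_NM.items():
        kind = TRANSFORMS[p]
        out[p] = float({"sqrt": np.sqrt(mean_nm), "log": np.log(mean_nm), "identity": mean_nm}[kind])
    return out


def _log_scale_moments(protein, intercept, total_sd):
    """Analytic (delta-method) mean and SD of log concentration given the
    transform-scale Normal(intercept, total_sd)."""
    kind = TRANSFORMS[protein]
    if kind == "log":
        return intercept, total_sd
    if kind == "sqrt":
        return 2 * np.log(intercept), 2 * total_sd / intercept
    return np.log(intercept), total_sd / intercept


def simulate_proteins(dosages, variant_defs, covariates, config: SimConfig, rng,
                      betas=None, noise_sd=None, intercepts=None):
    """Transform-scale protein values and back-transformed concentrations.

    transformed = intercept + sum beta * (dosage - 2 maf) + covariate terms
    + Normal(0, noise_sd); concentrations below zero after back-transform
    are truncated at 0 (counted).
    """
    if betas is None or noise_sd is None:
        betas, noise_sd = _resolve_effects(config, variant_defs)
    if intercepts is None:
        intercepts = _transform_intercepts()
    n = dosages.shape[0]
    vid_col = {d["variant_id"]: i for i, d in enumerate(variant_defs)}
    maf = {d["variant_id"]: d["maf"] for d in variant_defs}
    cov_eff = _as_dict(config.covariate_effects)
    transformed = {}
    conc = {}
    n_truncated = 0
    for p in PROTEINS:
        t = np.full(n, intercepts[p])
        for vid, beta in betas[p].items():
            t = t + beta * (dosages[:, vid_col[vid]] - 2 * maf[vid])
        if p in cov_eff:
            t = t + np.asarray(covariates, dtype=float) @ np.asarray(cov_eff[p], dtype=float)
        t = t + rng.normal(0.0, noise_sd[p], size=n)
        kind = TRANSFORMS[p]
        if kind == "sqrt":
            n_truncated += int(np.sum(t < 0))
            c = np.maximum(t, 0.0) ** 2
        elif kind == "log":
            c = np.exp(t)
        else:
            n_truncated += int(np.sum(t < 0))
            c = np.maximum(t, 0.0)
        transformed[p] = t
        conc[p] = c
    return pd.DataFrame(conc), pd.DataFrame(transformed), n_truncated


# ---------------------------------------------------------------------------
# disease


def simulate_case_control(conc: pd.DataFrame, truth: SimTruth, config: SimConfig, rng):
    """Bernoulli disease status from the logistic model on standardised log
    concentrations: logit P = intercept + sum gamma_p z_p with z_p the log
    concentration standardised by the analytic population moments."""
    logit = np.full(len(conc), config.disease_intercept)
    for p, gamma in truth.gamma_per_sd_log.items():
        if gamma == 0.0:
            continue
        with np.errstate(divide="ignore"):
            logc = np.log(np.clip(conc[p].to_numpy(), 1e-12, None))
        z = (logc - truth.log_mu[p]) / truth.log_sd[p]
        logit = logit + gamma * z
    return (rng.uniform(size=len(conc)) < expit(logit)).astype(int)


# ---------------------------------------------------------------------------
# SRM peaks


def simulate_srm_peaks(conc: pd.DataFrame, sample_ids, config: SimConfig, rng,
                       peptide_specs=PEPTIDE_STANDARDS, scheme=DEFAULT_SCHEME,
                       batch_size: int = 20) -> pd.DataFrame:
    """Long-format transition report with multiplicative lognormal noise.

    The light/heavy ratio of a sample x peptide carries a shared lognormal
    factor with CV ``srm_noise_cv`` (mean 1) plus a small per-transition
    jitter (CV/10), so the three transitions stay concordant; with
    probability ``corrupt_qualifier_rate`` one qualifier's light area is
    tripled, which the qualifier check should flag.
    """
    cv = config.srm_noise_cv
    s = np.sqrt(np.log1p(cv**2))
    s_jit = np.sqrt(np.log1p((cv / 10.0) ** 2))
    rel = np.array([1.0, 0.6, 0.3])
    n = len(conc)
    sample_ids = np.asarray(sample_ids)
    batches = np.arange(n) // batch_size + 1
    frames = []
    for spec in peptide_specs:
        prot = spec.protein
        spike = compute_spike_concentration(spec, scheme)
        ratios = conc[prot].to_numpy() / spike
        shared = rng.lognormal(-s**2 / 2, s, size=n) if cv > 0 else np.ones(n)
        corrupt = rng.uniform(size=n) < config.corrupt_qualifier_rate
        corrupt_t = rng.integers(1, 3, size=n)  # a qualifier slot (1 or 2)
        heavy = config.heavy_area * rel[None, :] * rng.lognormal(0, 0.2, size=(n, 3))
        jit = rng.lognormal(-s_jit**2 / 2, s_jit, size=(n, 3)) if cv > 0 else np.ones((n, 3))
        light = heavy * (ratios * shared)[:, None] * jit
        light[corrupt, corrupt_t[corrupt]] *= 3.0
        # interleave light/heavy rows per sample x transition
        area = np.stack([light, heavy], axis=2).reshape(-1)  # n*3*2
        frames.append(pd.DataFrame({
            "sample_id": np.repeat(sample_ids, 6),
            "batch": np.repeat(batches, 6),
            "peptide": prot,
            "transition_id": np.tile(np.repeat([f"{prot}_t{t + 1}" for t in range(3)], 2), n),
            "isotope": np.tile(["light", "heavy"], 3 * n),
            "area": area,
            "rt_min": np.tile(np.repeat(10.0 + 2.0 * np.arange(3), 2), n),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# orchestration


def _build_truth(config: SimConfig, variant_defs, betas, noise_sd, intercepts) -> SimTruth:
    sd = _as_dict(config.marginal_sd)
    ors = _as_dict(config.or_per_sd)
    log_mu, log_sd, theta_t = {}, {}, {}
    for p in PROTEINS:
        mu, sdev = _log_scale_moments(p, intercepts[p], sd[p])
        log_mu[p], log_sd[p] = float(mu), float(sdev)
        gamma = float(np.log(ors.get(p, 1.0)))
        # implied slope per transform unit: for log proteins d z/d t = 1/log_sd
        kind = TRANSFORMS[p]
        if kind == "log":
            theta_t[p] = gamma / log_sd[p]
        elif kind == "sqrt":
            theta_t[p] = gamma / log_sd[p] * 2.0 / intercepts[p]  # local, at the mean
        else:
            theta_t[p] = gamma / log_sd[p] / intercepts[p]
    return SimTruth(
        variant_maf={d["variant_id"]: d["maf"] for d in variant_defs},
        pqtl_beta=betas, noise_sd=noise_sd, intercept=intercepts,
        total_sd={p: sd[p] for p in PROTEINS},
        log_mu=log_mu, log_sd=log_sd,
        gamma_per_sd_log={p: float(np.log(ors.get(p, 1.0))) for p in PROTEINS},
        theta_transformed=theta_t,
        disease_intercept=config.disease_intercept,
    )


def simulate_cohort(config: SimConfig, with_srm: bool = True) -> SimulatedCohort:
    """Draw a full case-control cohort under the configuration.

    Individuals are sampled from the population model in chunks and
    retained until the requested case and control counts are reached
    (error after ``max_chunks`` chunks if the disease model cannot supply
    them).  Returns phenotypes, true concentrations, cohort genotypes, the
    SRM transition report, and the SimTruth.
    """
    rng = np.random.default_rng(config.seed)
    genome_rng = np.random.default_rng(
        config.seed if config.genome_seed is None else config.genome_seed
    )
    variant_defs = _build_variant_defs(config, genome_rng)
    betas, noise_sd = _resolve_effects(config, variant_defs)
    intercepts = _transform_intercepts()
    truth = _build_truth(config, variant_defs, betas, noise_sd, intercepts)

    kept_dos, kept_cov, kept_conc, kept_status = [], [], [], []
    n_cases = n_controls = 0
    n_drawn = 0
    n_case_drawn = 0
    for _ in range(config.max_chunks):
        if n_cases >= config.n_cases and n_controls >= config.n_controls:
            break
        m = config.chunk_size
        dos = simulate_genotypes(variant_defs, m, rng)
        cov = np.column_stack([
            (rng.uniform(size=m) < config.sex_p).astype(float),
            rng.normal(config.age_mean, config.age_sd, size=m),
            rng.standard_normal(m),
            rng.standard_normal(m),
        ])
        conc, _, _ = simulate_proteins(dos, variant_defs, cov, config, rng, betas, noise_sd, intercepts)
        status = simulate_case_control(conc, truth, config, rng)
        n_drawn += m
        n_case_drawn += int(status.sum())
        for want, flag in ((config.n_cases, 1), (config.n_controls, 0)):
            have = n_cases if flag else n_controls
            idx = np.where(status == flag)[0][: want - have]
            if len(idx) == 0:
                continue
            kept_dos.append(dos[idx])
            kept_cov.append(cov[idx])
            kept_conc.append(conc.iloc[idx])
            kept_status.append(status[idx])
            if flag:
                n_cases += len(idx)
            else:
                n_controls += len(idx)
    if n_cases < config.n_cases or n_controls < config.n_controls:
        raise RuntimeError(
            f"could not reach {config.n_cases}/{config.n_controls} cases/controls "
            f"after {n_drawn} draws; adjust disease_intercept"
        )
    dosages = np.vstack(kept_dos)
    covs = np.vstack(kept_cov)
    conc = pd.concat(kept_conc, ignore_index=True)
    status = np.concatenate(kept_status)
    truth.prevalence = float(n_case_drawn) / n_drawn if n_drawn else float("nan")

    order = np.argsort(-status, kind="stable")  # cases first, stable within group
    dosages, covs, status = dosages[order], covs[order], status[order]
    conc = conc.iloc[order].reset_index(drop=True)
    sample_ids = [f"S{i + 1:04d}" for i in range(len(status))]

    pheno = pd.DataFrame({
        "sample_id": sample_ids, "status": status,
        "sex": covs[:, 0].astype(int), "age": covs[:, 1],
        "pc1": covs[:, 2], "pc2": covs[:, 3],
    })
    conc.insert(0, "sample_id", sample_ids)

    variants = [
        VariantRecord(
            variant_id=d["variant_id"], chrom=d["chrom"], pos=d["pos"],
            ref="A", alt="G", dosages=dosages[:, i], maf=float("nan"),
            imputation_r2=1.0, genotyped=True,
        )
        for i, d in enumerate(variant_defs)
    ]
    transitions = (
        simulate_srm_peaks(conc.drop(columns="sample_id"), sample_ids, config, rng)
        if with_srm else pd.DataFrame()
    )
    return SimulatedCohort(config=config, pheno=pheno, conc=conc,
                           variants=variants, transitions=transitions, truth=truth)


def write_cohort(cohort: SimulatedCohort, outdir):
    """Write a simulated cohort as VCF + CSVs + truth JSON."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(cohort.variants, cohort.pheno["sample_id"], out / "genotypes.vcf")
    cohort.pheno.to_csv(out / "phenotypes.csv", index=False)
    cohort.conc.to_csv(out / "concentrations_true.csv", index=False)
    if len(cohort.transitions):
        cohort.transitions.to_csv(out / "transitions.csv", index=False)
    t = cohort.truth
    with open(out / "truth.json", "w") as fh:
        json.dump({
            "variant_maf": t.variant_maf, "pqtl_beta": t.pqtl_beta,
            "noise_sd": t.noise_sd, "intercept": t.intercept,
            "log_mu": t.log_mu, "log_sd": t.log_sd,
            "gamma_per_sd_log": t.gamma_per_sd_log,
            "theta_transformed": t.theta_transformed,
            "disease_intercept": t.disease_intercept,
            "prevalence": t.prevalence,
        }, fh, indent=1)
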