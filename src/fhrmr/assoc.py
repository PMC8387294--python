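"""Case-control association of protein concentrations with disease.

Protein concentrations are first transformed towards normality (a fixed
per-protein map: square root for FH, FHR-2, FHR-3, FHR-4; natural log for
FHL-1 and FHR-5; identity for FHR-1, which is already near-normal).  The
case-control difference on the transformed scale is tested with a
covariate-adjusted linear model (Wald test), and the odds ratio of disease
per one standard deviation of log concentration comes from a logistic
model with the same covariates.  The correlation structure of the seven
proteins is summarised in controls with pairwise Pearson coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TRANSFORMS",
    "AssocResult",
    "CollinearityError",
    "ConvergenceError",
    "transform_concentration",
    "linear_assoc",
    "logistic_assoc",
    "logistic_or_per_sd",
    "correlation_matrix",
    "summarize_cohort",
    "association_table",
]

TRANSFORMS = {
    "FH": "sqrt",
    "FHL-1": "log",
    "FHR-1": "identity",
    "FHR-2": "sqrt",
    "FHR-3": "sqrt",
    "FHR-4": "sqrt",
    "FHR-5": "log",
}

COVARIATES = ["sex", "age", "pc1", "pc2"]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class CollinearityError(ValueError):
    """Design matrix is rank deficient; message names the collinear columns."""


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


@dataclass(frozen=True)
class AssocResult:
    protein: str
    beta: float
    se: float
    p: float
    n_used: int
    or_point: float = float("nan")
    or_ci95: tuple = (float("nan"), float("nan"))


def transform_concentration(protein: str, conc):
    """Normalising transform of a concentration (scalar or array), per the
    fixed per-protein map.  log(0) and sqrt of negatives become NaN with a
    warning rather than raising."""
    if protein not in TRANSFORMS:
        raise KeyError(f"unknown protein {protein!r}")
    kind = TRANSFORMS[protein]
    arr = np.asarray(conc, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if kind == "sqrt":
            out = np.sqrt(arr)
        elif kind == "log":
            out = np.log(arr)
            out = np.where(np.isneginf(out), np.nan, out)
        else:
            out = arr + 0.0
    if np.any(np.isnan(out) & np.isfinite(arr)):
        warnings.warn(f"{protein}: non-positive concentrations became NaN under {kind}", stacklevel=2)
    return out if np.ndim(conc) else float(out)


def _design(predictor, covariates, names):
    x = np.asarray(predictor, dtype=float).reshape(-1, 1)
    parts = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(-1, 1)
        parts.append(cov)
    return np.hstack(parts)


def _check_rank(X, names):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns via near-zero R diagonal of the QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] if i < len(names) else f"col{i}" for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise CollinearityError(f"design matrix is rank deficient; collinear columns: {bad}")


def _column_names(covariates):
    if covariates is None:
        return ["const", "predictor"]
    cov = np.asarray(covariates)
    k = 1 if cov.ndim == 1 else cov.shape[1]
    if isinstance(covariates, pd.DataFrame):
        return ["const", "predictor"] + list(covariates.columns)
    return ["const", "predictor"] + [f"cov{i}" for i in range(k)]


def linear_assoc(outcome, predictor, covariates=None, protein: str = "") -> AssocResult:
    """Covariate-adjusted OLS of a (transformed) outcome on a predictor.

    Returns the predictor's coefficient with its classical standard error
    and two-sided Wald p-value.  Rows with any missing value are dropped
    (complete-case analysis).
    """
    y = np.asarray(outcome, dtype=float)
    names = _column_names(covariates)
    X = _design(predictor, covariates, names)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    if len(y) <= X.shape[1]:
        raise ValueError("not enough complete observations for the model")
    _check_rank(X, names)
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        protein=protein, beta=float(fit.params[1]), se=float(fit.bse[1]),
        p=float(fit.pvalues[1]), n_used=int(len(y)),
    )


def logistic_assoc(status, predictor, covariates=None, protein: str = "") -> AssocResult:
    """Covariate-adjusted logistic regression of case status on a predictor
    (maximum likelihood); OR and Wald 95% CI refer to one predictor unit."""
    y = np.asarray(status, dtype=float)
    names = _column_names(covariates)
    X = _design(predictor, covariates, names)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    _check_rank(X, names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise ConvergenceError(f"logistic fit did not converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge")
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return AssocResult(
        protein=protein, beta=beta, se=se, p=float(fit.pvalues[1]), n_used=int(len(y)),
        or_point=float(np.exp(beta)),
        or_ci95=(float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))),
    )


def logistic_or_per_sd(status, conc, covariates=None, protein: str = "") -> AssocResult:
    """Odds ratio of disease per one SD of log concentration.

    Concentrations are log-transformed and standardised by the sample SD of
    the analysis sample (cases and controls pooled, complete cases) before
    the covariate-adjusted logistic fit, so the OR is invariant to the
    concentration unit.
    """
    conc = np.asarray(conc, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        logc = np.log(np.where(conc > 0, conc, np.nan))
    sd = np.nanstd(logc, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("log concentrations have zero variance")
    z = (logc - np.nanmean(logc)) / sd
    return logistic_assoc(status, z, covariates, protein=protein)


def correlation_matrix(conc: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of a protein
    concentration table (samples x proteins).  Zero-variance proteins give
    NaN entries with a warning."""
    zero_var = [c for c in conc.columns if conc[c].dropna().nunique() <= 1]
    if zero_var:
        warnings.warn(f"zero-variance proteins {zero_var}: correlation undefined", stacklevel=2)
    return conc.corr(method="pearson", min_periods=min_periods)


def summarize_cohort(samples: pd.DataFrame, proteins=None) -> pd.DataFrame:
    """Mean concentration and normal-approximation 95% CI (mean +/- 1.96 SE)
    per protein per status group, on the nM scale."""
    proteins = list(proteins) if proteins is not None else [
        c for c in samples.columns if c not in ("sample_id", "status", "sex", "age", "pc1", "pc2")
    ]
    rows = []
    for status, grp in samples.groupby("status"):
        for prot in proteins:
            vals = grp[prot].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError(f"group {status!r} has < 2 observations for {prot}")
            m = vals.mean()
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            rows.append((status, prot, m, m - Z95 * se, m + Z95 * se, len(vals)))
    return pd.DataFrame(rows, columns=["status", "protein", "mean_nM", "ci_lo", "ci_hi", "n"])


def association_table(pheno: pd.DataFrame, conc: pd.DataFrame) -> pd.DataFrame:
    """Per-protein case-control association summary.

    ``pheno`` carries sample_id, status (0/1), sex, age, pc1, pc2; ``conc``
    is tidy (sample_id, protein, conc_nM) or wide (sample_id + one column
    per protein).  Returns the linear-model beta/SE/p on the transformed
    scale plus the per-SD logistic OR with its 95% CI.
    """
    if "protein" in conc.columns:
        wide = conc.pivot_table(index="sample_id", columns="protein", values="conc_nM", aggfunc="first")
    else:
        wide = conc.set_index("sample_id")
    merged = pheno.set_index("sample_id").join(wide, how="inner")
    cov = merged[COVARIATES]
    rows = []
    for prot in [c for c in wide.columns if c in TRANSFORMS]:
        y = transform_concentration(prot, merged[prot].to_numpy())
        lin = linear_assoc(y, merged["status"].to_numpy(), cov, protein=prot)
        logi = logistic_or_per_sd(merged["status"].to_numpy(), merged[prot].to_numpy(), cov, protein=prot)
        rows.append({
            "protein": prot, "beta": lin.beta, "se": lin.se, "p": lin.p, "n": lin.n_used,
            "or_per_sd": logi.or_point, "or_ci_lo": logi.or_ci95[0], "or_ci_hi": logi.or_ci95[1],
        })
    return pd.DataFrame(rows)
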