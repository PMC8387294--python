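"""Stable-isotope-dilution SRM quantitation of FH-family proteins.

Turns exported transition peak areas (light = endogenous, heavy = spiked
stable-isotope standard) into plasma protein concentrations in nM.  Single
point isotope dilution: the endogenous concentration is the light/heavy
peak-area ratio of the quantifier transition times the known plasma
equivalent spike concentration of the heavy standard.  The two remaining
transitions per peptide act as qualifiers confirming specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from pyteomics import mass as _ptmass

__all__ = [
    "PeptideSpec",
    "SpikeScheme",
    "PeakRecord",
    "QuantResult",
    "InvalidSequenceError",
    "MissingStandardError",
    "MalformedTransitionSetError",
    "LLOQ_NM",
    "HEAVY_SHIFTS",
    "CARBAMIDOMETHYL",
    "compute_peptide_mass",
    "compute_spike_concentration",
    "quantify_endogenous",
    "check_qualifiers",
    "apply_lloq",
    "batch_cv",
    "read_transition_report",
    "quantify_samples",
    "replicate_cv",
    "load_config",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Lower limit of quantitation per protein, nM plasma.
LLOQ_NM = {
    "FH": 25.0,
    "FHL-1": 0.25,
    "FHR-1": 2.0,
    "FHR-2": 1.0,
    "FHR-3": 1.0,
    "FHR-4": 4.0,
    "FHR-5": 3.0,
}

#: Monoisotopic mass increments (Da) of the stable-isotope labels used for
#: the heavy standards: K(13C6,15N2), R(13C6,15N4), F(13C9,15N1), Y(13C9,15N1).
HEAVY_SHIFTS = {"K": 8.01420, "R": 10.00827, "F": 10.02728, "Y": 10.02728}

#: Carbamidomethyl cysteine adduct (iodoacetamide alkylation), Da.
CARBAMIDOMETHYL = 57.02146

DEFAULT_QUALIFIER_TOLERANCE = 0.30


class InvalidSequenceError(ValueError):
    """Peptide sequence contains a non-canonical residue letter."""


class MissingStandardError(ValueError):
    """Heavy-standard peak area is zero: no internal standard signal."""


class MalformedTransitionSetError(ValueError):
    """A peptide does not have exactly one quantifier plus two qualifiers."""


@dataclass(frozen=True)
class PeptideSpec:
    """A proteotypic standard peptide and its stock concentration.

    ``heavy_labels`` lists ``(residue_index, mass_shift_da)`` pairs (0-based
    index into ``sequence``); standards may carry more than one labelled
    residue.  Every cysteine is assumed alkylated with ``cys_mod_mass``.
    """

    protein: str
    sequence: str
    heavy_labels: tuple = ()
    cys_mod_mass: float = CARBAMIDOMETHYL
    stock_ng_per_ul: float = 0.0

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - AMINO_ACIDS:
            bad = sorted(set(seq) - AMINO_ACIDS)
            raise InvalidSequenceError(
                f"{self.protein}: non-canonical residue letter(s) {bad} in {self.sequence!r}"
            )
        for idx, shift in self.heavy_labels:
            if not 0 <= idx < len(seq):
                raise InvalidSequenceError(
                    f"{self.protein}: heavy-label index {idx} outside sequence"
                )
            if shift <= 0:
                raise ValueError(f"{self.protein}: heavy mass shift must be > 0")
        if self.stock_ng_per_ul < 0:
            raise ValueError("stock concentration must be >= 0")


@dataclass(frozen=True)
class SpikeScheme:
    """Volumes of the standard-dilution and spiking protocol.

    The concentrated standard mix (``aliquot_ul``) is diluted with
    ``diluent_ul`` of solvent; ``spike_ul`` of the dilution is added to the
    digest of ``plasma_ul`` of plasma.  ``injected_plasma_equiv_ul`` records
    the plasma equivalent per LC injection (bookkeeping only: the isotope
    ratio is volume-independent).
    """

    aliquot_ul: float = 5.0
    diluent_ul: float = 195.0
    spike_ul: float = 2.0
    plasma_ul: float = 5.0
    injected_plasma_equiv_ul: float = 0.8

    def __post_init__(self):
        for name in ("aliquot_ul", "diluent_ul", "spike_ul", "plasma_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def dilution_factor(self) -> float:
        return (self.aliquot_ul + self.diluent_ul) / self.aliquot_ul


@dataclass(frozen=True)
class PeakRecord:
    """One sample x peptide x transition light/heavy peak-area pair."""

    sample_id: str
    peptide: str
    transition_id: str
    role: str  # "quantifier" | "qualifier"
    light_area: float
    heavy_area: float
    rt_min: float = float("nan")


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    protein: str
    conc_nM: float
    below_lloq: bool
    qualifier_concordant: bool


def compute_peptide_mass(spec: PeptideSpec) -> float:
    """Monoisotopic mass (Da) of the heavy, Cys-alkylated peptide.

    Residue masses plus water, plus every heavy-label shift, plus one
    ``cys_mod_mass`` per cysteine.
    """
    seq = spec.sequence.upper()
    base = _ptmass.calculate_mass(sequence=seq, monoisotopic=True) if seq else _ptmass.calculate_mass(formula="H2O")
    heavy = sum(shift for _, shift in spec.heavy_labels)
    return base + heavy + seq.count("C") * spec.cys_mod_mass


def compute_spike_concentration(spec: PeptideSpec, scheme: SpikeScheme) -> float:
    """Plasma-equivalent concentration (nM) of the spiked heavy standard.

    stock [ng/uL] / dilution_factor * spike_ul / plasma_ul gives the mass
    of standard per unit plasma volume; dividing by the peptide molar mass
    converts to molarity.  1 ng/uL == 1e-3 g/L, so nM = value * 1e6 / mass.
    """
    mass_da = compute_peptide_mass(spec)
    if mass_da <= 0:
        raise ValueError("peptide mass must be > 0")
    ng_per_ul_plasma = (
        spec.stock_ng_per_ul / scheme.dilution_factor * scheme.spike_ul / scheme.plasma_ul
    )
    return ng_per_ul_plasma * 1e6 / mass_da


def quantify_endogenous(light_area: float, heavy_area: float, spike_nm: float) -> float:
    """Endogenous plasma concentration (nM) from the quantifier transition.

    conc = (light / heavy) * spike.  Light and heavy co-elute from the same
    injection, so the ratio is independent of the injected plasma volume.
    """
    if heavy_area <= 0:
        raise MissingStandardError("heavy-standard peak area is zero or negative")
    if light_area < 0:
        raise ValueError("light peak area must be >= 0")
    return light_area / heavy_area * spike_nm


def check_qualifiers(records, rel_tolerance: float = DEFAULT_QUALIFIER_TOLERANCE) -> bool:
    """True when both qualifier light/heavy ratios agree with the quantifier.

    Agreement means relative deviation |r_q - r_0| / r_0 <= ``rel_tolerance``
    where r_0 is the quantifier ratio.  A zero quantifier ratio requires the
    qualifiers to be zero as well.
    """
    records = list(records)
    if len(records) != 3:
        raise MalformedTransitionSetError(f"expected 3 transitions, got {len(records)}")
    quantifiers = [r for r in records if r.role == "quantifier"]
    qualifiers = [r for r in records if r.role == "qualifier"]
    if len(quantifiers) != 1 or len(qualifiers) != 2:
        raise MalformedTransitionSetError("expected 1 quantifier + 2 qualifiers")
    if len({(r.sample_id, r.peptide) for r in records}) != 1:
        raise MalformedTransitionSetError("transitions mix samples or peptides")
    q = quantifiers[0]
    r0 = q.light_area / q.heavy_area if q.heavy_area > 0 else np.nan
    if not np.isfinite(r0):
        return False
    for rec in qualifiers:
        if rec.heavy_area <= 0:
            return False
        r = rec.light_area / rec.heavy_area
        if r0 == 0:
            if r != 0:
                return False
        elif abs(r - r0) / r0 > rel_tolerance:
            return False
    return True


def apply_lloq(protein: str, conc_nm: float, lloq_table=None) -> bool:
    """True when ``conc_nm`` is below the protein's LLOQ (boundary counts
    as quantifiable).  Values are retained by callers and only flagged."""
    table = LLOQ_NM if lloq_table is None else lloq_table
    if protein not in table:
        raise KeyError(f"no LLOQ defined for protein {protein!r}")
    return conc_nm < table[protein]


def batch_cv(values) -> float:
    """Percent coefficient of variation (sample SD / mean * 100) of
    replicate concentrations.  NaN when the mean is zero."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 replicates for a %CV")
    m = arr.mean()
    if m == 0:
        warnings.warn("zero-mean replicates: %CV undefined", stacklevel=2)
        return float("nan")
    return float(arr.std(ddof=1) / m * 100.0)


# ---------------------------------------------------------------------------
# Transition-report table pipeline

REPORT_COLUMNS = ["sample_id", "batch", "peptide", "transition_id", "isotope", "area", "rt_min"]


def read_transition_report(path_or_df) -> pd.DataFrame:
    """Read a long-format transition report CSV.

    Expected columns: sample_id, batch, peptide, transition_id,
    isotope ("light"|"heavy"), area, rt_min (rt_min optional).
    Returns one row per sample x peptide x transition with light_area and
    heavy_area columns.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = {"sample_id", "peptide", "transition_id", "isotope", "area"} - set(df.columns)
    if missing:
        raise ValueError(f"transition report missing columns {sorted(missing)}")
    if "batch" not in df.columns:
        df = df.assign(batch=1)
    bad = set(df["isotope"].unique()) - {"light", "heavy"}
    if bad:
        raise ValueError(f"unknown isotope labels {sorted(bad)}")
    wide = (
        df.pivot_table(
            index=["sample_id", "batch", "peptide", "transition_id"],
            columns="isotope",
            values="area",
            aggfunc="first",
        )
        .rename(columns={"light": "light_area", "heavy": "heavy_area"})
        .reset_index()
    )
    wide.columns.name = None
    return wide


def quantify_samples(
    transitions: pd.DataFrame,
    peptide_specs,
    scheme: SpikeScheme,
    qualifier_tolerance: float = DEFAULT_QUALIFIER_TOLERANCE,
    lloq_table=None,
) -> pd.DataFrame:
    """Quantify every sample x protein from a wide transition table.

    The quantifier transition is the one with the largest total heavy
    signal per peptide per batch.  Returns a tidy frame with columns
    sample_id, batch, protein, conc_nM, below_lloq, qualifier_concordant;
    samples with no heavy signal get NaN and a warning.
    """
    if "isotope" in transitions.columns:  # long-format report passed directly
        transitions = read_transition_report(transitions)
    specs = {s.protein: s for s in peptide_specs}
    spikes = {p: compute_spike_concentration(s, scheme) for p, s in specs.items()}
    table = LLOQ_NM if lloq_table is None else lloq_table

    df = transitions[transitions["peptide"].isin(specs)].copy()
    skipped = set(transitions["peptide"]) - set(specs)
    if skipped:
        warnings.warn(f"no peptide spec for {sorted(skipped)}; skipped", stacklevel=2)

    sizes = df.groupby(["batch", "peptide", "sample_id"]).size()
    if (sizes != 3).any():
        bad = sizes[sizes != 3].index[0]
        raise MalformedTransitionSetError(
            f"{bad[2]}/{bad[1]}: {sizes[bad]} transitions, expected 3"
        )

    # quantifier = transition with the largest summed heavy signal, per batch
    heavy_sum = df.groupby(["batch", "peptide", "transition_id"])["heavy_area"].transform("sum")
    df["_rank"] = heavy_sum
    quant_tid = (
        df.loc[df.groupby(["batch", "peptide"])["_rank"].idxmax(), ["batch", "peptide", "transition_id"]]
        .set_index(["batch", "peptide"])["transition_id"]
    )
    df["is_quant"] = df["transition_id"].to_numpy() == (
        df.set_index(["batch", "peptide"]).index.map(quant_tid).to_numpy()
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = np.where(df["heavy_area"] > 0, df["light_area"] / df["heavy_area"], np.nan)

    keys = ["sample_id", "batch", "peptide"]
    quant = df[df["is_quant"]].set_index(keys)
    qual = df[~df["is_quant"]].copy()
    r0 = quant["ratio"].rename("r0")
    qual = qual.join(r0, on=keys)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_dev = np.where(
            qual["r0"] > 0,
            np.abs(qual["ratio"] - qual["r0"]) / qual["r0"],
            np.where(qual["ratio"] == 0, 0.0, np.inf),
        )
    qual["rel_dev"] = np.where(np.isfinite(qual["ratio"]), rel_dev, np.inf)
    concord = (qual.groupby(keys)["rel_dev"].max() <= qualifier_tolerance).rename("qualifier_concordant")

    out = quant.reset_index()[keys + ["ratio"]]
    out["spike"] = out["peptide"].map(spikes)
    out["conc_nM"] = out["ratio"] * out["spike"]
    missing = ~np.isfinite(out["conc_nM"])
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} sample x peptide pairs had no heavy-standard signal",
            stacklevel=2,
        )
    out["below_lloq"] = np.where(
        missing, True, out["conc_nM"].to_numpy() < out["peptide"].map(table).to_numpy()
    )
    out = out.join(concord, on=keys)
    out.loc[missing, "qualifier_concordant"] = False
    out = out.rename(columns={"peptide": "protein"})
    return out[["sample_id", "batch", "protein", "conc_nM", "below_lloq", "qualifier_concordant"]]


def replicate_cv(conc: pd.DataFrame) -> pd.DataFrame:
    """Batch QC: %CV per protein per batch over replicate measurements.

    ``conc`` is the output of :func:`quantify_samples`; replicates are rows
    sharing (batch, protein, sample_id is irrelevant) -- the %CV is taken
    across all samples appearing more than once per (protein, sample_id)
    or, when none repeat, across the batch's QC duplicates supplied by the
    caller.  Here we compute it per (batch, protein) across all rows, which
    matches duplicate-only QC batches.
    """
    rows = []
    for (batch, protein), grp in conc.dropna(subset=["conc_nM"]).groupby(["batch", "protein"]):
        if len(grp) < 2:
            continue
        rows.append((batch, protein, batch_cv(grp["conc_nM"].to_numpy()), len(grp)))
    return pd.DataFrame(rows, columns=["batch", "protein", "cv_percent", "n"])


def load_config(path):
    """Load a YAML quantitation config: peptide specs, spike scheme,
    optional LLOQ overrides and qualifier tolerance."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = [
        PeptideSpec(
            protein=p["protein"],
            sequence=p["sequence"],
            heavy_labels=tuple((int(i), float(s)) for i, s in p.get("heavy_labels", [])),
            cys_mod_mass=float(p.get("cys_mod_mass", CARBAMIDOMETHYL)),
            stock_ng_per_ul=float(p.get("stock_ng_per_ul", 0.0)),
        )
        for p in raw["peptides"]
    ]
    scheme = SpikeScheme(**raw.get("scheme", {}))
    lloq = {str(k): float(v) for k, v in raw.get("lloq_nM", {}).items()} or None
    tol = float(raw.get("qualifier_tolerance", DEFAULT_QUALIFIER_TOLERANCE))
    return specs, scheme, lloq, tol
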