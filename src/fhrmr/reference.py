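"""Bundled reference constants for the FH-family assay and MR analysis.

Holds the seven stable-isotope standard peptides (Glu-C proteotypic
peptides for FH, FHL-1 and FHR-1..FHR-5) with their stock concentrations,
the default spike scheme, published assay reproducibility figures, and a
loader for the published instrument-level summary statistics (cis/trans
pQTLs of circulating FHR protein concentrations with their AMD
case-control and consortium GWAS associations) used for worked examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .srm import HEAVY_SHIFTS, PeptideSpec, SpikeScheme

__all__ = [
    "PROTEINS",
    "PEPTIDE_STANDARDS",
    "DEFAULT_SCHEME",
    "PUBLISHED_SPIKE_NM",
    "PUBLISHED_BATCH_CV",
    "CONTROL_MEAN_NM",
    "load_fhr_instruments",
]

PROTEINS = ("FH", "FHL-1", "FHR-1", "FHR-2", "FHR-3", "FHR-4", "FHR-5")

_K, _R, _F, _Y = (HEAVY_SHIFTS[a] for a in "KRFY")

#: The seven heavy standards: sequence, labelled residues (0-based index,
#: mass shift), and stock concentration in the concentrated mix (ng/uL).
PEPTIDE_STANDARDS = (
    PeptideSpec("FH", "VTYKCFE", ((3, _K),), stock_ng_per_ul=47.6),
    PeptideSpec("FHL-1", "NGWSPTPRCIRVSFTL", ((7, _R),), stock_ng_per_ul=0.95),
    PeptideSpec("FHR-1", "ATFCDFPKINHGILYDEE", ((5, _F),), stock_ng_per_ul=7.14),
    PeptideSpec("FHR-2", "AMFCDFPKINHGILYDEE", ((5, _F),), stock_ng_per_ul=19.0),
    PeptideSpec("FHR-3", "VACHPGYGLPKAQTTVTCTE", ((6, _Y), (10, _K)), stock_ng_per_ul=4.76),
    PeptideSpec("FHR-4", "YQCQSYYE", ((0, _Y),), stock_ng_per_ul=4.76),
    PeptideSpec("FHR-5", "RGWSTPPICSFTKGE", ((0, _R), (12, _K)), stock_ng_per_ul=4.76),
)

#: 5 uL concentrated mix + 195 uL diluent; 2 uL spiked into a 5 uL plasma digest.
DEFAULT_SCHEME = SpikeScheme(
    aliquot_ul=5.0, diluent_ul=195.0, spike_ul=2.0, plasma_ul=5.0, injected_plasma_equiv_ul=0.8
)

#: Published plasma-equivalent spike concentrations (nM) under DEFAULT_SCHEME.
PUBLISHED_SPIKE_NM = {
    "FH": 500.0,
    "FHL-1": 5.0,
    "FHR-1": 32.75,
    "FHR-2": 86.75,
    "FHR-3": 21.68,
    "FHR-4": 41.5,
    "FHR-5": 27.5,
}

#: Published between-batch %CV on duplicate commercial serum (74 runs, 37 batches).
PUBLISHED_BATCH_CV = {
    "FH": 13.4,
    "FHL-1": 21.0,
    "FHR-1": 18.3,
    "FHR-2": 15.3,
    "FHR-3": 14.4,
    "FHR-4": 14.6,
    "FHR-5": 9.7,
}

#: Published mean circulating concentrations in controls (nM); used as
#: default location parameters by the cohort simulator.
CONTROL_MEAN_NM = {
    "FH": 737.3,
    "FHL-1": 10.4,
    "FHR-1": 31.2,
    "FHR-2": 45.3,
    "FHR-3": 24.1,
    "FHR-4": 46.1,
    "FHR-5": 25.5,
}


def load_fhr_instruments() -> pd.DataFrame:
    """Published instrument-level summary statistics for the FHR proteins.

    One row per instrumental variable: the pQTL association with the
    protein concentration in 252 controls (beta_exp, se_exp, p_exp), the
    variant's association with advanced AMD in the same case-control study
    (beta_cc, se_cc; log-OR scale) and in the large external consortium
    GWAS (beta_ext, se_ext), plus alleles, cis/trans class, published
    instrument-strength R2 and minor-allele frequency.
    """
    with resources.files("fhrmr").joinpath("data/fhr_instruments.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
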