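import numpy as np
import pytest

from fhrmr.simulate import LDBlock, PqtlEffect, SimConfig, simulate_cohort


def recovery_config(seed: int, **overrides) -> SimConfig:
    """Study-condition cohort for parameter-recovery runs.

    Defaults mirror the targeted case-control study (352/252, one cis pQTL
    per FHR protein with the published variance explained, published per-SD
    disease odds ratios), with two deliberate departures used by the tests:
    FHL-1 is given a cis instrument (R2 0.30) so its MR path is exercised,
    and FHR-3's disease effect is set to null so the no-effect protein's CI
    should cover OR = 1.
    """
    blocks = (
        LDBlock("FHL-1", 4, 0.8, "1"),
        LDBlock("FHR-1", 4, 0.8, "1"),
        LDBlock("FHR-2", 4, 0.8, "1"),
        LDBlock("FHR-3", 4, 0.8, "1"),
        LDBlock("FHR-4", 4, 0.8, "1"),
        LDBlock("FHR-5", 4, 0.8, "1"),
        LDBlock("null0", 4, 0.5, "2"),
    )
    pqtl = tuple(
        PqtlEffect(f"sim_{p}_1", p, r2=r2)
        for p, r2 in {
            "FHL-1": 0.30, "FHR-1": 0.53, "FHR-2": 0.44,
            "FHR-3": 0.35, "FHR-4": 0.25, "FHR-5": 0.15,
        }.items()
    )
    or_per_sd = (
        ("FH", 1.01), ("FHL-1", 1.35), ("FHR-1", 1.81), ("FHR-2", 1.66),
        ("FHR-3", 1.0), ("FHR-4", 1.27), ("FHR-5", 1.38),
    )
    # the genetic architecture (variant MAFs) is part of the study design and
    # is held fixed across replicate cohorts; only individuals are resampled
    kwargs = dict(seed=seed, genome_seed=777, blocks=blocks, pqtl=pqtl, or_per_sd=or_per_sd)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 604-sample cohort under the study conditions."""
    return simulate_cohort(recovery_config(seed=20210713))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
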