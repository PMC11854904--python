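import numpy as np
import pytest

from apcad.categorize import categorize_frame
from apcad.simulate import SimConfig, simulate_biopsy, zero_noise


@pytest.fixture(scope="session")
def disomy_case():
    """One noisy disomic full-genome case, categorized."""
    df, truth = simulate_biopsy(SimConfig(seed=7, sex="XY"))
    return categorize_frame(df), truth


@pytest.fixture(scope="session")
def clean_disomy_case():
    """Zero-noise disomic case restricted to a few chromosomes."""
    cfg = zero_noise(SimConfig(seed=5, sex="XX", chromosomes=("1", "21", "X", "Y")))
    df, truth = simulate_biopsy(cfg)
    return categorize_frame(df), truth


def single_chrom_case(seed, events=(), chromosome="2", noise=True, **kw):
    """Helper used across test modules: simulate one autosome (+X, +Y)."""
    cfg = SimConfig(seed=seed, events=events,
                    chromosomes=(chromosome, "X", "Y"), **kw)
    if not noise:
        cfg = zero_noise(cfg)
    df, truth = simulate_biopsy(cfg)
    return categorize_frame(df), truth
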