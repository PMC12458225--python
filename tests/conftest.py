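"""Shared fixtures: scaled-down synthetic bundles reused across test modules."""

import pytest

from pairdimer.repeats_adjacency import default_tng_pwm, pwm_pvalue_table
from pairdimer.synthetic_data import GenomeConfig, simulate_genome


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced genome bundle (fast to build, still statistically usable)."""
    config = GenomeConfig(
        n_fg_peaks=150,
        n_bg_peaks=600,
        n_repeats=80,
        n_genes=120,
        n_blacklist=2,
        seed=11,
    )
    return simulate_genome(config)


@pytest.fixture(scope="session")
def default_bundle():
    """The default-scale bundle used for statistical recovery checks."""
    return simulate_genome(GenomeConfig(seed=7))


@pytest.fixture(scope="session")
def tng_table():
    pwm = default_tng_pwm()
    return pwm, pwm_pvalue_table(pwm)
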