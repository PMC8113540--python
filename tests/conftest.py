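import numpy as np
import pytest

from teparyscan import simulate


@pytest.fixture(scope="session")
def nlr_sim():
    """One mid-sized two-species NLR genome shared by the NLR tests."""
    return simulate.simulate_nlr_genome(simulate.NlrSimSpec(n_proteins=80, seed=23))


@pytest.fixture(scope="session")
def panel_sim():
    """A small two-population panel with one planted sweep and fixed sites."""
    spec = simulate.PopSimSpec(
        n_wild=8,
        n_landrace=12,
        chrom_lengths={"Chr01": 2_000_000, "Chr02": 2_000_000},
        sweep_blocks=[("Chr01", 600_000, 900_000, 0.0)],
        fixed_sites=[("Chr02", 1_000_000), ("Chr02", 1_500_000)],
        missing_rate=0.02,
        seed=31,
    )
    return simulate.simulate_two_population_vcf(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
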