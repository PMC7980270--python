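import numpy as np
import pytest


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def introgression_fixture():
    """Default donor/recipient/control panel with injected tracts.

    Session-scoped: the rIBD tests and acceptance checks share one
    simulation (a 20 Mb genome, 33 diploids).
    """
    from introscan import synthetic_data as sd

    cfg = sd.introgression_demography(seed=7)
    panel = sd.simulate_genome(cfg)
    overlay_rng = np.random.default_rng(7)
    panel, truth = sd.inject_introgression(panel, "donor", "recipient", overlay_rng)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def sweep_fixture():
    """Two-group 10 Mb panel with one 100 kb star sweep in 'extreme'."""
    from introscan import synthetic_data as sd
    from introscan.panel import GenomicInterval

    cfg = sd.sweep_demography(seed=11)
    neutral = sd.simulate_genome(cfg)
    overlay_rng = np.random.default_rng(11)
    region = GenomicInterval("chr1", 4_950_000, 5_050_000)
    swept, truth = sd.inject_sweep(
        neutral, region, "extreme", 0.05, overlay_rng, locus_length=cfg.locus_length
    )
    return cfg, neutral, swept, truth
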