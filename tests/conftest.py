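import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")

from strainsieve import (RunConfig, SimulationConfig, Thresholds,
                         plant_variants, simulate_read_counts, simulate_reference)


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def small_sim():
    """A small 4-sample planted dataset used across modules."""
    cfg = SimulationConfig(
        seed=11, n_samples=4, genome_length=5000, n_variant_sites=40,
        depth=500, sharing_spec={4: 4, 3: 6, 2: 10, 1: 20},
        unmapped_fraction=0.05,
    )
    ref = simulate_reference(cfg.genome_length, 0.5, seed=cfg.seed)
    truth = plant_variants(ref, cfg)
    records = simulate_read_counts(truth, cfg.depth, seed=cfg.seed + 1)
    return cfg, ref, truth, records
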