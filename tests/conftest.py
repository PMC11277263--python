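import numpy as np
import pytest

from ribopause import (
    SimulationConfig,
    generate_transcriptome,
    simulate_rpf_library,
)


@pytest.fixture(scope="session")
def small_world():
    """A small seeded synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(n_transcripts=40, seed=11)
    models, truth = generate_transcriptome(cfg)
    lib = simulate_rpf_library(models, truth, cfg, 60_000,
                               rng=np.random.default_rng(5))
    return cfg, models, truth, lib


@pytest.fixture(scope="session")
def tx_index(small_world):
    _, models, _, _ = small_world
    return {t.transcript_id: t for t in models}
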