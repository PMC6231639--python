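import logging

import numpy as np
import pytest

from archefda.simulation import SimConfig, simulate_subjects

logging.getLogger("archefda").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared across tests (n=200, fixed seed)."""
    cfg = SimConfig(n=200)
    sample, xi, z, y = simulate_subjects(cfg, seed=12345)
    return {"config": cfg, "sample": sample, "xi": xi, "z": z, "y": y}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
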