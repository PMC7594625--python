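import numpy as np
import pandas as pd
import pytest

import bloodmet as bm


def make_design(modes, outcomes=None):
    """Build a DesignTable from per-pair detection modes (and case outcomes)."""
    if outcomes is None:
        outcomes = [0] * len(modes)
    rows = []
    for i, (m, y) in enumerate(zip(modes, outcomes)):
        pid = f"P{i + 1:04d}"
        rows.append({"pair_id": pid, "role": "case", "detection_mode": m,
                     "metastasis": int(y)})
        rows.append({"pair_id": pid, "role": "control", "detection_mode": m,
                     "metastasis": pd.NA})
    return bm.DesignTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_design():
    rng = np.random.default_rng(42)
    modes = np.where(rng.random(30) < 0.7, "screening", "interval")
    outcomes = (rng.random(30) < 0.3).astype(int)
    return make_design(modes, outcomes)


@pytest.fixture(scope="session")
def raw_bundle(small_design):
    return bm.simulate_raw_beadchip(small_design, n_genes=100, seed=11)


@pytest.fixture
def light_config():
    """Cheap-but-valid sampler settings for unit tests."""
    return bm.GeneModelConfig(chains=2, warmup=200, draws=400, seed=3,
                              min_ess=100.0, max_rhat=1.05)
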