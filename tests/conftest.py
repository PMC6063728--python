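import numpy as np
import pytest

import dropscreen as ds


@pytest.fixture(scope="session")
def small_screen():
    """One 300-gene stochastic screen with scores, shared across tests."""
    cfg = ds.SimConfig(n_genes=300, seed=11)
    guides, truth = ds.simulate_library(cfg)
    table = ds.simulate_screen(guides, truth, cfg)
    scores, lfc, removed = ds.score_screen(table, guides, n_iter=1000, seed=11)
    companions = ds.simulate_companions(truth, cfg)
    return {"config": cfg, "guides": guides, "truth": truth, "table": table,
            "scores": scores, "lfc": lfc, "removed": removed,
            "companions": companions}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
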