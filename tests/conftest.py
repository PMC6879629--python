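import numpy as np
import pandas as pd
import pytest

from ontarget import ingest
from ontarget.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A compact planted experiment shared by the read-only tests."""
    cfg = SimConfig(n_promoters=2000, n_genes=800, seed=20260928)
    return cfg, simulate_experiment(cfg)


@pytest.fixture(scope="session")
def null_experiment():
    """No planted signal at all: every gene is null."""
    cfg = SimConfig(
        n_promoters=10_000,
        n_genes=4000,
        n_on_target=0,
        n_off_only=0,
        n_off_reversed=0,
        n_active_motifs=0,
        lfc_magnitude=0.0,
        seed=7,
    )
    return cfg, simulate_experiment(cfg)


@pytest.fixture()
def toy_expr():
    """4 promoters x 6 samples with unit weights, two groups of three."""
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(6)]
    values = pd.DataFrame(
        rng.normal(5, 1, size=(4, 6)), index=[f"p{i}" for i in range(4)], columns=samples
    )
    weights = pd.DataFrame(1.0, index=values.index, columns=values.columns)
    meta = pd.DataFrame(
        {
            "cell_line": "toy",
            "treatment": ["control"] * 3 + ["drug"] * 3,
            "timepoint": ["NA"] * 3 + ["48h"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
            "batch": ["b1", "b2", "b1", "b2", "b1", "b2"],
        },
        index=samples,
    )
    sf = pd.Series(1.0, index=samples)
    return ingest.ExpressionMatrix(values, weights, sf, meta)
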