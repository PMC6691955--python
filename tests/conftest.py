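import numpy as np
import pandas as pd
import pytest

from ibdmark import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort reused by read-only tests."""
    cfg = SimulationConfig(n_samples=40, n_genes=120, n_informative=20,
                           n_blocks=5, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def logistic_instance():
    """Standardised random logistic problem with planted sparse signal."""
    rng = np.random.default_rng(11)
    n, p = 60, 30
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    beta = np.zeros(p)
    beta[:4] = 1.5
    prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    if y.sum() in (0, n):  # pragma: no cover - essentially impossible
        y[0] = 1 - y[0]
    return X, y


def make_ct_table(records):
    """Long-format Ct table from (sample, gene, [ct...]) triples."""
    rows = []
    for sample, gene, cts in records:
        for i, ct in enumerate(cts, start=1):
            rows.append((sample, gene, i, float(ct)))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])
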