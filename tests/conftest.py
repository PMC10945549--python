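import numpy as np
import pandas as pd
import pytest

import kirscreen as ks
from kirscreen.kir_core import fit_kir_model


def random_problem(rng, n=None, p=None, p_max=20):
    """Small random regression problem with a planted 3-kinase signal."""
    n = n if n is not None else int(rng.integers(10, 31))
    p = p if p is not None else int(rng.integers(3, p_max + 1))
    X = rng.uniform(0, 100, (n, p))
    k = min(3, p)
    beta = np.zeros(p)
    beta[rng.choice(p, k, replace=False)] = rng.uniform(0.05, 0.3, k)
    y = 1.0 - beta.sum() + (X / 100.0) @ beta + rng.normal(0, 0.02, n)
    return X, y


@pytest.fixture(scope="session")
def sim():
    """Default planted screen (34 drugs, 50 kinases, 10 cytokines, 5
    planted kinases each, noise sd 0.02)."""
    return ks.simulate_screen(ks.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def fitted_models(sim):
    """KiR models for every cytokine of the default screen (expensive;
    shared across tests)."""
    X, Y = sim["X_screen"], sim["Y_screen"]
    return {c: fit_kir_model(X, Y[c].to_numpy(), c) for c in Y.columns}


@pytest.fixture(scope="session")
def efficacy_table():
    """Hand-sized efficacy table for ranking tests."""
    return pd.DataFrame(
        [[80.0, 20.0], [50.0, 50.0], [10.0, 0.0]],
        index=["drugA", "drugB", "drugC"], columns=["CYT01", "CYT02"],
    )
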