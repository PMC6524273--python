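import numpy as np
import pandas as pd
import pytest

from seromir import CountMatrix, filter_expressed, log2cpm, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down simulated cohort shared across tests (fixed seed)."""
    cm, truth = simulate_cohort(
        n_pc=12, n_btc=6, n_hc=10, n_mirna=150, n_de=12, seed=42
    )
    return cm, truth


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    cm, truth = small_cohort
    kept = filter_expressed(cm)
    return log2cpm(kept), kept, truth


def random_count_matrix(rng, n_mirna=20, n_samples=10, lam=50.0):
    counts = pd.DataFrame(
        rng.poisson(lam, size=(n_mirna, n_samples)),
        index=[f"mir-{i:03d}" for i in range(n_mirna)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
    groups = ["PC", "BTC", "HC"] * (n_samples // 3 + 1)
    meta = pd.DataFrame(
        {
            "group": groups[:n_samples],
            "age": rng.uniform(30, 80, n_samples).round(1),
            "gender": rng.choice(["M", "F"], n_samples),
            "bmi": rng.uniform(18, 32, n_samples).round(1),
        },
        index=counts.columns,
    )
    return CountMatrix(counts, meta)
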