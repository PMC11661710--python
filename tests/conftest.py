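import numpy as np
import pandas as pd
import pytest

from esotwin.cohort import DEFAULT_SCHEMA, Cohort
from esotwin.simulate import generate, registry_like_preset


def make_cohort(n: int = 20, seed: int = 0, **overrides) -> Cohort:
    """Small hand-rolled cohort with controllable columns."""
    rng = np.random.default_rng(seed)
    pt = rng.choice(["T1", "T2", "T3", "T4"], n)
    table = pd.DataFrame({
        "id": [f"p{i}" for i in range(n)],
        "histology": rng.choice(["adenocarcinoma", "squamous"], n),
        "treatment": rng.integers(0, 2, n),
        "time_months": rng.uniform(1, 100, n).round(2),
        "event": rng.integers(0, 2, n),
        "pT": pt,
        "pN": rng.choice(["N0", "N1", "N2", "N3"], n),
        "pM": rng.choice(["M0", "M1"], n, p=[0.9, 0.1]),
        "margin": rng.choice(["R0", "R1", "R2"], n, p=[0.8, 0.15, 0.05]),
        "age": rng.normal(65, 8, n).round(1),
        "sex": rng.choice(["M", "F"], n),
        "weight_loss": rng.integers(0, 2, n).astype(float),
        "comorbidity_count": rng.poisson(1.0, n).astype(float),
        "location": rng.choice(["upper", "middle", "lower"], n),
        "grade": rng.choice(["G1", "G2", "G3"], n),
    })
    for col, vals in overrides.items():
        table[col] = vals
    return Cohort(table, DEFAULT_SCHEMA)


@pytest.fixture(scope="session")
def small_ac_run():
    """One modest adenocarcinoma draw shared across tests."""
    cfg = registry_like_preset("adenocarcinoma", n=800, seed=7)
    return generate(cfg)
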