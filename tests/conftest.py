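import numpy as np
import pandas as pd
import pytest

from ventmp.synthetic import SynthConfig, generate_cohort


def long_series(adm_id, rows):
    """rows: list of (t_min, dict of variable -> value) -> long-format frame."""
    out = []
    for t, d in rows:
        for var, val in d.items():
            out.append((adm_id, float(t), var, float(val)))
    return pd.DataFrame(out, columns=["admission_id", "t_min", "variable", "value"])


@pytest.fixture(scope="session")
def small_cohort():
    """300 admissions, fixed seed; shared across read-only tests."""
    return generate_cohort(SynthConfig(n_admissions=300, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
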