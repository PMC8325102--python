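import numpy as np
import pandas as pd
import pytest

from kinasecall import (
    QuantMatrix,
    build_pwm,
    generate_proteome,
    uniform_background,
)


@pytest.fixture(scope="session")
def toy_pwm():
    """Two-letter worked example: alphabet {A,R}, N=4, windows AA,AA,AA,AR."""
    bg = pd.Series(0.5, index=["A", "R"])
    return build_pwm(["AA", "AA", "AA", "AR"], bg)


@pytest.fixture(scope="session")
def small_proteome():
    return generate_proteome(n_proteins=30, mean_length=120, seed=11)


@pytest.fixture()
def quant_matrix_factory():
    """Build a QuantMatrix from a dict of column -> values (NaN = missing)."""

    def make(columns: dict, proteins=None):
        df = pd.DataFrame(columns)
        df.index = proteins or [f"P{i}" for i in range(len(df))]
        df.index.name = "protein_id"
        groups = {c: c.rsplit("_", 1)[0] for c in df.columns}
        return QuantMatrix(data=df, groups=groups)

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
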