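import numpy as np
import pandas as pd
import pytest

from riboseek.screen import ExpressionMatrix
from riboseek.simulate import SimulationConfig, generate_all


def make_expression(values: dict[str, list[float]], tissues: dict[str, str],
                    species: str = "sp") -> ExpressionMatrix:
    """Build a small ExpressionMatrix from gene -> per-sample levels."""
    df = pd.DataFrame(values).T
    df.columns = list(tissues)
    meta = pd.DataFrame(
        {
            "species": species,
            "tissue": [tissues[s] for s in df.columns],
            "replicate": range(1, len(df.columns) + 1),
        },
        index=pd.Index(df.columns, name="sample_id"),
    )
    return ExpressionMatrix(df, meta)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A full synthetic fixture directory generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    truth = generate_all(SimulationConfig(seed=20260101), out)
    return out, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
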