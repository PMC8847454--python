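import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_instruments(rng: np.random.Generator, j: int = 12) -> pd.DataFrame:
    """A random harmonized instrument table (gamma >= 0 convention)."""
    gamma = np.abs(rng.normal(0.08, 0.03, size=j)) + 0.02
    sx = rng.uniform(0.002, 0.01, size=j)
    sy = rng.uniform(0.005, 0.03, size=j)
    theta = rng.normal(0.0, 0.3)
    Gamma = theta * gamma + rng.normal(0.0, sy)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(j)],
            "gamma_hat": gamma,
            "sigma_x": sx,
            "Gamma_hat": Gamma,
            "sigma_y": sy,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def instruments(rng):
    return make_instruments(rng)


@pytest.fixture
def summary_tsv(tmp_path):
    """Write a small standard-schema summary table; returns (path, frame)."""

    def _write(df: pd.DataFrame, name: str = "sumstats.tsv"):
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write
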