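import numpy as np
import pandas as pd
import pytest

from spiral_alt import SyntheticConfig, generate_beep_panel
from spiral_alt.esm import MOOD_ITEMS


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def beep_panel(default_config):
    """One default beep panel shared across tests (seed fixed)."""
    return generate_beep_panel(default_config, seed=20240)


def make_beep_df(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal canonical beep table from sparse row dicts."""
    base = {
        "subject": "s1",
        "condition": "control",
        "period": "pre",
        "day": 1,
        "block": 1,
        "delay_min": 0.0,
        **{m: 4.0 for m in MOOD_ITEMS},
        "thought_pleasant": 4.0,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def exact_cov_sample(cov: np.ndarray, n: int, mean=None, seed: int = 0) -> np.ndarray:
    """Data matrix whose *sample* covariance (ddof=1) equals ``cov`` exactly:
    orthogonalize a random Gaussian draw, then color by the Cholesky factor."""
    cov = np.asarray(cov, float)
    k = cov.shape[0]
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, k))
    Z -= Z.mean(axis=0)
    # exact whitening of the sample covariance
    L = np.linalg.cholesky(Z.T @ Z / (n - 1))
    Z = Z @ np.linalg.inv(L).T
    X = Z @ np.linalg.cholesky(cov).T
    if mean is not None:
        X += np.asarray(mean, float)
    return X
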