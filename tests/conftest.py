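import numpy as np
import pandas as pd
import pytest

from gazemind import ScreenGeometry


@pytest.fixture
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_samples(t, x_prop, y_prop, valid=None) -> pd.DataFrame:
    """Build a gaze-sample frame from raw arrays (test helper)."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x_prop, dtype=float)
    y = np.asarray(y_prop, dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    return pd.DataFrame({"t_sec": t, "x_prop": x, "y_prop": y, "valid": np.asarray(valid, bool)})


def uniform_times(n: int, rate: float = 250.0, t0: float = 0.0) -> np.ndarray:
    return t0 + np.arange(n) / rate
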