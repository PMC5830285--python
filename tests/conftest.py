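import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Well-conditioned complete dataset (m=40, p=8, T=3)."""
    from sparsemtl import MultitaskDataset

    X = rng.standard_normal((40, 8))
    theta = np.zeros((8, 3))
    theta[[1, 4]] = rng.uniform(0.5, 1.5, (2, 3))
    Y = X @ theta + 0.1 * rng.standard_normal((40, 3))
    return MultitaskDataset(X=X, Y=Y)


def write_tables(tmp_path, X, Y, fx="feats.csv", fy="targs.csv"):
    import pandas as pd

    fx_path, fy_path = tmp_path / fx, tmp_path / fy
    pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])]).to_csv(fx_path, index=False)
    pd.DataFrame(Y, columns=[f"y{i}" for i in range(Y.shape[1])]).to_csv(fy_path, index=False)
    return fx_path, fy_path
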