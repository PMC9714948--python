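import numpy as np
import pytest

from hilasso import CoefMatrix, Dataset
from hilasso.core import BootstrapDraw


def coef_matrix_from_values(values: np.ndarray) -> CoefMatrix:
    """Build a CoefMatrix (with consistent draws) from a p x B array with NaNs."""
    values = np.asarray(values, dtype=float)
    p, B = values.shape
    draws = [
        BootstrapDraw(
            row_idx=np.arange(3),
            col_idx=np.flatnonzero(~np.isnan(values[:, b])),
            seed=b,
        )
        for b in range(B)
    ]
    return CoefMatrix(values=values, draws=draws)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset(rng):
    """n=50, p=10 with three strong coefficients of 5 on independent predictors."""
    X = rng.standard_normal((50, 10))
    beta = np.zeros(10)
    beta[:3] = 5.0
    y = X @ beta + rng.normal(0, 1.0, 50)
    return Dataset(X=X, y=y), beta


@pytest.fixture
def random_masked_matrix(rng):
    """6 x 5 coefficient matrix with a random missing mask (no all-missing column)."""
    values = rng.normal(size=(6, 5))
    mask = rng.random((6, 5)) < 0.4
    for b in range(5):  # keep every draw nonempty
        if mask[:, b].all():
            mask[rng.integers(0, 6), b] = False
    values[mask] = np.nan
    return coef_matrix_from_values(values)
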