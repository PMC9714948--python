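"""Container for a regression problem: design matrix, response, predictor names."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Dataset:
    """A samples x predictors design matrix with a response vector.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Numeric design matrix, one row per sample.
    y : ndarray of shape (n,)
        Response vector; continuous for regression, 0/1 for logistic mode.
    predictor_ids : sequence of str, optional
        Column identifiers. Defaults to ``V1 .. Vp``.
    """

    X: np.ndarray
    y: np.ndarray
    predictor_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples x predictors matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite entries")
        if self.predictor_ids is None:
            self.predictor_ids = np.array([f"V{j + 1}" for j in range(self.X.shape[1])])
        else:
            self.predictor_ids = np.asarray(self.predictor_ids, dtype=object)
            if self.predictor_ids.shape[0] != self.X.shape[1]:
                raise ValueError("predictor_ids length does not match number of columns")
            ids, counts = np.unique(self.predictor_ids.astype(str), return_counts=True)
            dups = ids[counts > 1]
            if dups.size:
                raise ValueError(f"duplicate predictor identifiers: {', '.join(dups)}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]
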