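"""Response-surface surrogates: polynomial regression over (T, %WB, pH).

The polynomial surrogate is linear in temperature x1 and wheat-bran
percentage x2 and quadratic in pH x3:

    y = b0 + b1*x1 + b2*x2 + b3*x3 + b4*x3^2

With b4 < 0 the pH response has an interior maximum at -b3 / (2 b4),
while temperature and substrate push the optimum to a box boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Dataset",
    "PolynomialModel",
    "PUBLISHED_POLYNOMIAL",
    "fit_polynomial",
    "predict_polynomial",
    "r_squared",
]

DATASET_COLUMNS = ("temperature_C", "wb_percent", "pH", "activity")


class SurrogateError(ValueError):
    """Invalid surrogate input."""


@dataclass(frozen=True)
class Dataset:
    """Training records (temperature deg C, %WB, pH, activity U/gds)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SurrogateError(f"dataset missing column(s): {', '.join(missing)}")
        vals = self.frame[list(DATASET_COLUMNS)].to_numpy(dtype=float)
        if vals.shape[0] == 0:
            raise SurrogateError("dataset is empty")
        if not np.isfinite(vals).all():
            raise SurrogateError("dataset contains non-finite values")
        wb = self.frame["wb_percent"].to_numpy(dtype=float)
        if ((wb < 0) | (wb > 100)).any():
            raise SurrogateError("wb_percent must lie in [0, 100]")

    @classmethod
    def from_records(cls, records) -> "Dataset":
        return cls(pd.DataFrame(records, columns=list(DATASET_COLUMNS)))

    @property
    def x(self) -> np.ndarray:
        """(n, 3) inputs ordered (temperature, wb_percent, pH)."""
        return self.frame[["temperature_C", "wb_percent", "pH"]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["activity"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class PolynomialModel:
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3, self.beta4])

    @property
    def stationary_ph(self) -> float:
        """pH at which dy/dpH = 0; the interior optimum when beta4 < 0."""
        if self.beta4 == 0:
            raise SurrogateError("no stationary pH: beta4 is 0")
        return -self.beta3 / (2.0 * self.beta4)

    def predict(self, x) -> np.ndarray | float:
        return predict_polynomial(self, x)


#: The published regression surface, kept distinct from any refit.
PUBLISHED_POLYNOMIAL = PolynomialModel(
    beta0=-2299.6275,
    beta1=7.896875,
    beta2=-0.591625,
    beta3=839.270625,
    beta4=-69.7646875,
)

_DESIGN_NAMES = ("intercept", "temperature_C", "wb_percent", "pH", "pH_squared")


def _design_matrix(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != 3:
        raise SurrogateError("inputs must have 3 columns (temperature, wb_percent, pH)")
    return np.column_stack([np.ones(len(x)), x[:, 0], x[:, 1], x[:, 2], x[:, 2] ** 2])


def fit_polynomial(data: Dataset) -> PolynomialModel:
    """Ordinary least squares on the (1, x1, x2, x3, x3^2) design.

    Raises if the design matrix is rank deficient, naming the columns
    involved in the collinearity.
    """
    if len(data) < 5:
        raise SurrogateError(f"need >= 5 records to fit 5 coefficients, have {len(data)}")
    X = _design_matrix(data.x)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # columns whose removal does not drop the rank are in the dependency
        guilty = [
            name
            for j, name in enumerate(_DESIGN_NAMES)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise SurrogateError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(guilty)
        )
    res = sm.OLS(data.y, X).fit()
    return PolynomialModel(*(float(b) for b in res.params))


def predict_polynomial(m: PolynomialModel, x) -> np.ndarray | float:
    """Evaluate the polynomial at one (x1, x2, x3) point or an (n, 3) array."""
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 1
    out = _design_matrix(arr) @ m.coefficients
    return float(out[0]) if scalar else out


def r_squared(predictions, observations) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Returns NaN (with a warning) when the observations have zero
    variance, where R^2 is undefined.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) < 2:
        raise SurrogateError("predictions/observations must be equal-length vectors (n >= 2)")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined: observations have zero variance", stacklevel=2)
        return math.nan
    ss_res = float(((o - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot
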