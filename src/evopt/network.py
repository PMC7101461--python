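"""A 3-10-1 feed-forward regression network trained by Levenberg-Marquardt.

The network maps (temperature, %WB, pH) to predicted activity through a
single hidden layer of 10 tanh (sigmoidal) units and one linear output
unit.  Inputs and target are min-max scaled to [-1, 1] before training.
Training minimizes the mean squared error on the normalized target by
damped Gauss-Newton (Levenberg-Marquardt) steps, with the Jacobian of
the network output with respect to the weights obtained by
backpropagation.  Because a 51-parameter network on a handful of records
is heavily over-parameterized, training is restarted from many random
initializations and the restart with the best overall R^2 is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .surrogate import Dataset, SurrogateError, r_squared

__all__ = ["NetworkModel", "FitReport", "train_network", "predict_network"]

log = logging.getLogger(__name__)

N_HIDDEN = 10

# Levenberg-Marquardt schedule
LAMBDA_INIT = 1e-3
LAMBDA_FACTOR = 10.0
LAMBDA_MAX = 1e10
GRAD_TOL = 1e-7
MSE_TOL = 1e-10
MAX_EPOCHS = 1000


@dataclass(frozen=True)
class NetworkModel:
    """Trained 3-10-1 network: weights, biases and normalization ranges."""

    w1: np.ndarray  # (10, 3) hidden weights
    b1: np.ndarray  # (10,) hidden biases
    w2: np.ndarray  # (10,) output weights
    b2: float  # output bias
    x_min: np.ndarray  # (3,) per-input range
    x_max: np.ndarray
    y_min: float  # target range
    y_max: float

    def predict(self, x) -> np.ndarray | float:
        return predict_network(self, x)


@dataclass(frozen=True)
class FitReport:
    """Training diagnostics of the selected restart.

    ``mse`` is the final training MSE on the normalized ([-1, 1]) target;
    ``mse_history`` records the MSE after each accepted LM step.  Split
    R^2 values are None unless a train/validation/test split was used;
    NaN flags an undefined R^2 (zero target variance in a split).
    """

    r2_overall: float
    r2_train: float | None
    r2_validation: float | None
    r2_test: float | None
    restart_index: int
    mse: float
    n_epochs: int
    mse_history: tuple[float, ...] = field(repr=False, default=())


class TrainingError(RuntimeError):
    """All restarts failed to produce a finite fit."""


# ---------------------------------------------------------------------------
# parameter vector layout: [w1.ravel() (30), b1 (10), w2 (10), b2 (1)]

N_PARAMS = 3 * N_HIDDEN + N_HIDDEN + N_HIDDEN + 1


def _unpack(theta: np.ndarray):
    w1 = theta[: 3 * N_HIDDEN].reshape(N_HIDDEN, 3)
    b1 = theta[3 * N_HIDDEN : 4 * N_HIDDEN]
    w2 = theta[4 * N_HIDDEN : 5 * N_HIDDEN]
    b2 = theta[5 * N_HIDDEN]
    return w1, b1, w2, b2


def _forward(theta: np.ndarray, xn: np.ndarray) -> np.ndarray:
    """Network output (normalized units) at normalized inputs xn (n, 3)."""
    w1, b1, w2, b2 = _unpack(theta)
    h = np.tanh(xn @ w1.T + b1)
    return h @ w2 + b2


def _jacobian(theta: np.ndarray, xn: np.ndarray) -> np.ndarray:
    """(n, n_params) Jacobian d output / d theta via backpropagation."""
    w1, b1, w2, b2 = _unpack(theta)
    h = np.tanh(xn @ w1.T + b1)  # (n, 10)
    dh = 1.0 - h**2  # tanh'
    n = len(xn)
    J = np.empty((n, N_PARAMS))
    # d/dW1[j,k] = w2[j] * dh[:,j] * xn[:,k]
    J[:, : 3 * N_HIDDEN] = ((w2 * dh)[:, :, None] * xn[:, None, :]).reshape(n, 3 * N_HIDDEN)
    J[:, 3 * N_HIDDEN : 4 * N_HIDDEN] = w2 * dh  # biases b1
    J[:, 4 * N_HIDDEN : 5 * N_HIDDEN] = h  # output weights
    J[:, 5 * N_HIDDEN] = 1.0  # output bias
    return J


def _minmax_scale(v: np.ndarray, lo, hi) -> np.ndarray:
    span = np.asarray(hi, dtype=float) - np.asarray(lo, dtype=float)
    safe = np.where(span == 0, 1.0, span)
    out = 2.0 * (v - lo) / safe - 1.0
    return np.where(span == 0, 0.0, out)


def _fit_lm(
    theta: np.ndarray, xn: np.ndarray, yn: np.ndarray, max_epochs: int
) -> tuple[np.ndarray, list[float], int]:
    """Levenberg-Marquardt on 0.5*SSE; returns (theta, accepted-MSE history, epochs)."""
    n = len(yn)
    pred = _forward(theta, xn)
    mse = float(((yn - pred) ** 2).mean())
    history = [mse]
    lam = LAMBDA_INIT
    eye = np.eye(N_PARAMS)
    epoch = 0
    while epoch < max_epochs:
        epoch += 1
        r = yn - _forward(theta, xn)
        J = _jacobian(theta, xn)
        g = J.T @ r  # gradient of 0.5*SSE w.r.t. theta (up to sign)
        if np.linalg.norm(g, ord=np.inf) < GRAD_TOL or mse < MSE_TOL:
            break
        JtJ = J.T @ J
        accepted = False
        while lam <= LAMBDA_MAX:
            try:
                step = np.linalg.solve(JtJ + lam * eye, g)
            except np.linalg.LinAlgError:
                lam *= LAMBDA_FACTOR
                continue
            cand = theta + step
            cand_pred = _forward(cand, xn)
            cand_mse = float(((yn - cand_pred) ** 2).mean())
            if np.isfinite(cand_mse) and cand_mse < mse:
                theta, mse = cand, cand_mse
                history.append(mse)
                lam = max(lam / LAMBDA_FACTOR, 1e-20)
                accepted = True
                break
            lam *= LAMBDA_FACTOR
        if not accepted:
            break  # damping exhausted: local minimum to working precision
    return theta, history, epoch


def train_network(
    data: Dataset,
    seed: int,
    restarts: int = 64,
    split: str = "all",
    max_epochs: int = MAX_EPOCHS,
) -> tuple[NetworkModel, FitReport]:
    """Train the 3-10-1 network, best of ``restarts`` random initializations.

    Restart r draws its uniform [-0.5, 0.5] initial weights from a
    generator seeded with ``seed + r``, making the whole procedure
    deterministic.  ``split='all'`` trains on every record and reports
    only the overall R^2; ``split='holdout'`` holds out one random
    validation and one test record (seeded) and reports per-split R^2
    alongside.  The restart with the highest overall R^2 wins.
    """
    if len(data) < 2:
        raise SurrogateError("need at least 2 records to train")
    if restarts < 1:
        raise SurrogateError("restarts must be >= 1")
    if split not in ("all", "holdout"):
        raise SurrogateError(f"unknown split policy {split!r}")

    x, y = data.x, data.y
    x_min, x_max = x.min(axis=0), x.max(axis=0)
    y_min, y_max = float(y.min()), float(y.max())
    xn = _minmax_scale(x, x_min, x_max)
    yn = _minmax_scale(y, y_min, y_max)

    n = len(y)
    if split == "holdout" and n >= 3:
        perm = np.random.default_rng(seed).permutation(n)
        idx_val, idx_test = np.array([perm[0]]), np.array([perm[1]])
        idx_train = perm[2:]
    else:
        idx_train, idx_val, idx_test = np.arange(n), None, None

    best = None  # (r2, restart, theta, history, epochs)
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        theta0 = rng.uniform(-0.5, 0.5, size=N_PARAMS)
        theta, history, epochs = _fit_lm(theta0, xn[idx_train], yn[idx_train], max_epochs)
        pred_all = _forward(theta, xn)
        if not np.isfinite(pred_all).all():
            log.info("restart %d discarded: non-finite predictions", r)
            continue
        r2 = r_squared(pred_all, yn)
        log.debug("restart %d: overall R^2 = %.6f, epochs = %d", r, r2, epochs)
        if np.isfinite(r2) and (best is None or r2 > best[0]):
            best = (r2, r, theta, history, epochs)
    if best is None:
        raise TrainingError("all restarts failed (non-finite fits)")

    r2, restart, theta, history, epochs = best
    w1, b1, w2, b2 = _unpack(theta)
    model = NetworkModel(
        w1=w1.copy(), b1=b1.copy(), w2=w2.copy(), b2=float(b2),
        x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max,
    )

    def _split_r2(idx):
        if idx is None or len(idx) == 0:
            return None
        if len(idx) == 1:  # single held-out point: undefined variance
            return float("nan")
        return r_squared(_forward(theta, xn[idx]), yn[idx])

    report = FitReport(
        r2_overall=float(r2),
        r2_train=_split_r2(idx_train) if split == "holdout" else None,
        r2_validation=_split_r2(idx_val),
        r2_test=_split_r2(idx_test),
        restart_index=restart,
        mse=float(history[-1]),
        n_epochs=epochs,
        mse_history=tuple(history),
    )
    return model, report


def predict_network(m: NetworkModel, x) -> np.ndarray | float:
    """Denormalized prediction at one point or an (n, 3) array.

    Inputs outside the training range are extrapolated (logged at DEBUG).
    """
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[1] != 3:
        raise SurrogateError("inputs must have 3 columns (temperature, wb_percent, pH)")
    if ((arr < m.x_min) | (arr > m.x_max)).any():
        log.debug("predicting outside the training range (extrapolation)")
    xn = _minmax_scale(arr, m.x_min, m.x_max)
    theta = np.concatenate([m.w1.ravel(), m.b1, m.w2, [m.b2]])
    out_n = _forward(theta, xn)
    span = m.y_max - m.y_min
    if span == 0:
        out = np.full_like(out_n, m.y_min)
    else:
        out = (out_n + 1.0) / 2.0 * span + m.y_min
    scalar = np.asarray(x, dtype=float).ndim == 1
    return float(out[0]) if scalar else out
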