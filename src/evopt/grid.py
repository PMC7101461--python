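"""Constrained lattice enumeration and exhaustive surrogate optimization.

Candidate media conditions form a box lattice over temperature, %WB and
pH.  Each lattice point carries a 1-based iteration number with pH as
the outermost (slowest) axis, temperature in the middle and %WB
innermost:

    iteration = i_pH * (nT * nWB) + i_T * nWB + i_WB + 1

Optimization is exhaustive: the surrogate is evaluated at every point
and the argmax reported, together with the aligned 10-iteration window
containing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Axis", "GridSpec", "GridResult", "DEFAULT_GRID", "enumerate_grid", "optimize", "top_window_table"]


class GridError(ValueError):
    """Invalid grid specification or evaluation failure."""


@dataclass(frozen=True)
class Axis:
    name: str
    low: float
    high: float
    step: float

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise GridError(f"axis {self.name!r}: step must be > 0, got {self.step}")
        if self.low > self.high:
            raise GridError(f"axis {self.name!r}: low > high")

    @property
    def count(self) -> int:
        return int(math.floor((self.high - self.low) / self.step + 1e-9)) + 1

    def values(self) -> np.ndarray:
        # one final rounding keeps axis membership bit-stable
        return np.round(self.low + np.arange(self.count) * self.step, 10)


@dataclass(frozen=True)
class GridSpec:
    temperature: Axis
    wb_percent: Axis
    ph: Axis

    @property
    def size(self) -> int:
        return self.temperature.count * self.wb_percent.count * self.ph.count


#: The search box for the protease surrogates: 26-30 degC by 1, 70-90 %WB
#: by 2.5, pH 4-8 by 0.1 (41 * 5 * 9 = 1845 points).
DEFAULT_GRID = GridSpec(
    temperature=Axis("temperature_C", 26.0, 30.0, 1.0),
    wb_percent=Axis("wb_percent", 70.0, 90.0, 2.5),
    ph=Axis("pH", 4.0, 8.0, 0.1),
)

GRID_COLUMNS = ("iteration", "temperature_C", "wb_percent", "pH")


@dataclass(frozen=True)
class GridResult:
    """Evaluated grid: per-point predictions, argmax and its window."""

    frame: pd.DataFrame  # columns iteration, temperature_C, wb_percent, pH, predicted
    argmax: pd.Series
    top_window: pd.DataFrame


def enumerate_grid(g: GridSpec) -> pd.DataFrame:
    """All lattice points in iteration order (pH slowest, %WB fastest)."""
    t, wb, ph = g.temperature.values(), g.wb_percent.values(), g.ph.values()
    ph_grid, t_grid, wb_grid = np.meshgrid(ph, t, wb, indexing="ij")
    n = g.size
    return pd.DataFrame(
        {
            "iteration": np.arange(1, n + 1),
            "temperature_C": t_grid.ravel(),
            "wb_percent": wb_grid.ravel(),
            "pH": ph_grid.ravel(),
        }
    )


def point_at(g: GridSpec, iteration: int) -> tuple[float, float, float]:
    """Decode an iteration number to (temperature, wb_percent, pH)."""
    if not (1 <= iteration <= g.size):
        raise GridError(f"iteration {iteration} outside 1..{g.size}")
    idx = iteration - 1
    n_t, n_wb = g.temperature.count, g.wb_percent.count
    i_ph, rem = divmod(idx, n_t * n_wb)
    i_t, i_wb = divmod(rem, n_wb)
    return (
        float(g.temperature.values()[i_t]),
        float(g.wb_percent.values()[i_wb]),
        float(g.ph.values()[i_ph]),
    )


def _predict(model, x: np.ndarray) -> np.ndarray:
    fn = getattr(model, "predict", model)
    return np.asarray(fn(x), dtype=float).reshape(len(x))


def optimize(model, g: GridSpec = DEFAULT_GRID) -> GridResult:
    """Evaluate ``model`` at every grid point and locate the maximum.

    ``model`` is anything with a ``predict((n, 3) array)`` method (or a
    bare callable) taking columns (temperature, wb_percent, pH).  Ties
    go to the lowest iteration number.
    """
    frame = enumerate_grid(g)
    x = frame[["temperature_C", "wb_percent", "pH"]].to_numpy()
    pred = _predict(model, x)
    if not np.isfinite(pred).all():
        bad = frame.iloc[int(np.flatnonzero(~np.isfinite(pred))[0])]
        raise GridError(
            "non-finite prediction at iteration "
            f"{int(bad.iteration)}: (T {bad.temperature_C}, WB {bad.wb_percent}, "
            f"pH {bad.pH})"
        )
    frame = frame.assign(predicted=pred)
    best = int(np.argmax(pred))  # np.argmax returns the first (lowest) index on ties
    argmax = frame.iloc[best]
    return GridResult(frame=frame, argmax=argmax, top_window=_window(frame, best))


def _window(frame: pd.DataFrame, best_idx: int) -> pd.DataFrame:
    # aligned decade of iterations (1-10, 11-20, ...) containing the argmax
    it = int(frame.iloc[best_idx]["iteration"])
    start = (it - 1) // 10 * 10 + 1
    sel = frame[(frame.iteration >= start) & (frame.iteration <= start + 9)]
    return sel.reset_index(drop=True)


def top_window_table(res: GridResult) -> pd.DataFrame:
    """The 10-iteration window around the maximum, one row per iteration."""
    return res.top_window[["iteration", "temperature_C", "wb_percent", "pH", "predicted"]].copy()
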