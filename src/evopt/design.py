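"""Three-variable EVOP worksheet construction.

An EVOP (evolutionary operation) phase perturbs the current operating
centre of a process along a full 2^3 factorial: two replicate centre
runs plus the eight corner conditions, each repeated over cycles.  The
three controllable variables here are incubation temperature (deg C),
initial medium pH, and the wheat-bran share of a wheat-bran + soybean-meal
substrate mix (percent wheat bran by mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "FactorSpec",
    "RunCondition",
    "Worksheet",
    "RUN_ORDER",
    "CODED_DESIGN",
    "FACTOR_NAMES",
    "build_worksheet",
    "ratio_to_percent",
    "attach_cycle",
]

#: Canonical run labels, fixed order.
RUN_ORDER: tuple[str, ...] = (
    "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8", "A9", "A10",
)

#: Coded levels (temperature, pH, wheat-bran %) per run.  A1/A6 are the
#: duplicated centre; the remaining eight runs are the 2^3 corners.
CODED_DESIGN: dict[str, tuple[int, int, int]] = {
    "A1": (0, 0, 0),
    "A2": (-1, -1, -1),
    "A3": (-1, +1, +1),
    "A4": (+1, -1, +1),
    "A5": (+1, +1, -1),
    "A6": (0, 0, 0),
    "A7": (+1, +1, +1),
    "A8": (-1, -1, +1),
    "A9": (+1, -1, -1),
    "A10": (-1, +1, -1),
}

#: Axis names in design order: T (temperature), P (pH), R (substrate ratio
#: expressed as % wheat bran).
FACTOR_NAMES: tuple[str, str, str] = ("temperature", "pH", "wb_percent")


class DesignError(ValueError):
    """Invalid design specification or worksheet data."""


@dataclass(frozen=True)
class FactorSpec:
    """One controllable variable and its +/- search amplitude.

    ``centre`` is the current operating level; ``half_step`` the EVOP
    perturbation, so the factorial levels are ``centre - half_step`` and
    ``centre + half_step``.
    """

    name: str
    units: str
    centre: float
    half_step: float

    def __post_init__(self) -> None:
        if not (self.half_step > 0):
            raise DesignError(
                f"factor {self.name!r}: half_step must be > 0, got {self.half_step}"
            )
        if not (math.isfinite(self.centre) and math.isfinite(self.half_step)):
            raise DesignError(f"factor {self.name!r}: non-finite level")

    @property
    def low(self) -> float:
        return self.centre - self.half_step

    @property
    def high(self) -> float:
        return self.centre + self.half_step

    def actual(self, coded: int) -> float:
        """Map a coded level in {-1, 0, +1} to factor units."""
        if coded not in (-1, 0, 1):
            raise DesignError(f"coded level must be -1, 0 or +1, got {coded}")
        return self.centre + coded * self.half_step

    def coded(self, actual: float) -> int:
        """Inverse of :meth:`actual`; the value must sit on a design level."""
        z = (actual - self.centre) / self.half_step
        c = int(round(z))
        if c not in (-1, 0, 1) or not math.isclose(z, c, abs_tol=1e-9):
            raise DesignError(
                f"{actual} is not a design level of factor {self.name!r}"
            )
        return c


@dataclass(frozen=True)
class RunCondition:
    """A single worksheet run: label, coded triple and actual conditions."""

    run_id: str
    coded: tuple[int, int, int]
    actual: tuple[float, float, float]


@dataclass(frozen=True)
class Worksheet:
    """A full EVOP phase: 3 factors, 10 runs, zero or more response cycles.

    ``cycles[c][r]`` is the response (activity, U/gds) of run ``r`` in
    cycle ``c``; run order is always A1...A10.
    """

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    runs: tuple[RunCondition, ...]
    cycles: tuple[tuple[float, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.runs) != 10:
            raise DesignError(f"worksheet needs exactly 10 runs, got {len(self.runs)}")
        centre = [r.run_id for r in self.runs if r.coded == (0, 0, 0)]
        if centre != ["A1", "A6"]:
            raise DesignError(f"centre runs must be A1 and A6, got {centre}")
        corners = {r.coded for r in self.runs if r.coded != (0, 0, 0)}
        full = {(a, b, c) for a in (-1, 1) for b in (-1, 1) for c in (-1, 1)}
        if corners != full:
            raise DesignError("corner runs must cover all 8 sign patterns of 2^3")
        for cyc in self.cycles:
            _validate_responses(cyc)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def run_ids(self) -> tuple[str, ...]:
        return tuple(r.run_id for r in self.runs)

    def responses(self) -> np.ndarray:
        """All responses as an (n_cycles, 10) array."""
        return np.asarray(self.cycles, dtype=float).reshape(self.n_cycles, 10)

    def coded_matrix(self) -> np.ndarray:
        """(10, 3) matrix of coded levels in run order."""
        return np.array([r.coded for r in self.runs], dtype=int)


def _validate_responses(responses: Sequence[float]) -> tuple[float, ...]:
    vals = tuple(float(v) for v in responses)
    if len(vals) != 10:
        raise DesignError(f"a cycle needs exactly 10 responses, got {len(vals)}")
    for v in vals:
        if not math.isfinite(v):
            raise DesignError(f"non-finite response {v!r}")
        if v < 0:
            raise DesignError(f"negative response {v}; activities are >= 0")
    return vals


def build_worksheet(
    factors: Sequence[FactorSpec],
) -> Worksheet:
    """Construct the empty 10-run worksheet for three factors.

    The run coding is fixed (A1/A6 at the centre, A2...A10 the 2^3
    corners); actual conditions are the image of the coded levels under
    each factor's centre +/- half_step mapping.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise DesignError(f"exactly 3 factors required, got {len(factors)}")
    runs = tuple(
        RunCondition(
            run_id=rid,
            coded=CODED_DESIGN[rid],
            actual=tuple(f.actual(c) for f, c in zip(factors, CODED_DESIGN[rid])),
        )
        for rid in RUN_ORDER
    )
    return Worksheet(factors=factors, runs=runs)


def ratio_to_percent(wb_grams: float, sm_grams: float) -> float:
    """Wheat-bran mass share of a wheat-bran + soybean-meal mix, in percent.

    Bridges the ``WB:SM`` gram-ratio notation (e.g. 4:1) to the %WB axis
    used throughout the package: ``100 * wb / (wb + sm)``.
    """
    if wb_grams < 0 or sm_grams < 0:
        raise DesignError("masses must be non-negative")
    total = wb_grams + sm_grams
    if total <= 0:
        raise DesignError("total substrate mass must be positive")
    return 100.0 * wb_grams / total


def attach_cycle(ws: Worksheet, responses: Sequence[float]) -> Worksheet:
    """Return a new worksheet with one more cycle of responses appended."""
    vals = _validate_responses(responses)
    return replace(ws, cycles=ws.cycles + (vals,))
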