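"""EVOP worksheet statistics and the shift/stop decision rule.

For a 2^3 factorial with duplicated centre, the main effect of a factor
is the mean response at its high level minus the mean at its low level
(centre runs excluded); a two-factor interaction is the same contrast on
the sign product of the two factors.  The change-in-mean effect compares
the average over all ten runs with the centre average: a strongly
negative value means the current centre out-performs its neighbourhood.
Effects are judged against error limits (~2 standard errors) built from
an estimate of the run-to-run standard deviation s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .design import Worksheet

__all__ = [
    "EffectsReport",
    "ErrorLimits",
    "Decision",
    "per_run_averages",
    "per_run_differences",
    "main_effect",
    "interaction_effect",
    "change_in_mean",
    "estimate_sd",
    "error_limits",
    "decide",
    "build_report",
    "RANGE_FACTORS",
]

FACTOR_CODES = {"T": 0, "P": 1, "R": 2}
PAIR_CODES = {"TP": (0, 1), "TR": (0, 2), "PR": (1, 2)}

#: Range-method multipliers f(k, n) from standard EVOP practice:
#: s = f * range(per-run differences), k = runs per cycle, n = cycles.
RANGE_FACTORS: dict[int, dict[int, float]] = {
    5: {2: 0.30, 3: 0.35, 4: 0.37, 5: 0.38, 6: 0.39, 7: 0.40, 8: 0.40, 9: 0.40, 10: 0.41},
    10: {2: 0.23, 3: 0.27, 4: 0.29, 5: 0.30, 6: 0.31, 7: 0.31, 8: 0.31, 9: 0.32, 10: 0.32},
}


class EffectsError(ValueError):
    """Invalid input to an effects computation."""


@dataclass(frozen=True)
class EffectsReport:
    """All worksheet statistics for one response vector."""

    per_run_average: tuple[float, ...]
    per_run_difference: tuple[float, ...]
    effect_T: float
    effect_P: float
    effect_R: float
    effect_TP: float
    effect_TR: float
    effect_PR: float
    change_in_mean: float
    s: float
    n_cycles: int

    @property
    def main_effects(self) -> dict[str, float]:
        return {"T": self.effect_T, "P": self.effect_P, "R": self.effect_R}

    @property
    def all_effects(self) -> dict[str, float]:
        return {
            **self.main_effects,
            "TP": self.effect_TP,
            "TR": self.effect_TR,
            "PR": self.effect_PR,
        }


@dataclass(frozen=True)
class ErrorLimits:
    """+/- half-widths against which averages/effects are compared."""

    for_average: float
    for_effects: float
    for_change_in_mean: float


@dataclass(frozen=True)
class Decision:
    """Outcome of comparing effects with error limits.

    ``shift_direction`` maps factor code (T/P/R) to -1, 0 or +1: the sign
    of each *significant* main effect, i.e. the direction in which moving
    the centre one half-step is expected to improve yield.
    """

    verdict: Literal["shift", "optimum_reached", "continue_cycles"]
    shift_direction: dict[str, int]
    rationale: str


def per_run_averages(ws: Worksheet) -> np.ndarray:
    """Arithmetic mean across cycles for each of the 10 runs."""
    if ws.n_cycles < 1:
        raise EffectsError("worksheet has no cycles")
    return ws.responses().mean(axis=0)


def per_run_differences(ws: Worksheet, i: int = 0, j: int = 1) -> np.ndarray:
    """Per-run response difference cycle ``i`` minus cycle ``j`` (0-based)."""
    n = ws.n_cycles
    if not (0 <= i < n and 0 <= j < n):
        raise EffectsError(f"cycle index out of range (have {n} cycles)")
    resp = ws.responses()
    return resp[i] - resp[j]


def _contrast(responses: Sequence[float], signs: np.ndarray) -> float:
    # signs: per-run +1/-1/0; contrast = (sum at + minus sum at -)/4
    r = np.asarray(responses, dtype=float)
    if r.shape != (10,):
        raise EffectsError("responses must be a vector of 10 values in run order")
    return float((r[signs > 0].sum() - r[signs < 0].sum()) / 4.0)


def main_effect(responses: Sequence[float], ws: Worksheet, factor: str) -> float:
    """Main effect of T, P or R: mean at coded +1 minus mean at coded -1."""
    try:
        col = FACTOR_CODES[factor]
    except KeyError:
        raise EffectsError(f"unknown factor {factor!r}; expected one of T, P, R")
    return _contrast(responses, ws.coded_matrix()[:, col])


def interaction_effect(responses: Sequence[float], ws: Worksheet, pair: str) -> float:
    """Two-factor interaction (TP, TR or PR): contrast on the sign product."""
    try:
        a, b = PAIR_CODES[pair]
    except KeyError:
        raise EffectsError(f"unknown pair {pair!r}; expected one of TP, TR, PR")
    coded = ws.coded_matrix()
    return _contrast(responses, coded[:, a] * coded[:, b])


def change_in_mean(responses: Sequence[float], ws: Worksheet) -> float:
    """Mean of all 10 responses minus the mean of the two centre runs."""
    r = np.asarray(responses, dtype=float)
    if r.shape != (10,):
        raise EffectsError("responses must be a vector of 10 values in run order")
    centre = np.array([run.coded == (0, 0, 0) for run in ws.runs])
    return float(r.mean() - r[centre].mean())


def estimate_sd(
    ws: Worksheet,
    method: str = "pooled",
    fixed: float | None = None,
) -> float:
    """Estimate the run-to-run standard deviation s.

    ``pooled``: sqrt(sum(d^2) / (2 k)) over the per-run differences d
    between the accumulated prior-cycle average and the newest cycle
    (for two cycles this is simply cycle 1 minus cycle 2), k = 10 runs.
    ``range``: range(d) times the standard EVOP factor f(k, n).
    ``fixed``: return the supplied constant (used to reproduce published
    error limits whose s derivation is not documented).
    """
    if method == "fixed":
        if fixed is None or fixed < 0:
            raise EffectsError("method 'fixed' needs a non-negative s value")
        return float(fixed)
    n = ws.n_cycles
    if n < 2:
        raise EffectsError(f"method {method!r} needs >= 2 cycles, have {n}")
    resp = ws.responses()
    d = resp[: n - 1].mean(axis=0) - resp[n - 1]
    if method == "pooled":
        return float(math.sqrt(float(d @ d) / (2 * 10)))
    if method == "range":
        try:
            f = RANGE_FACTORS[10][n]
        except KeyError:
            raise EffectsError(f"no range factor tabulated for k=10, n={n}")
        return float((d.max() - d.min()) * f)
    raise EffectsError(f"unknown sd method {method!r}")


def error_limits(s: float, n_cycles: int) -> ErrorLimits:
    """Error limits from s and the cycle count n.

    for_average = 2 s / sqrt(n); for_effects = 2 s / sqrt(2 n);
    for_change_in_mean = 1.78 s / sqrt(2 n).
    """
    if s < 0:
        raise EffectsError("s must be >= 0")
    if n_cycles < 1:
        raise EffectsError("n_cycles must be >= 1")
    root_n = math.sqrt(n_cycles)
    root_2n = math.sqrt(2 * n_cycles)
    return ErrorLimits(
        for_average=2.0 * s / root_n,
        for_effects=2.0 * s / root_2n,
        for_change_in_mean=1.78 * s / root_2n,
    )


def decide(report: EffectsReport, limits: ErrorLimits) -> Decision:
    """Apply the EVOP decision rule.

    Any effect strictly larger in magnitude than the effects error limit
    calls for a shift of the centre, one half-step in the direction of
    each significant main effect.  Otherwise, a change-in-mean below its
    negative error limit indicates the centre already beats its
    neighbourhood (optimum reached); failing both, run more cycles.
    """
    significant = {
        name: eff
        for name, eff in report.all_effects.items()
        if abs(eff) > limits.for_effects
    }
    if significant:
        direction = {
            f: (int(np.sign(report.main_effects[f])) if f in significant else 0)
            for f in ("T", "P", "R")
        }
        names = ", ".join(sorted(significant))
        return Decision(
            verdict="shift",
            shift_direction=direction,
            rationale=(
                f"effect(s) {names} exceed the error limit "
                f"±{limits.for_effects:.2f}; move the centre one half-step "
                "per significant main effect"
            ),
        )
    zero = {f: 0 for f in ("T", "P", "R")}
    if report.change_in_mean < -limits.for_change_in_mean:
        return Decision(
            verdict="optimum_reached",
            shift_direction=zero,
            rationale=(
                f"no effect exceeds ±{limits.for_effects:.2f} and the change in "
                f"mean {report.change_in_mean:.2f} is below "
                f"-{limits.for_change_in_mean:.2f}: the centre out-performs its "
                "neighbourhood"
            ),
        )
    return Decision(
        verdict="continue_cycles",
        shift_direction=zero,
        rationale="no effect is significant and the centre does not clearly "
        "dominate; run further cycles to sharpen the error limits",
    )


def build_report(
    ws: Worksheet,
    responses: Sequence[float] | None = None,
    sd_method: str = "pooled",
    sd: float | None = None,
) -> EffectsReport:
    """Assemble the full statistics report for one response vector.

    ``responses`` defaults to the per-run averages across cycles; pass a
    single cycle's responses to reproduce a per-cycle column.
    """
    avg = per_run_averages(ws)
    if ws.n_cycles >= 2:
        diff = per_run_differences(ws, 0, 1)
    else:
        diff = np.zeros(10)
    r = avg if responses is None else np.asarray(responses, dtype=float)
    return EffectsReport(
        per_run_average=tuple(avg),
        per_run_difference=tuple(diff),
        effect_T=main_effect(r, ws, "T"),
        effect_P=main_effect(r, ws, "P"),
        effect_R=main_effect(r, ws, "R"),
        effect_TP=interaction_effect(r, ws, "TP"),
        effect_TR=interaction_effect(r, ws, "TR"),
        effect_PR=interaction_effect(r, ws, "PR"),
        change_in_mean=change_in_mean(r, ws),
        s=estimate_sd(ws, sd_method, fixed=sd),
        n_cycles=ws.n_cycles,
    )
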