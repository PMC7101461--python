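"""Synthetic response surfaces, worksheets and whole EVOP campaigns.

The generator emulates a smooth protease-activity surface — linear in
temperature and wheat-bran fraction, quadratic in pH — with optional
two-factor interactions expressed in coded units, additive Gaussian
measurement noise, and a shared per-cycle offset that mimics
batch-to-batch (cycle) variability.  Because every generated response
has a known analytic value, each stage of the EVOP/surrogate pipeline
can be checked against closed-form ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import FactorSpec, Worksheet, attach_cycle, build_worksheet
from .effects import Decision, EffectsReport, ErrorLimits, build_report, decide, error_limits
from .surrogate import Dataset

__all__ = [
    "TrueSurface",
    "PhaseRecord",
    "CampaignTrace",
    "generate_dataset",
    "generate_worksheet",
    "simulate_campaign",
]

PHASE_SEED_STRIDE = 1000  # child seed = seed + 1000*phase + cycle


class SyntheticError(ValueError):
    """Invalid synthetic-surface specification."""


@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth surface y = b0 + b1*T + b2*WB + b3*pH + b4*pH^2 (+ interactions).

    Interaction coefficients act on coded units (products of -1/0/+1
    levels), so they only contribute where a factorial coding is defined.
    ``noise_sd`` is the additive measurement noise (U/gds), or the
    coefficient of variation when ``noise_model='cv'``; ``cycle_bias_sd``
    is the standard deviation of a per-cycle offset shared by all runs.
    """

    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    beta4: float = 0.0
    gamma_tp: float = 0.0
    gamma_tr: float = 0.0
    gamma_pr: float = 0.0
    noise_sd: float = 0.0
    cycle_bias_sd: float = 0.0
    noise_model: str = "additive"

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.cycle_bias_sd < 0:
            raise SyntheticError("noise_sd and cycle_bias_sd must be >= 0")
        if self.noise_model not in ("additive", "cv"):
            raise SyntheticError(f"unknown noise model {self.noise_model!r}")

    @property
    def has_interactions(self) -> bool:
        return any((self.gamma_tp, self.gamma_tr, self.gamma_pr))

    @property
    def stationary_ph(self) -> float | None:
        """The pH optimum of the noiseless surface (None if not quadratic)."""
        if self.beta4 >= 0:
            return None
        return -self.beta3 / (2.0 * self.beta4)

    def value(self, x, coded: Sequence[int] | None = None) -> np.ndarray:
        """Noiseless surface value at (n, 3) actual conditions (T, %WB, pH)."""
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        y = (
            self.beta0
            + self.beta1 * arr[:, 0]
            + self.beta2 * arr[:, 1]
            + self.beta3 * arr[:, 2]
            + self.beta4 * arr[:, 2] ** 2
        )
        if self.has_interactions:
            if coded is None:
                raise SyntheticError(
                    "surface has coded-unit interactions; a factorial coding is required"
                )
            c = np.atleast_2d(np.asarray(coded, dtype=float))
            y = y + (
                self.gamma_tp * c[:, 0] * c[:, 1]
                + self.gamma_tr * c[:, 0] * c[:, 2]
                + self.gamma_pr * c[:, 1] * c[:, 2]
            )
        return y


def _noise(surface: TrueSurface, mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if surface.noise_sd == 0:
        return np.zeros_like(mean)
    if surface.noise_model == "cv":
        sd = surface.noise_sd * np.abs(mean)
    else:
        sd = np.full_like(mean, surface.noise_sd)
    return rng.normal(0.0, 1.0, size=mean.shape) * sd


def generate_dataset(
    s: TrueSurface, design: Sequence[Sequence[float]], seed: int
) -> Dataset:
    """Noisy observations of the surface at the given (T, %WB, pH) points."""
    x = np.atleast_2d(np.asarray(design, dtype=float))
    if x.shape[1] != 3:
        raise SyntheticError("design points must have 3 columns (T, %WB, pH)")
    rng = np.random.default_rng(seed)
    y = s.value(x) + _noise(s, s.value(x), rng)
    return Dataset.from_records(
        [(float(a), float(b), float(c), float(v)) for (a, b, c), v in zip(x, y)]
    )


def generate_worksheet(
    s: TrueSurface,
    factors: Sequence[FactorSpec],
    n_cycles: int,
    seed: int,
) -> Worksheet:
    """A 10-run worksheet with ``n_cycles`` cycles drawn from the surface.

    Each cycle adds one shared Normal(0, cycle_bias_sd) offset plus
    per-run noise.  Negative draws are clipped to 0 (activities cannot
    be negative); a warning is emitted when clipping occurs since it
    biases the analytic expectations.
    """
    if n_cycles < 1:
        raise SyntheticError("n_cycles must be >= 1")
    ws = build_worksheet(factors)
    # run conditions are stored (T, pH, %WB); the surface takes (T, %WB, pH)
    actual = np.array([r.actual for r in ws.runs])[:, [0, 2, 1]]
    coded = ws.coded_matrix()
    mean = s.value(actual, coded=coded if s.has_interactions else None)
    for c in range(n_cycles):
        rng = np.random.default_rng(seed + c)
        bias = rng.normal(0.0, s.cycle_bias_sd) if s.cycle_bias_sd > 0 else 0.0
        resp = mean + bias + _noise(s, mean, rng)
        if (resp < 0).any():
            warnings.warn("clipping negative synthetic responses to 0", stacklevel=2)
            resp = np.clip(resp, 0.0, None)
        ws = attach_cycle(ws, resp)
    return ws


@dataclass(frozen=True)
class PhaseRecord:
    centre: tuple[float, float, float]
    worksheet: Worksheet
    report: EffectsReport
    limits: ErrorLimits
    decision: Decision


@dataclass(frozen=True)
class CampaignTrace:
    phases: tuple[PhaseRecord, ...]
    final_centre: tuple[float, float, float]
    true_optimum_ph: float | None = None

    @property
    def n_phases(self) -> int:
        return len(self.phases)


def simulate_campaign(
    s: TrueSurface,
    start_factors: Sequence[FactorSpec],
    max_phases: int = 5,
    n_cycles: int = 2,
    seed: int = 0,
) -> CampaignTrace:
    """Run a multi-phase EVOP campaign on the synthetic surface.

    Each phase generates a worksheet at the current centre, computes the
    effects report (pooled s) and applies the decision rule.  A shift
    verdict moves the centre one half-step along each significant main
    effect and opens a new phase; any other verdict — or a shift with no
    significant main effect, which cannot move the centre — ends the
    campaign.  Phase p uses child seed ``seed + 1000 p``.
    """
    if max_phases < 1:
        raise SyntheticError("max_phases must be >= 1")
    if n_cycles < 2:
        raise SyntheticError("campaign phases need >= 2 cycles for a data-driven s")
    factors = tuple(start_factors)
    phases: list[PhaseRecord] = []
    for p in range(max_phases):
        ws = generate_worksheet(s, factors, n_cycles, seed + PHASE_SEED_STRIDE * p)
        report = build_report(ws, sd_method="pooled")
        limits = error_limits(report.s, ws.n_cycles)
        decision = decide(report, limits)
        centre = tuple(f.centre for f in factors)
        phases.append(PhaseRecord(centre, ws, report, limits, decision))
        if decision.verdict != "shift" or all(
            v == 0 for v in decision.shift_direction.values()
        ):
            break
        factors = tuple(
            FactorSpec(f.name, f.units, f.centre + d * f.half_step, f.half_step)
            for f, d in zip(factors, (decision.shift_direction[k] for k in ("T", "P", "R")))
        )
    return CampaignTrace(
        phases=tuple(phases),
        final_centre=tuple(f.centre for f in factors),
        true_optimum_ph=s.stationary_ph,
    )
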