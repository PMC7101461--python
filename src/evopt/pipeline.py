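"""End-to-end pipeline: worksheet analysis -> surrogate fit -> grid optimum.

The bundle produced by :func:`run_full_pipeline` chains the stages the
way the study did: EVOP statistics on the worksheet, assembly of the
per-run averages into a surrogate training table, a surrogate fit
(published polynomial, refit polynomial, or the 3-10-1 network), and an
exhaustive grid optimization of the fitted surface.  The bundle is a
deterministic function of (inputs, config, seed): provenance carries
the package version, the seed and SHA-256 digests of the input files,
but no wall-clock state.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from . import __version__
from .effects import build_report, decide, error_limits
from .grid import DEFAULT_GRID, GridSpec, optimize, top_window_table
from .io import load_dataset_csv, load_worksheet_csv, sha256_of, worksheet_to_dataset
from .network import train_network
from .surrogate import PUBLISHED_POLYNOMIAL, fit_polynomial

__all__ = ["RunConfig", "Bundle", "run_full_pipeline", "bundle_json_schema"]


class RunConfig(BaseModel):
    """Pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    worksheet: Optional[str] = None  # worksheet CSV; default: packaged phase-I table
    dataset: Optional[str] = None  # training CSV; default: averages of the worksheet
    model: Literal["polynomial", "mfnn", "published_polynomial"] = "published_polynomial"
    seed: int = 0
    restarts: int = 64
    sd_method: Literal["fixed", "pooled", "range"] = "fixed"
    sd: Optional[float] = None


class StageEffects(BaseModel):
    per_run_average: list[float]
    per_run_difference: list[float]
    effects: dict[str, float]
    change_in_mean: float
    s: float
    n_cycles: int
    error_limits: dict[str, float]
    decision: dict


class StageFit(BaseModel):
    model: str
    coefficients: Optional[list[float]] = None
    r2_overall: Optional[float] = None
    restart_index: Optional[int] = None
    final_mse: Optional[float] = None


class StageOptimize(BaseModel):
    grid_size: int
    argmax: dict[str, float]
    top_window: list[dict[str, float]]


class Provenance(BaseModel):
    package: str
    version: str
    seed: int
    input_digests: dict[str, str]


class Bundle(BaseModel):
    """Schema of the pipeline's single JSON output."""

    model_config = ConfigDict(extra="forbid")

    provenance: Provenance
    evop: StageEffects
    fit: StageFit
    optimize: StageOptimize


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def run_full_pipeline(config: RunConfig, grid: GridSpec = DEFAULT_GRID) -> Bundle:
    digests: dict[str, str] = {}

    # stage 1: EVOP analysis ------------------------------------------------
    try:
        if config.worksheet is not None:
            ws = load_worksheet_csv(config.worksheet)
            digests["worksheet"] = sha256_of(config.worksheet)
        else:
            from .io import fixture_path, load_table4

            ws = load_table4()
            digests["worksheet"] = sha256_of(fixture_path("table4.csv"))
        sd = config.sd
        if config.sd_method == "fixed" and sd is None:
            # fall back to the pooled estimate so "fixed" without a value works
            report = build_report(ws, sd_method="pooled")
        else:
            report = build_report(ws, sd_method=config.sd_method, sd=sd)
        limits = error_limits(report.s, ws.n_cycles)
        decision = decide(report, limits)
    except Exception as e:
        raise PipelineError(f"stage 'evop' failed: {e}") from e

    # stage 2: training-table assembly --------------------------------------
    try:
        if config.dataset is not None:
            data = load_dataset_csv(config.dataset)
            digests["dataset"] = sha256_of(config.dataset)
        else:
            data = worksheet_to_dataset(ws)
    except Exception as e:
        raise PipelineError(f"stage 'dataset' failed: {e}") from e

    # stage 3: surrogate fit -------------------------------------------------
    try:
        if config.model == "published_polynomial":
            model = PUBLISHED_POLYNOMIAL
            fit = StageFit(model="published_polynomial", coefficients=list(model.coefficients))
        elif config.model == "polynomial":
            model = fit_polynomial(data)
            fit = StageFit(model="polynomial", coefficients=list(model.coefficients))
        else:
            model, fr = train_network(data, seed=config.seed, restarts=config.restarts)
            fit = StageFit(
                model="mfnn",
                r2_overall=fr.r2_overall,
                restart_index=fr.restart_index,
                final_mse=fr.mse,
            )
    except Exception as e:
        raise PipelineError(f"stage 'fit' failed: {e}") from e

    # stage 4: grid optimization ---------------------------------------------
    try:
        res = optimize(model, grid)
        window = top_window_table(res)
        opt = StageOptimize(
            grid_size=grid.size,
            argmax={
                "iteration": float(res.argmax.iteration),
                "temperature_C": float(res.argmax.temperature_C),
                "wb_percent": float(res.argmax.wb_percent),
                "pH": float(res.argmax.pH),
                "predicted": float(res.argmax.predicted),
            },
            top_window=[
                {k: float(v) for k, v in row.items()}
                for row in window.to_dict(orient="records")
            ],
        )
    except Exception as e:
        raise PipelineError(f"stage 'optimize' failed: {e}") from e

    return Bundle(
        provenance=Provenance(
            package="evopt", version=__version__, seed=config.seed, input_digests=digests
        ),
        evop=StageEffects(
            per_run_average=list(report.per_run_average),
            per_run_difference=list(report.per_run_difference),
            effects=report.all_effects,
            change_in_mean=report.change_in_mean,
            s=report.s,
            n_cycles=report.n_cycles,
            error_limits={
                "for_average": limits.for_average,
                "for_effects": limits.for_effects,
                "for_change_in_mean": limits.for_change_in_mean,
            },
            decision={
                "verdict": decision.verdict,
                "shift_direction": decision.shift_direction,
                "rationale": decision.rationale,
            },
        ),
        fit=fit,
        optimize=opt,
    )


def bundle_json_schema() -> dict:
    """JSON-schema export of the bundle model (also shipped as a data file)."""
    return Bundle.model_json_schema()


def write_bundle(bundle: Bundle, path) -> None:
    Path(path).write_text(json.dumps(bundle.model_dump(), indent=2, sort_keys=True))
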