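"""CSV/JSON/YAML readers and writers and the packaged fixture tables.

Worksheet CSV schema: ``run_id, temperature_C, pH, wb_percent,
cycle1, ..., cycleN`` (header required, comma separator, dot decimal,
UTF-8).  Dataset CSV schema: ``temperature_C, wb_percent, pH,
activity``.  Two fixtures ship with the package: the phase-I EVOP
worksheet (``table4.csv``) and the 9-record surrogate training table
(``table2.csv``), both transcribed verbatim from the published study.
"""

from __future__ import annotations

import hashlib
import json
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    CODED_DESIGN,
    RUN_ORDER,
    DesignError,
    FactorSpec,
    Worksheet,
    attach_cycle,
    build_worksheet,
)
from .grid import Axis, GridSpec
from .network import NetworkModel, FitReport
from .surrogate import DATASET_COLUMNS, Dataset, PolynomialModel, SurrogateError

__all__ = [
    "load_worksheet_csv",
    "save_worksheet_csv",
    "load_dataset_csv",
    "save_dataset_csv",
    "worksheet_to_dataset",
    "fixture_path",
    "load_table4",
    "load_table2",
    "save_model_json",
    "load_model_json",
    "load_grid_yaml",
    "sha256_of",
]

WORKSHEET_FIXED_COLUMNS = ("run_id", "temperature_C", "pH", "wb_percent")
_CYCLE_RE = re.compile(r"^cycle(\d+)$")

#: Default units per factor axis.
FACTOR_UNITS = {"temperature": "degC", "pH": "pH", "wb_percent": "%WB"}


class IOError_(ValueError):
    """Malformed input file."""


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture CSV (``table2.csv`` or ``table4.csv``)."""
    return Path(resources.files("evopt.data") / name)


def load_worksheet_csv(path) -> Worksheet:
    """Read and validate a worksheet CSV (runs in A1...A10 order).

    The factor specification is reconstructed from the data: the centre
    is run A1's condition and each half-step the distance from the
    centre to run A2's (the (-,-,-) corner's) condition.
    """
    df = pd.read_csv(path)
    missing = [c for c in WORKSHEET_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing column(s): {', '.join(missing)}")
    cycle_cols = sorted(
        (c for c in df.columns if _CYCLE_RE.match(c)),
        key=lambda c: int(_CYCLE_RE.match(c).group(1)),
    )
    got = list(df["run_id"])
    if got != list(RUN_ORDER):
        absent = sorted(set(RUN_ORDER) - set(got))
        if absent:
            raise IOError_(f"{path}: missing run(s): {', '.join(absent)}")
        raise IOError_(f"{path}: runs must appear in order {', '.join(RUN_ORDER)}")
    for col in ("temperature_C", "pH", "wb_percent", *cycle_cols):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise IOError_(f"{path}: column {col!r} contains non-numeric cells")

    centre = df.iloc[0][["temperature_C", "pH", "wb_percent"]].to_numpy(dtype=float)
    low = df.iloc[1][["temperature_C", "pH", "wb_percent"]].to_numpy(dtype=float)
    half = centre - low  # A2 is the (-1,-1,-1) corner
    if (half <= 0).any():
        raise IOError_(f"{path}: cannot infer positive half-steps from A1/A2")
    factors = tuple(
        FactorSpec(name, FACTOR_UNITS[name], float(c), float(h))
        for name, c, h in zip(("temperature", "pH", "wb_percent"), centre, half)
    )
    ws = build_worksheet(factors)
    # every row must sit on its run's design level
    expect = np.array([r.actual for r in ws.runs])
    actual = df[["temperature_C", "pH", "wb_percent"]].to_numpy(dtype=float)
    if not np.allclose(expect, actual, atol=1e-9):
        bad = RUN_ORDER[int(np.argmax(np.abs(expect - actual).sum(axis=1)))]
        raise IOError_(f"{path}: run {bad} conditions do not match the factorial design")
    for col in cycle_cols:
        try:
            ws = attach_cycle(ws, df[col].to_numpy(dtype=float))
        except DesignError as e:
            raise IOError_(f"{path}: column {col!r}: {e}") from e
    return ws


def save_worksheet_csv(ws: Worksheet, path) -> None:
    df = pd.DataFrame(
        {
            "run_id": ws.run_ids,
            "temperature_C": [r.actual[0] for r in ws.runs],
            "pH": [r.actual[1] for r in ws.runs],
            "wb_percent": [r.actual[2] for r in ws.runs],
        }
    )
    for c, cyc in enumerate(ws.cycles, start=1):
        df[f"cycle{c}"] = cyc
    df.to_csv(path, index=False)


def load_dataset_csv(path) -> Dataset:
    df = pd.read_csv(path)
    if df.empty:
        raise IOError_(f"{path}: dataset file has no records")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing column(s): {', '.join(missing)}")
    for col in DATASET_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise IOError_(f"{path}: column {col!r} contains non-numeric cells")
    try:
        return Dataset(df[list(DATASET_COLUMNS)].astype(float))
    except SurrogateError as e:
        raise IOError_(f"{path}: {e}") from e


def save_dataset_csv(ds: Dataset, path) -> None:
    ds.frame.to_csv(path, index=False)


def load_table4() -> Worksheet:
    """The packaged phase-I EVOP worksheet (10 runs, 2 cycles)."""
    return load_worksheet_csv(fixture_path("table4.csv"))


def load_table2() -> Dataset:
    """The packaged 9-record surrogate training table."""
    return load_dataset_csv(fixture_path("table2.csv"))


def worksheet_to_dataset(ws: Worksheet) -> Dataset:
    """Per-run averages as surrogate training records (%WB encoding)."""
    from .effects import per_run_averages

    avg = per_run_averages(ws)
    return Dataset.from_records(
        [
            (r.actual[0], r.actual[2], r.actual[1], float(a))
            for r, a in zip(ws.runs, avg)
        ]
    )


# --------------------------------------------------------------------------
# model (de)serialization

def save_model_json(model, path, fit_report: FitReport | None = None) -> None:
    if isinstance(model, PolynomialModel):
        doc = {"kind": "polynomial", "coefficients": list(model.coefficients)}
    elif isinstance(model, NetworkModel):
        doc = {
            "kind": "mfnn",
            "w1": model.w1.tolist(),
            "b1": model.b1.tolist(),
            "w2": model.w2.tolist(),
            "b2": model.b2,
            "x_min": model.x_min.tolist(),
            "x_max": model.x_max.tolist(),
            "y_min": model.y_min,
            "y_max": model.y_max,
        }
    else:
        raise IOError_(f"cannot serialize model of type {type(model).__name__}")
    if fit_report is not None:
        doc["fit_report"] = {
            "r2_overall": fit_report.r2_overall,
            "r2_train": fit_report.r2_train,
            "r2_validation": fit_report.r2_validation,
            "r2_test": fit_report.r2_test,
            "restart_index": fit_report.restart_index,
            "mse": fit_report.mse,
            "n_epochs": fit_report.n_epochs,
        }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model_json(path):
    doc = json.loads(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "polynomial":
        return PolynomialModel(*doc["coefficients"])
    if kind == "mfnn":
        return NetworkModel(
            w1=np.asarray(doc["w1"], dtype=float),
            b1=np.asarray(doc["b1"], dtype=float),
            w2=np.asarray(doc["w2"], dtype=float),
            b2=float(doc["b2"]),
            x_min=np.asarray(doc["x_min"], dtype=float),
            x_max=np.asarray(doc["x_max"], dtype=float),
            y_min=float(doc["y_min"]),
            y_max=float(doc["y_max"]),
        )
    raise IOError_(f"{path}: unknown model kind {kind!r}")


def load_grid_yaml(path) -> GridSpec:
    """Grid spec from YAML: per-axis ``low``/``high``/``step`` mappings."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    axes = {}
    for key, name in (("temperature", "temperature_C"), ("wb_percent", "wb_percent"), ("ph", "pH")):
        if key not in doc:
            raise IOError_(f"{path}: missing axis {key!r}")
        spec = doc[key]
        unknown = set(spec) - {"low", "high", "step"}
        if unknown:
            raise IOError_(f"{path}: axis {key!r}: unknown key(s) {sorted(unknown)}")
        axes[key] = Axis(name, float(spec["low"]), float(spec["high"]), float(spec["step"]))
    return GridSpec(temperature=axes["temperature"], wb_percent=axes["wb_percent"], ph=axes["ph"])


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
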