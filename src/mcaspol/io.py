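"""Serialization of results: CSV for traces and sweeps, JSON for records.

Column dictionaries:

* competition trace CSV: ``time``, ``fraction_peak1..N``, ``peak_count``
* phase diagram CSV (long format): ``Dvi``, ``amount``, ``label``,
  ``delta_v``, ``seed``, ``error``
* ROI trace CSV: ``time``, ``roi_id``, ``intensity``
* run records / fit results: JSON objects
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .frap_fit import FitResult
from .peaks import CompetitionTrace
from .assays import PhaseDiagram

__all__ = [
    "trace_to_frame",
    "frame_to_trace",
    "write_trace",
    "read_trace",
    "write_phase_diagram",
    "read_phase_diagram",
    "fit_result_to_dict",
    "write_json",
    "RunRecord",
]


class SchemaError(ValueError):
    """A result file is missing a required column or field."""


def trace_to_frame(trace: CompetitionTrace) -> pd.DataFrame:
    cols = {"time": trace.times}
    for i in range(trace.n_tracked):
        cols[f"fraction_peak{i + 1}"] = trace.fractions[i]
    cols["peak_count"] = trace.peak_counts
    return pd.DataFrame(cols)


def frame_to_trace(df: pd.DataFrame, meta: dict | None = None) -> CompetitionTrace:
    for col in ("time", "peak_count"):
        if col not in df.columns:
            raise SchemaError(f"trace table is missing column {col!r}")
    fcols = sorted((c for c in df.columns if c.startswith("fraction_peak")),
                   key=lambda c: int(c.rsplit("peak", 1)[1]))
    if not fcols:
        raise SchemaError("trace table has no fraction_peak columns")
    return CompetitionTrace(
        times=df["time"].to_numpy(dtype=float),
        fractions=np.stack([df[c].to_numpy(dtype=float) for c in fcols]),
        peak_counts=df["peak_count"].to_numpy(dtype=int),
        meta=dict(meta or {}),
    )


def write_trace(trace: CompetitionTrace, path: str | Path) -> None:
    trace_to_frame(trace).to_csv(path, index=False)


def read_trace(path: str | Path) -> CompetitionTrace:
    return frame_to_trace(pd.read_csv(path))


PHASE_COLUMNS = ("Dvi", "amount", "label", "delta_v", "seed")


def write_phase_diagram(pd_obj: PhaseDiagram, path: str | Path) -> None:
    pd_obj.table.to_csv(path, index=False)


def read_phase_diagram(path: str | Path) -> PhaseDiagram:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in PHASE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"phase diagram table is missing column {col!r}")
    Dvi_values = tuple(sorted(df["Dvi"].unique()))
    amount_values = tuple(sorted(df["amount"].unique()))
    labels = np.empty((len(Dvi_values), len(amount_values)), dtype=object)
    delta = np.full(labels.shape, np.nan)
    for _, row in df.iterrows():
        i = Dvi_values.index(row["Dvi"])
        j = amount_values.index(row["amount"])
        labels[i, j] = row["label"]
        delta[i, j] = row["delta_v"]
    return PhaseDiagram(Dvi_values, amount_values, labels, delta, df)


def fit_result_to_dict(fit: FitResult) -> dict:
    d = dataclasses.asdict(fit)
    d["ci95"] = {k: list(v) for k, v in fit.ci95.items()}
    return d


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


@dataclasses.dataclass
class RunRecord:
    """Reproducibility record written next to every CLI output."""

    command: str
    config: dict
    seeds: dict
    wall_time_s: float
    outputs: list[str]
    conservation_audit: dict = dataclasses.field(default_factory=dict)
    package_version: str = ""
    python_version: str = dataclasses.field(default_factory=platform.python_version)
    timestamp: float = dataclasses.field(default_factory=time.time)

    def write(self, path: str | Path) -> None:
        write_json(dataclasses.asdict(self), path)
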