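"""Recording and model file formats, plus the persisted run configuration.

Recordings are two-column delimited text (time_s, value) with optional
``#``-prefixed ``key: value`` header lines; the reader sniffs the delimiter
and also accepts single-column files when a sample rate is declared (in the
header or by the caller).  Models are versioned JSON documents.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ModelIOError, ValidationError
from .ocsvm import OneClassSvmModel
from .preprocess import Scaler
from .recording import FlowRecording

MODEL_SCHEMA = "valvemonitor.ocsvm/1"

_DELIMITERS = (",", ";", "\t", None)  # None = any whitespace


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def _sniff_delimiter(line: str) -> str | None:
    for delim in (",", ";", "\t"):
        if delim in line:
            return delim
    return None


def write_recording(recording: FlowRecording, path) -> None:
    """Write the two-column text format with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# sample_rate: {recording.sample_rate}\n")
        fh.write(f"# units: {recording.units}\n")
        if recording.scenario is not None:
            fh.write(f"# scenario: {recording.scenario}\n")
        if "config" in recording.meta:
            fh.write(f"# config: {json.dumps(recording.meta['config'])}\n")
        fh.write("# columns: time_s\tvalue\n")
        for t, v in zip(recording.times, recording.values):
            fh.write(f"{t:.10g}\t{v:.10g}\n")


def read_recording(
    path,
    delimiter: str | None = "auto",
    sample_rate: float | None = None,
    time_column: int = 0,
    value_column: int = 1,
) -> FlowRecording:
    """Read a recording from delimited text.

    ``delimiter="auto"`` sniffs comma/semicolon/tab, falling back to
    whitespace.  Single-column files need ``sample_rate`` (argument or
    ``# sample_rate:`` header); times are then reconstructed as ``i / fs``.
    Malformed rows are reported with their line number.
    """
    if not os.path.exists(path):
        raise ModelIOError(f"recording file not found: {path}")
    header_lines: list[str] = []
    rows: list[list[float]] = []
    data_delim = delimiter
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#") or line.startswith("%"):
                header_lines.append(line)
                continue
            if data_delim == "auto":
                data_delim = _sniff_delimiter(line)
            parts = line.split(data_delim) if data_delim else line.split()
            try:
                rows.append([float(p) for p in parts if p != ""])
            except ValueError:
                # tolerate one non-numeric leading line (column names)
                if not rows:
                    header_lines.append(line)
                    continue
                raise ValidationError(
                    f"{path}: malformed row at line {lineno}: {line!r}"
                ) from None
    if not rows:
        raise ValidationError(f"{path}: no data rows found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValidationError(
            f"{path}: inconsistent column counts {sorted(widths)}"
        )
    width = widths.pop()
    meta = _parse_header(header_lines)
    declared_rate = sample_rate
    if declared_rate is None and "sample_rate" in meta:
        declared_rate = float(meta["sample_rate"])

    data = np.asarray(rows, dtype=float)
    if width == 1:
        if declared_rate is None:
            raise ValidationError(
                f"{path}: single-column file needs a declared sample rate"
            )
        rec = FlowRecording.from_values(data[:, 0], sample_rate=declared_rate)
        times, values, rate = rec.times, rec.values, declared_rate
    else:
        if max(time_column, value_column) >= width:
            raise InputError(
                f"{path}: requested columns ({time_column}, {value_column}) "
                f"but file has {width}"
            )
        times = data[:, time_column]
        values = data[:, value_column]
        if times.size < 2:
            raise ValidationError(f"{path}: need at least two samples")
        dt = np.median(np.diff(times))
        if dt <= 0:
            raise ValidationError(f"{path}: times are not increasing")
        rate = declared_rate if declared_rate is not None else 1.0 / dt

    scenario = meta.get("scenario")
    units = meta.get("units", "ml/s")
    full_meta: dict = {"source_path": str(path)}
    if "config" in meta:
        try:
            full_meta["config"] = json.loads(meta["config"])
        except json.JSONDecodeError:
            pass
    return FlowRecording(
        times=times,
        values=values,
        sample_rate=float(rate),
        units=units,
        scenario=scenario,
        meta=full_meta,
    )


def save_model(model: OneClassSvmModel, path) -> None:
    """Serialize a trained model as versioned JSON (text, round-trip exact)."""
    doc = {
        "schema": MODEL_SCHEMA,
        "support_vectors": model.support_vectors.tolist(),
        "alphas": model.alphas.tolist(),
        "rho": model.rho,
        "gamma": model.gamma,
        "nu": model.nu,
        "l": model.l,
        "training_score": model.training_score,
        "dual_objective": model.dual_objective,
        "n_iterations": model.n_iterations,
        "kkt_violation": model.kkt_violation,
        "boundary_tol": model.boundary_tol,
        "slicing_anchor": model.slicing_anchor,
        "columns": list(model.columns) if model.columns else None,
        "scaler": (
            {
                "mean": model.scaler.mean.tolist(),
                "sd": model.scaler.sd.tolist(),
                "columns": list(model.scaler.columns),
            }
            if model.scaler is not None
            else None
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path) -> OneClassSvmModel:
    """Load a model; schema mismatches and corruption raise ModelIOError."""
    if not os.path.exists(path):
        raise ModelIOError(f"model file not found: {path}")
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelIOError(f"corrupt model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise ModelIOError(
            f"unsupported model schema {doc.get('schema') if isinstance(doc, dict) else None!r} "
            f"(expected {MODEL_SCHEMA!r})"
        )
    try:
        scaler = None
        if doc.get("scaler") is not None:
            s = doc["scaler"]
            scaler = Scaler(
                mean=np.asarray(s["mean"], dtype=float),
                sd=np.asarray(s["sd"], dtype=float),
                columns=tuple(s["columns"]),
            )
        return OneClassSvmModel(
            support_vectors=np.asarray(doc["support_vectors"], dtype=float),
            alphas=np.asarray(doc["alphas"], dtype=float),
            rho=float(doc["rho"]),
            gamma=float(doc["gamma"]),
            nu=float(doc["nu"]),
            l=int(doc["l"]),
            training_score=float(doc.get("training_score", math.nan)),
            dual_objective=float(doc.get("dual_objective", math.nan)),
            n_iterations=int(doc.get("n_iterations", 0)),
            kkt_violation=float(doc.get("kkt_violation", math.nan)),
            boundary_tol=float(doc.get("boundary_tol", 1e-6)),
            scaler=scaler,
            columns=tuple(doc["columns"]) if doc.get("columns") else None,
            slicing_anchor=doc.get("slicing_anchor", "minimum"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"incomplete model file {path}: {exc}") from exc


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, persisted next to outputs."""

    recordings: list[str] = field(default_factory=list)
    model_path: str | None = None
    output_path: str | None = None
    n_features: int = 2
    slicing_anchor: str = "minimum"
    nu: float = 0.05
    gamma: float = 7.0
    tol: float = 1e-6
    holdout: float = 0.0
    nu_grid: list[float] = field(default_factory=lambda: [0.01, 0.05, 0.1, 0.2])
    gamma_grid: list[float] = field(default_factory=lambda: [0.1, 1.0, 7.0, 20.0, 100.0])
    alpha: float = 0.01
    seed: int | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")
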