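"""Configuration, tabular readers/writers and provenance records."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import LengthPoint, LengthSeries
from .errors import InvalidInputError
from .mechanics import SensorDesign

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "load_design",
    "read_length_series",
    "write_length_series",
    "write_report",
    "write_provenance",
]

_SCHEMA_VERSION = "1"
_KNOWN_KEYS = {
    "design", "data", "output_dir", "noise_floor", "n_boot", "seed",
    "gates", "log_level", "lp_grid", "length_grid", "free_parameters",
}
_DEFAULTS = {
    "noise_floor": 0.05,
    "n_boot": 200,
    "seed": 0,
    "log_level": "INFO",
    "free_parameters": ["LP"],
}


@dataclass
class RunConfig:
    """Validated analysis configuration with defaults applied."""

    design: dict | None = None
    data: dict = field(default_factory=dict)
    output_dir: str = "."
    noise_floor: float = 0.05
    n_boot: int = 200
    seed: int = 0
    gates: list | None = None
    log_level: str = "INFO"
    lp_grid: list | None = None
    length_grid: list | None = None
    free_parameters: list = field(default_factory=lambda: ["LP"])

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def sensor_design(self) -> SensorDesign:
        if self.design is None:
            raise InvalidInputError("config has no design block")
        return SensorDesign.from_dict(self.design)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected (naming them); missing optional keys receive
    defaults (noise_floor 0.05, n_boot 200, seed 0).
    """
    path = Path(path)
    text = path.read_text()
    raw = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text)) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config root must be a mapping: {path}")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise InvalidInputError(f"unknown config keys: {', '.join(unknown)}")
    merged = {**_DEFAULTS, **raw}
    if not float(merged["seed"]).is_integer():
        raise InvalidInputError("seed must be an integer")
    merged["seed"] = int(merged["seed"])
    cfg = RunConfig(**merged)
    for role, p in (cfg.data or {}).items():
        if not Path(p).exists():
            raise InvalidInputError(f"data path for {role!r} not found: {p}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    payload = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_design(path) -> SensorDesign:
    """Read a sensor design from a YAML/JSON file (keys pair/domain/env)."""
    path = Path(path)
    text = path.read_text()
    raw = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text))
    return SensorDesign.from_dict(raw)


_SERIES_COLUMNS = ("context", "repeat", "n_repeats", "efficiency_mean",
                   "efficiency_sem")


def read_length_series(path) -> LengthSeries:
    """Read a FRET-length series CSV.

    Required columns: context, repeat, n_repeats, efficiency_mean; the
    efficiency_sem column is optional (defaults to 0 with a warning).
    Non-numeric cells are reported with their row index.
    """
    import warnings

    df = pd.read_csv(path, comment="#")
    missing = [c for c in _SERIES_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing column(s) {', '.join(missing)}")
    if "efficiency_sem" not in df.columns:
        warnings.warn(f"{path}: no efficiency_sem column; "
                      "uncertainties default to 0")
        df["efficiency_sem"] = 0.0
    for col in ("n_repeats", "efficiency_mean", "efficiency_sem"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        if bad or vals.isna().any():
            rows = bad or df.index[vals.isna()].tolist()
            raise InvalidInputError(
                f"{path}: non-numeric or missing {col} at row(s) {rows}")
        df[col] = vals
    contexts = df["context"].unique()
    repeats = df["repeat"].unique()
    if len(contexts) != 1 or len(repeats) != 1:
        raise InvalidInputError(
            f"{path}: expected a single context and repeat per file, got "
            f"{list(contexts)} / {list(repeats)}")
    points = [LengthPoint(int(r.n_repeats), float(r.efficiency_mean),
                          float(r.efficiency_sem))
              for r in df.itertuples()]
    return LengthSeries(str(contexts[0]), str(repeats[0]), points)


def write_length_series(series: LengthSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tsmod length-series schema v{_SCHEMA_VERSION}\n")
        pd.DataFrame([{
            "context": series.context_label,
            "repeat": series.repeat_sequence,
            "n_repeats": p.n_repeats,
            "efficiency_mean": p.efficiency_mean,
            "efficiency_sem": p.efficiency_sem,
        } for p in series.points]).to_csv(fh, index=False)


def write_report(obj, path) -> None:
    """Write any report object (dict or dataclass with to_dict) as JSON."""
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)


def write_provenance(out_dir, command: str, seed: int | None,
                     config: dict | None = None) -> Path:
    """Drop a provenance JSON (version, command, seed, config hash)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config or {}, sort_keys=True, default=str)
    record = {
        "tool": "tsmod",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
    }
    path = out_dir / f"provenance_{command}.json"
    path.write_text(json.dumps(record, indent=2))
    return path
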