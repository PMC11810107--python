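"""Canonical table schemas, validated IO, and run configuration.

All tables are delimited text (comma by default, tab accepted) with a
header row; output files carry ``#``-prefixed provenance lines (package
version, config hash, seed) so every result can be traced to the exact
run that produced it. Readers validate required columns and dtypes and
report offending row numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .config import Perturbation, SimConfig

__all__ = [
    "SchemaError",
    "CELL_REQUIRED",
    "CELL_OPTIONAL",
    "TRACK_REQUIRED",
    "BULK_REQUIRED",
    "read_cells",
    "read_tracks",
    "read_bulk",
    "write_table",
    "RunConfig",
]

CELL_REQUIRED = (
    "cell_id",
    "well_id",
    "condition",
    "fixation_time_h",
    "cfz_flag",
    "chx_flag",
    "dna",
    "geminin",
    "size_se",
)
CELL_OPTIONAL = ("aha", "k48", "mv151", "stage", "ell")
CELL_NUMERIC = ("fixation_time_h", "dna", "geminin", "size_se", "aha", "k48", "mv151", "ell")

TRACK_REQUIRED = (
    "track_id",
    "time_h",
    "nuclear_area",
    "geminin",
    "birth_time_h",
    "g1s_time_h",
    "division_time_h",
    "complete",
)
BULK_REQUIRED = ("time_h", "cell_count", "mean_size")


class SchemaError(ValueError):
    pass


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, comment="#", encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as e:  # malformed text
        raise SchemaError(f"{path}: cannot parse delimited text ({e})") from e


def _require(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, cols, path, finite=True) -> pd.DataFrame:
    for col in cols:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row}"
            )
        if finite and np.isinf(coerced.to_numpy(dtype=float)).any():
            row = int(np.isinf(coerced.to_numpy(dtype=float)).argmax()) + 2
            raise SchemaError(f"{path}: non-finite value in column {col!r} at line {row}")
        df[col] = coerced
    return df


def _boolean(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    truthy = {"true": True, "1": True, "false": False, "0": False}
    for col in cols:
        if col not in df.columns:
            continue
        if df[col].dtype == bool:
            continue
        mapped = df[col].astype(str).str.strip().str.lower().map(truthy)
        if mapped.isna().any():
            row = int(mapped.isna().idxmax()) + 2
            raise SchemaError(f"{path}: non-boolean value in column {col!r} at line {row}")
        df[col] = mapped.astype(bool)
    return df


def read_cells(path) -> pd.DataFrame:
    """Read and validate a CellRecord table.

    Enforces the required columns, numeric/boolean dtypes and the
    invariant that each well maps to exactly one (condition, cfz_flag,
    chx_flag, fixation_time_h) combination.
    """
    df = _read_delimited(path)
    _require(df, CELL_REQUIRED, path)
    df = _numeric(df, CELL_NUMERIC, path)
    df = _boolean(df, ("cfz_flag", "chx_flag"), path)
    meta = df.groupby("well_id")[["condition", "cfz_flag", "chx_flag", "fixation_time_h"]]
    bad = meta.nunique().gt(1).any(axis=1)
    if bad.any():
        raise SchemaError(
            f"{path}: well(s) {list(bad[bad].index)} map to more than one "
            "(condition, cfz, chx, fixation time) combination"
        )
    return df


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a long-format Track table."""
    df = _read_delimited(path)
    _require(df, TRACK_REQUIRED, path)
    df = _numeric(
        df, ("time_h", "nuclear_area", "geminin", "birth_time_h"), path
    )
    # landmark times may legitimately be missing (incomplete tracks)
    for col in ("g1s_time_h", "division_time_h"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _boolean(df, ("complete",), path)
    complete = df[df["complete"]]
    if complete["division_time_h"].isna().any():
        raise SchemaError(f"{path}: complete tracks must have a division time")
    return df


def read_bulk(path) -> pd.DataFrame:
    """Read and validate a BulkTimepoint table."""
    df = _read_delimited(path)
    _require(df, BULK_REQUIRED, path)
    df = _numeric(df, BULK_REQUIRED, path)
    if (df["cell_count"] <= 0).any():
        row = int((df["cell_count"] <= 0).idxmax()) + 2
        raise SchemaError(f"{path}: non-positive cell count at line {row}")
    return df


def write_table(df: pd.DataFrame, path, provenance: Mapping[str, Any] | None = None) -> None:
    """Write a table as CSV with ``#`` provenance header lines.

    Provenance contains no timestamps: identical runs produce
    byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def _dataclass_from_dict(cls, data: Mapping[str, Any], context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise SchemaError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, keyed per module.

    Unknown keys are rejected on load; defaults are the module defaults.
    The config (and its hash) is echoed into the provenance header of
    every output table.
    """

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    conditions: tuple[str, ...] = ("control", "CDK2i")
    treat_h: float = 24.0
    n_tracks: int = 100
    # staging
    staging_min_cells: int = 500
    # trajectory
    trajectory_grid: int = 200
    trajectory_density_floor: float = 0.01
    heatmap_ell_bins: int = 12
    heatmap_size_bins: int = 12
    heatmap_min_cells: int = 20
    # turnover
    turnover_centre: str = "median"
    n_boot: int = 2000
    # growth
    smooth_window: int = 5
    trim_frames: int = 6
    size_percentiles: tuple[float, float] = (20.0, 80.0)
    bulk_timepoints: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data or {})
        sim_data = dict(data.pop("sim", {}) or {})
        pert_data = sim_data.pop("perturbations", None)
        sim = _dataclass_from_dict(SimConfig, sim_data, "sim")
        if pert_data is not None:
            perts = dict(sim.perturbations)
            for name, overrides in pert_data.items():
                perts[name] = _dataclass_from_dict(
                    Perturbation, overrides or {}, f"sim.perturbations.{name}"
                )
            sim = sim.replace(perturbations=perts)
        for key in ("conditions", "bulk_timepoints", "size_percentiles"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        cfg = _dataclass_from_dict(cls, {"sim": sim, **data}, "run config")
        cfg.sim.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["perturbations"] = {
            k: dataclasses.asdict(v) for k, v in self.sim.perturbations.items()
        }
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode("utf8")
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        from . import __version__

        return {
            "sizeflux_version": __version__,
            "config_sha256": self.digest(),
            "seed": self.sim.seed,
        }
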