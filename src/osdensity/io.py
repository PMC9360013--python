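"""Configuration and table I/O.

All interchange is plain CSV with explicit headers.  Files written by the
pipeline carry a leading comment line recording the package version, master
seed and configuration hash, so any output can be traced to the exact run
that produced it.  Readers validate schemas eagerly and report the offending
column/row, since silent schema drift is the usual failure mode of
long-format spectroscopy tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import WAVELENGTH_MAX, WAVELENGTH_MIN, FitBounds
from .synthetic_cohort import (CohortConfig, GroupParams, _daughter_defaults,
                               _mother_defaults)

__version__ = "0.1.0"

log = logging.getLogger("osdensity")


@dataclass(frozen=True)
class PipelineConfig:
    """Master configuration for a pipeline run.

    Defaults reproduce the constants of the measurement protocol (fit
    bounds, QC rules are fixed in code) and the default synthetic-cohort
    conditions.  Unknown keys in a config file are rejected.
    """

    seed: int = 1
    basis: str = "default"
    n_starts: int = 8
    log_residuals: bool = True
    equal_var: bool = True
    log_level: str = "INFO"
    bounds: FitBounds = field(default_factory=FitBounds)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def to_dict(self) -> dict:
        return _asdict_plain(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _dataclass_from_dict(cls, data, "config")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _asdict_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_asdict_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _dataclass_from_dict(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ValueError(f"{where}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    nested = {"bounds": (FitBounds, FitBounds),
              "cohort": (CohortConfig, CohortConfig),
              "daughters": (GroupParams, _daughter_defaults),
              "mothers": (GroupParams, _mother_defaults)}
    for key, value in data.items():
        if key in nested and isinstance(value, dict):
            cls_, default_factory = nested[key]
            merged = _asdict_plain(default_factory()) | value
            kwargs[key] = _dataclass_from_dict(cls_, merged, f"{where}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


# --------------------------------------------------------------------------
# CSV round-trip with provenance header

def write_table(df: pd.DataFrame, path: str | Path, *, seed: int,
                config_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# osdensity {__version__} | seed={seed} | config={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"required input {path} is missing; run the producing stage first")
    return pd.read_csv(path, comment="#")


# --------------------------------------------------------------------------
# Schema validation

SPECTRA_KEY = ["participant_id", "side", "cup_size", "offset_mm", "position",
               "wavelength_nm"]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table: missing columns {missing}")


def _require_numeric(df: pd.DataFrame, cols: list[str], name: str) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(f"{name} table: non-numeric value in column {c!r} "
                             f"at row {bad[0]}")
        df[c] = vals


def read_spectra_table(path: str | Path) -> pd.DataFrame:
    """Long-format spectra CSV, schema-checked.

    Wavelengths must lie in the instrument band; the
    (participant, side, cup, offset, position, wavelength) key must be
    unique; usable rows must carry positive signals.
    """
    df = read_table(path)
    _require_columns(df, SPECTRA_KEY + ["signal", "usable"], "spectra")
    _require_numeric(df, ["offset_mm", "position", "wavelength_nm", "signal",
                          "usable"], "spectra")
    out_of_band = df.index[(df["wavelength_nm"] < WAVELENGTH_MIN)
                           | (df["wavelength_nm"] > WAVELENGTH_MAX)]
    if len(out_of_band):
        row = out_of_band[0]
        raise ValueError(
            f"spectra table: wavelength {df.loc[row, 'wavelength_nm']} nm at row "
            f"{row} outside [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}]")
    dup = df.duplicated(subset=SPECTRA_KEY)
    if dup.any():
        row = df.index[dup][0]
        key = tuple(df.loc[row, SPECTRA_KEY])
        raise ValueError(f"spectra table: duplicate key {key} at row {row}")
    usable = df["usable"].astype(float)
    if not set(np.unique(usable)) <= {0.0, 1.0}:
        raise ValueError("spectra table: 'usable' must be 0 or 1")
    bad_sig = df.index[(usable == 1) & ~(df["signal"] > 0)]
    if len(bad_sig):
        raise ValueError(f"spectra table: non-positive usable signal at row {bad_sig[0]}")
    return df


def read_volumetrics_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    cols = ["participant_id", "vol_left_cm3", "vol_right_cm3",
            "fgv_left_cm3", "fgv_right_cm3", "dense_left_cm3", "dense_right_cm3"]
    _require_columns(df, cols, "volumetrics")
    _require_numeric(df, cols[1:], "volumetrics")
    if df["participant_id"].duplicated().any():
        raise ValueError("volumetrics table: duplicate participant_id")
    for side in ("left", "right"):
        vol = df[f"vol_{side}_cm3"]
        if (vol <= 0).any():
            raise ValueError(f"volumetrics table: non-positive vol_{side}_cm3")
        for kind in ("fgv", "dense"):
            v = df[f"{kind}_{side}_cm3"]
            bad = df.index[v.notna() & ((v < 0) | (v > vol))]
            if len(bad):
                raise ValueError(
                    f"volumetrics table: {kind}_{side}_cm3 outside [0, volume] "
                    f"at row {bad[0]}")
    return df


def read_covariates_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    cols = ["participant_id", "pair_id", "group", "age", "bmi"]
    _require_columns(df, cols, "covariates")
    _require_numeric(df, ["age", "bmi"], "covariates")
    if df["participant_id"].duplicated().any():
        raise ValueError("covariates table: duplicate participant_id")
    bad_group = ~df["group"].isin(["daughter", "mother"])
    if bad_group.any():
        raise ValueError(
            f"covariates table: group must be daughter|mother, got "
            f"{df.loc[df.index[bad_group][0], 'group']!r}")
    if (df["age"] <= 0).any() or (df["bmi"] <= 0).any():
        raise ValueError("covariates table: age and bmi must be > 0")
    return df


def read_tables(spectra_path, volumetrics_path, covariates_path) -> dict[str, pd.DataFrame]:
    """Load and validate the three pipeline inputs."""
    return {
        "spectra": read_spectra_table(spectra_path),
        "volumetrics": read_volumetrics_table(volumetrics_path),
        "covariates": read_covariates_table(covariates_path),
    }
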