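"""Trial-table readers/writers, configuration files, and run manifests.

The sole trial-table format is UTF-8 comma-separated text with a header
row; one row per trial, missing values as empty fields.  The column
dictionary is documented in ``docs/trial_table.md``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .normative import DPConfig
from .task import _COLUMNS, AgentParams, DesignSpec

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "load_config",
    "write_manifest",
]

TRIAL_COLUMNS = list(_COLUMNS)

_NUMERIC = [c for c in TRIAL_COLUMNS if c not in ("trial_type",)]


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (header row, empty fields for missing)."""
    table.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path, confidence_scale: str = "unit") -> pd.DataFrame:
    """Read and validate a trial table.

    ``confidence_scale="percent"`` accepts ratings on the 0-100 scale and
    divides by 100.  Rows violating basic invariants (negative RTs,
    confidence outside range, unknown trial type) are dropped with a
    warning naming their line numbers; a wrong header raises.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[TRIAL_COLUMNS]
    for c in _NUMERIC:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if confidence_scale == "percent":
        df["confidence"] = df["confidence"] / 100.0
    elif confidence_scale != "unit":
        raise ValueError("confidence_scale must be 'unit' or 'percent'")

    bad = pd.Series(False, index=df.index)
    bad |= ~df["trial_type"].isin(["double", "D1star", "D2star", "D1catch"])
    for col in ("rt1_s", "rt2_s"):
        bad |= df[col].notna() & (df[col] <= 0)
    for col in ("confidence", "conf_true"):
        bad |= df[col].notna() & ((df[col] < 0) | (df[col] > 1))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header row, 1-based
        warnings.warn(
            f"{path}: rejected {int(bad.sum())} malformed rows "
            f"(file lines {lines[:20]}{'...' if len(lines) > 20 else ''})"
        )
        df = df.loc[~bad]
    return df.reset_index(drop=True)


def _build(cls, block: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
    }
    return cls(**kwargs)


def load_config(path) -> dict:
    """Load a YAML run configuration.

    Recognized top-level blocks: ``design`` (DesignSpec), ``agent``
    (AgentParams), ``dp`` (DPConfig), ``fitting`` (free-form dict).
    Absent blocks get defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {
        "design": _build(DesignSpec, raw.get("design", {})),
        "agent": _build(AgentParams, raw.get("agent", {})),
        "dp": _build(DPConfig, raw.get("dp", {})),
        "fitting": raw.get("fitting", {}),
    }


def write_manifest(outdir, config: dict | None, seed: int | None, extra: dict | None = None) -> Path:
    """Record config, seed, and software version next to a run's outputs."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def jsonable(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    payload = {
        "version": __version__,
        "seed": seed,
        "config": {k: jsonable(v) for k, v in (config or {}).items()},
    }
    if extra:
        payload.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
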