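"""Delimited-table and configuration I/O with schema validation.

All tables are comma-separated UTF-8 text with a mandatory header row and
period decimal separator; numeric round-trips are lossless at full float
precision.  Every CLI run emits a provenance record (configuration hash,
seed, package version) alongside its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, ParseError

#: column -> required dtype kind ('f' float, 's' string) per table schema
SCHEMAS = {
    "crc": {"replicate_id": "s", "condition": "s",
            "concentration_um": "f", "response": "f"},
    "trace": {"time": "f", "response": "f"},
    "racemization": {"time_min": "f", "activity": "f"},
    "mutant_panel": {"construct": "s", "replicate_id": "s",
                     "percent_of_control": "f"},
    "mutant_raw": {"construct": "s", "replicate_id": "s",
                   "response_modulator": "f", "response_control": "f"},
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema.

    Missing columns and non-numeric cells (including locale-style comma
    decimals) raise :class:`ParseError` with row/column coordinates.
    """
    if schema not in SCHEMAS:
        raise ConfigurationError(f"unknown table schema {schema!r}")
    spec = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(spec) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out = {}
    for col, kind in spec.items():
        if kind == "s":
            out[col] = df[col]
            continue
        values = np.empty(len(df))
        for i, cell in enumerate(df[col]):
            try:
                values[i] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} in column "
                    f"{col!r}, row {i + 2}") from None
        out[col] = values
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as comma-separated UTF-8 with full float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def load_scheme_config(path) -> dict:
    """Load a scheme configuration from YAML (or JSON, a YAML subset)."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: malformed configuration: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    return cfg


def dump_config(cfg: dict, path=None) -> str:
    text = yaml.safe_dump(cfg, sort_keys=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def provenance_record(config: dict, seed: int | None = None) -> dict:
    """Reproducibility stamp: configuration hash, seed, package version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "allomod_version": __version__,
    }


def write_json(payload: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
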