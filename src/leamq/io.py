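"""Schema-validated CSV readers/writers, configuration and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError


@dataclass(frozen=True)
class TableSchema:
    """Declarative schema for a delimited input table."""

    name: str
    required: tuple[str, ...]
    id_column: str = "athlete_id"
    string_columns: tuple[str, ...] = ()
    categorical: Mapping[str, tuple] = field(default_factory=dict)


RESPONSE_SCHEMA = TableSchema(
    name="responses",
    required=("athlete_id", "version"),
    string_columns=("athlete_id", "version"),
    categorical={"version": ("v1", "v2")},
)

CLINICAL_SCHEMA = TableSchema(
    name="clinical",
    required=("athlete_id",),
    string_columns=("athlete_id", "centre", "rmr_method"),
    categorical={"rmr_method": ("first_principles", "metabolic_cart")},
)


def load_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV table, collecting every row/column problem
    into one :class:`SchemaError` so callers see all diagnostics at once."""
    df = pd.read_csv(path, dtype={c: str for c in schema.string_columns})
    errors: list[str] = []

    for col in schema.required:
        if col not in df.columns:
            errors.append(f"{schema.name}: missing required column {col!r}")
    if schema.id_column in df.columns:
        dup = df[schema.id_column][df[schema.id_column].duplicated()].unique()
        if dup.size:
            errors.append(f"{schema.name}: duplicate {schema.id_column}: {sorted(dup)}")
    for col, allowed in schema.categorical.items():
        if col in df.columns:
            bad = df[col].dropna()[~df[col].dropna().isin(allowed)].unique()
            if bad.size:
                errors.append(f"{schema.name}: column {col!r} has values {sorted(bad)} "
                              f"outside {allowed}")
    for col in df.columns:
        if col in schema.string_columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()]
        if len(bad_rows):
            errors.append(f"{schema.name}: non-numeric cells in column {col!r} "
                          f"rows {list(bad_rows[:5])}")
        else:
            df[col] = coerced
    if errors:
        raise SchemaError(errors)
    return df


def load_config(path) -> dict:
    """YAML/JSON pipeline configuration (scoring key, reference ranges,
    pipeline options) as a plain dict; empty file -> empty dict."""
    p = Path(path)
    try:
        with open(p) as fh:
            if p.suffix == ".json":
                return json.load(fh) or {}
            return yaml.safe_load(fh) or {}
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse config {p}: {exc}") from exc


def digest(obj) -> str:
    """Stable SHA-256 digest of a JSON-serialisable object or a file path."""
    if isinstance(obj, (str, Path)) and Path(obj).is_file():
        return hashlib.sha256(Path(obj).read_bytes()).hexdigest()
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_report(results, out_dir, timestamp: Optional[str] = None) -> list[Path]:
    """Write the result tables and the JSON run manifest to ``out_dir``.

    Output is deterministic (fixed column order, sorted manifest keys);
    the timestamp is included only when supplied so that reruns with the
    same manifest are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("associations", "roc", "clinical_comparison", "score_comparison",
                 "classification", "scores"):
        table = getattr(results, name, None)
        if table is None:
            continue
        p = out / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    manifest = dict(results.manifest)
    if timestamp is not None:
        manifest["timestamp"] = timestamp
    p = out / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written
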