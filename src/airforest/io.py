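"""Delimited-text input with a schema sidecar, plus run manifests.

A dataset is a CSV/TSV file with a header row.  The sidecar (YAML or
JSON, YAML being a superset) declares the outcome column and per-column
kinds::

    outcome: {name: y, kind: binary}
    covariates:
      - {name: age, kind: continuous}
      - {name: genotype, kind: snp}
      - {name: tissue, kind: nominal, levels: [liver, kidney, brain]}

Without a sidecar, the outcome defaults to the column named ``y`` (or
the last column) and covariate kinds are inferred from dtypes: numeric
columns are continuous, non-numeric ones nominal with levels taken from
the data (logged).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .data import ColumnSchema, DataMatrix, infer_covariate_schema
from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DataError(f"empty dataset file: {path}") from None
    if df.shape[0] == 0:
        raise DataError(f"dataset {path} has a header but no rows")
    return df


def read_schema(path) -> dict:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "outcome" not in spec:
        raise SchemaError(f"schema {path} must declare an 'outcome' entry")
    return spec


def read_dataset(path, schema_path=None) -> DataMatrix:
    """Read a delimited dataset (and optional schema sidecar) into a DataMatrix."""
    df = _read_table(path)
    if schema_path is not None:
        spec = read_schema(schema_path)
        out = spec["outcome"]
        out_name, out_kind = out["name"], out.get("kind", "binary")
        if out_name not in df.columns:
            raise SchemaError(f"outcome column {out_name!r} not in the data")
        cov_specs = spec.get("covariates")
        schema = []
        if cov_specs:
            for c in cov_specs:
                if c["name"] not in df.columns:
                    raise SchemaError(f"declared column {c['name']!r} not in the data")
                schema.append(ColumnSchema(c["name"], c.get("kind", "continuous"),
                                           levels=tuple(c["levels"]) if "levels" in c else None))
            X = df[[c.name for c in schema]]
        else:
            X = df.drop(columns=[out_name])
            schema = infer_covariate_schema(X)
    else:
        out_name = "y" if "y" in df.columns else df.columns[-1]
        X = df.drop(columns=[out_name])
        out_kind = ("continuous"
                    if pd.api.types.is_float_dtype(df[out_name]) else "binary")
        schema = infer_covariate_schema(X)
        logger.info("no schema given: outcome %r (%s), covariate kinds inferred "
                    "from dtypes", out_name, out_kind)
    y = df[out_name]
    logger.info("read %s: %d rows, %d covariates", path, len(df), X.shape[1])
    dm = DataMatrix(X, y, list(schema), outcome_kind=out_kind)
    dm.encode()  # validate levels and numeric parses eagerly, with column names
    return dm


def write_dataset(dm: DataMatrix, path, schema_path=None, outcome_name="y"):
    """Write a DataMatrix as CSV/TSV plus a YAML schema sidecar."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = dm.X.copy()
    df[outcome_name] = dm.y.values
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    if schema_path is not None:
        spec = {"outcome": {"name": outcome_name, "kind": dm.outcome_kind},
                "covariates": [
                    {"name": s.name, "kind": s.kind,
                     **({"levels": [_plain(l) for l in s.levels]} if s.levels else {})}
                    for s in dm.schema]}
        with open(schema_path, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)


def _plain(v):
    try:
        return v.item()
    except AttributeError:
        return v


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, seed, params: dict, inputs=()):
    """Record everything needed to reproduce a run bit-identically."""
    from . import __version__

    manifest = {
        "package": "airforest",
        "version": __version__,
        "seed": seed,
        "params": {k: _plain(v) for k, v in params.items()},
        "inputs": {str(p): file_checksum(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
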