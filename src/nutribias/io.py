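"""Cohort CSV and result TSV input/output.

Cohorts are CSVs with units encoded in the column suffixes (_kcal, _mg, _g,
_kg, _cm, _mmhg, _bpm, _lmin); results are TSVs whose leading comment lines
record the package version, the seed and a hash of the configuration, so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .models import COHORT_COLUMNS, NUTRIENT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["read_cohort", "write_cohort", "write_results", "config_hash"]

#: columns a cohort file must provide (outcomes may be absent for screening-only use)
REQUIRED_COLUMNS = ("id", "ffm_kg") + tuple(c for pair in NUTRIENT_COLUMNS.values() for c in pair)


class SchemaError(ValueError):
    """Input table does not match the documented cohort schema."""


def read_cohort(path, require_outcomes: bool = False) -> pd.DataFrame:
    """Read a cohort CSV, validating the column schema.

    Extra columns are preserved. A protein column in milligram-scale
    magnitudes triggers a units warning (values are left untouched).
    """
    df = pd.read_csv(path)
    required = list(REQUIRED_COLUMNS)
    if require_outcomes:
        required += [c for c in COHORT_COLUMNS if c not in REQUIRED_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing required columns: {', '.join(missing)}")
    for col in ("pri_sr_g", "pri_bio_g"):
        if col in df.columns and df[col].dropna().gt(1000).any():
            logger.warning(
                "column %s has values > 1000; protein is expected in g/day - check units", col
            )
    return df


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def config_hash(config) -> str:
    """Stable short hash of any JSON-serialisable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_results(
    table: pd.DataFrame,
    path,
    seed=None,
    config: dict | None = None,
) -> Path:
    """Write a result table as TSV with a reproducibility header block."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [
        f"# nutribias {__version__}",
        f"# seed: {seed}",
        f"# config: {config_hash(config or {})}",
    ]
    body = table.to_csv(sep="\t", index=False)
    path.write_text("\n".join(header) + "\n" + body)
    return path


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
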