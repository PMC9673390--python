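"""Reading and writing feature tables and configuration files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import COVARIATES, ERG_FEATURES, TABLE_COLUMNS, GeneratorConfig

_GROUP_ALIASES = {
    "smi": "SMI", "1": "SMI", "case": "SMI",
    "control": "control", "0": "control", "healthy": "control",
}
_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "0": "female",
}

_NUMERIC_COLUMNS = (*ERG_FEATURES, "age", "pupil")


class FeatureTableError(ValueError):
    """Raised for malformed feature-table files, naming the offending cells."""


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject-level feature table from CSV.

    Columns are matched by name (any order); group and sex accept the usual
    aliases (1/0, case/control, m/f).  Any missing value is rejected with the
    row and column named — complete ERG data is an input contract.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FeatureTableError(f"missing required columns: {missing}")
    extra = [c for c in df.columns if c not in TABLE_COLUMNS]
    if extra:
        raise FeatureTableError(f"unexpected columns: {extra}")
    df = df[list(TABLE_COLUMNS)]

    for col in TABLE_COLUMNS:
        null = df[col].isna()
        if null.any():
            row = int(np.nonzero(null.to_numpy())[0][0])
            raise FeatureTableError(f"missing value at row {row}, column {col!r}")

    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise FeatureTableError(f"non-numeric value at row {row}, column {col!r}")
        df[col] = coerced.astype(float)

    for col, aliases in (("group", _GROUP_ALIASES), ("sex", _SEX_ALIASES)):
        values = df[col].astype(str).str.strip().str.lower()
        unknown = ~values.isin(aliases)
        if unknown.any():
            row = int(np.nonzero(unknown.to_numpy())[0][0])
            raise FeatureTableError(
                f"unknown {col} label {df[col].iloc[row]!r} at row {row}"
            )
        df[col] = values.map(aliases)
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table[list(TABLE_COLUMNS)].to_csv(path, index=False)


def read_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a generator configuration from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cfg = GeneratorConfig.from_dict(data)
    cfg.validate()
    return cfg


def write_generator_config(cfg: GeneratorConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    data["feature_names"] = list(data["feature_names"])
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
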