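"""Schema-validated readers and writers for the delimited input tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .errors import SchemaError

SCHEMAS = {
    "patients": {"required": ["patient_id", "birth_year", "sex", "deprivation_index"]},
    "dispensings": {
        "required": ["patient_id", "drug", "date", "quantity_mg"],
        "dates": ["date"],
        "nonneg": ["quantity_mg"],
    },
    "enrolment": {
        "required": ["patient_id", "start_date", "end_date"],
        "dates": ["start_date", "end_date"],
    },
    "deaths": {"required": ["patient_id", "death_date"], "dates": ["death_date"]},
    "population": {"required": ["month", "population"], "nonneg": ["population"]},
}


def _parse_dates(df: pd.DataFrame, name: str, cols) -> list[str]:
    errors = []
    for c in cols:
        parsed = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
        bad = df[c].notna() & parsed.isna()
        for i in df.index[bad]:
            # +2: header line plus 1-based numbering
            errors.append(f"{name}.csv line {i + 2}: unparseable date {df.loc[i, c]!r} in column {c}")
        df[c] = parsed
    return errors


def read_table(path: str | Path, name: str) -> tuple[pd.DataFrame, list[str]]:
    """Read one input table, validating schema; returns (table, row errors).

    A missing column is fatal (:class:`SchemaError`); row-level problems
    (unparseable dates, negative quantities) are returned as messages with
    line numbers.
    """
    schema = SCHEMAS[name]
    df = pd.read_csv(path)
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}.csv: missing column(s) {missing}")
    errors = _parse_dates(df, name, schema.get("dates", ()))
    for c in schema.get("nonneg", ()):
        bad = df[c].notna() & (df[c] <= 0)
        for i in df.index[bad]:
            errors.append(
                f"{name}.csv line {i + 2}: non-positive {c} = {df.loc[i, c]}"
            )
    return df, errors


def read_tables(config: PipelineConfig) -> tuple[dict, list[str]]:
    """Read and validate all input tables; returns ({name: table}, errors)."""
    paths = {
        "patients": config.patients_path,
        "dispensings": config.dispensings_path,
        "enrolment": config.enrolment_path,
        "deaths": config.deaths_path,
        "population": config.population_path,
    }
    tables, errors = {}, []
    for name, path in paths.items():
        if name == "population" and not Path(path).exists():
            tables[name] = None
            continue
        tables[name], errs = read_table(path, name)
        errors.extend(errs)
    return tables, errors
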