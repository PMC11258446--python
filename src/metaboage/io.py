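"""CSV/JSON readers and writers for pipeline artifacts.

All tabular artifacts are CSV with an explicit ``NA`` missing-value token
and ``sample_id`` as the key column; models and reports are JSON.  Writers
emit full float precision so read(write(x)) round-trips numbers exactly.
Readers are strict: schema violations are reported with row/column
coordinates and decimal-comma files are rejected rather than coerced.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ID_COLS

NA_TOKEN = "NA"
_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


class SchemaError(ValueError):
    pass


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep=NA_TOKEN)


def _check_numeric(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for c in cols:
        if df[c].dtype == object:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            for i, v in df.loc[bad, c].items():
                if isinstance(v, str) and _DECIMAL_COMMA.match(v.strip()):
                    raise SchemaError(
                        f"{path}: decimal-comma value {v!r} at row {i}, "
                        f"column {c!r}; file rejected"
                    )
                raise SchemaError(
                    f"{path}: non-numeric value {v!r} at row {i}, column {c!r}"
                )
            df[c] = coerced.astype(float)
    return df


def read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    missing = [c for c in ID_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    analytes = [c for c in df.columns if c not in ID_COLS]
    if not analytes:
        raise SchemaError(f"{path}: no analyte columns found")
    return _check_numeric(df, analytes, path)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    write_table(matrix, path)


def read_pheno(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    required = ["sample_id", "cohort", "age", "sex", "bmi", "ethnicity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    numeric = [c for c in df.columns
               if c not in ("sample_id", "subject_id", "cohort", "ethnicity")]
    return _check_numeric(df, numeric, path)


def write_pheno(pheno: pd.DataFrame, path: str | Path) -> None:
    write_table(pheno, path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(o):
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, np.ndarray):
        return [_jsonable(v) for v in o.tolist()]
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    return o


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
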