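"""File I/O for response matrices, parameter sets and score tables.

CSV (UTF-8, comma, header row) for tabular artifacts; JSON for item
parameters and reports.  Response files may be 0- or 1-based; the base is
declared in the reader call (or a ``# category_base:`` comment line) and
data are re-based to 0..K-1 internally.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import ItemParameters
from .synthetic import ResponseMatrix

__all__ = [
    "read_responses",
    "write_responses",
    "read_item_parameters",
    "write_item_parameters",
    "read_score_table",
    "write_score_table",
]

COVARIATE_COLUMNS = (
    "child_age",
    "child_sex",
    "child_ethnicity",
    "parent_age",
    "parent_sex",
    "parent_education",
)


def write_responses(resp: ResponseMatrix, path, category_base: int = 0) -> None:
    df = resp.to_frame()
    item_cols = resp.item_names
    df[item_cols] = df[item_cols] + category_base
    with open(path, "w") as fh:
        fh.write(f"# category_base: {category_base}\n")
        df.to_csv(fh, index=False)


def read_responses(
    path,
    item_columns: list[str] | None = None,
    category_base: int | None = None,
    n_categories: int | None = None,
    allow_missing: bool = False,
) -> ResponseMatrix:
    """Read a person x item CSV into a 0-based integer response matrix.

    Columns other than ``person_id`` and the item columns are kept as
    covariates.  Out-of-range categories raise with the offending cell;
    missing cells are only allowed when ``allow_missing`` (coded -1).
    """
    path = Path(path)
    declared_base = None
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "category_base" in first:
            declared_base = int(first.split(":")[1])
    df = pd.read_csv(path, skiprows=skip)
    if category_base is None:
        category_base = declared_base if declared_base is not None else 0
    if item_columns is None:
        item_columns = [
            c
            for c in df.columns
            if c != "person_id" and c not in COVARIATE_COLUMNS and pd.api.types.is_numeric_dtype(df[c])
        ]
    data = df[item_columns].to_numpy()
    if np.isnan(data.astype(float)).any():
        if not allow_missing:
            r, c = np.argwhere(np.isnan(data.astype(float)))[0]
            raise ValueError(f"missing cell at row {r}, column {item_columns[c]!r}")
        data = np.where(np.isnan(data.astype(float)), category_base - 1, data)
    data = data.astype(int) - category_base
    if (data < -1).any() or ((data < 0) & ~np.full(data.shape, allow_missing)).any():
        r, c = np.argwhere(data < 0)[0]
        raise ValueError(
            f"category below base at row {r}, column {item_columns[c]!r}"
        )
    if n_categories is not None:
        bad = data >= n_categories
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"category {data[r, c] + category_base} out of range at row {r}, "
                f"column {item_columns[c]!r}"
            )
    covs = [c for c in df.columns if c not in item_columns and c != "person_id"]
    return ResponseMatrix(
        data,
        list(item_columns),
        df[covs] if covs else None,
        df["person_id"].to_numpy() if "person_id" in df else None,
    )


def write_item_parameters(params: ItemParameters, path) -> None:
    params.to_json(path)


def read_item_parameters(path) -> ItemParameters:
    return ItemParameters.from_json(path)


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
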