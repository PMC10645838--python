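"""CSV/JSON/MSP readers and writers with schema validation.

All tables are comma-separated UTF-8 with a mandatory header row and ``.``
decimals; the first column is always ``sample``. Round-trip fidelity
(read(write(x)) == x) is part of the contract and covered by tests.
"""
from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .linkages import PCT_COLUMNS, RATIO_COLUMNS
from .pmaa import read_msp, write_msp  # noqa: F401  (re-exported)


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, expected: list[str], optional: set[str]):
    missing = [c for c in expected if c not in df.columns and c not in optional]
    unknown = [c for c in df.columns if c not in expected]
    problems = []
    if missing:
        problems.append(f"missing columns: {missing}")
    if unknown:
        problems.append(f"unknown columns: {unknown}")
    if problems:
        raise SchemaError("; ".join(problems))


def _check_numeric(df: pd.DataFrame, non_negative: bool = True) -> pd.DataFrame:
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[series.isna()][0]
            raise SchemaError(f"non-numeric cell at row {row!r}, column {col!r}")
        if non_negative and (series < 0).any():
            row = df.index[series < 0][0]
            raise SchemaError(f"negative value at row {row!r}, column {col!r}")
        df[col] = series
    return df


def read_census_csv(path, kind: str = "percent") -> pd.DataFrame:
    """Read a per-sample linkage table (molar percent or glucose ratios)."""
    df = pd.read_csv(path)
    if "sample" not in df.columns:
        raise SchemaError("first column must be 'sample'")
    df = df.set_index("sample")
    if kind == "percent":
        expected = list(PCT_COLUMNS.values())
        optional: set[str] = set()
    elif kind == "ratio":
        expected = list(RATIO_COLUMNS.values())
        optional = {"glcp_ratio"}
    else:
        raise ValueError(f"kind must be percent|ratio, got {kind!r}")
    _check_columns(df, expected, optional)
    return _check_numeric(df)


def write_census_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample")


def read_band_csv(path) -> pd.DataFrame:
    """HPTLC band table: ``sample`` column, ``rf_<value>`` columns and an
    optional ``label`` column."""
    df = pd.read_csv(path)
    if "sample" not in df.columns:
        raise SchemaError("first column must be 'sample'")
    df = df.set_index("sample")
    rf_cols = [c for c in df.columns if c.startswith("rf_")]
    extra = [c for c in df.columns if c not in rf_cols and c != "label"]
    if not rf_cols:
        raise SchemaError("no rf_<value> columns found")
    if extra:
        raise SchemaError(f"unknown columns: {extra}")
    for c in rf_cols:
        try:
            rf = float(c[3:])
        except ValueError as exc:
            raise SchemaError(f"cannot parse Rf from column {c!r}") from exc
        if not 0 < rf < 1:
            raise SchemaError(f"Rf in column {c!r} must lie in (0, 1)")
    df[rf_cols] = _check_numeric(df[rf_cols].copy())
    return df


def write_band_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample")


def band_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series | None]:
    """Split a band table into the intensity matrix and its labels."""
    labels = df["label"] if "label" in df.columns else None
    x = df.drop(columns=["label"], errors="ignore")
    return x, labels


def rf_values(x: pd.DataFrame) -> np.ndarray:
    return np.array([float(c[3:]) for c in x.columns])


def write_report(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_reference_ratios() -> pd.DataFrame:
    """The packaged six-sample glucose-normalised ratio table of the bulb
    extracts (one-decimal values, as reported)."""
    with resources.files("fructans.data").joinpath("amica_linkage_ratios.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return read_census_csv(fh, kind="ratio")
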