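"""CSV schemas and validated readers for the pipeline's file formats.

All files are UTF-8, comma-separated, "." decimal, ISO-8601 dates; the
single token ``NA`` denotes a qPCR reaction that never crossed threshold
(and, generally, a missing value).  Validation errors name the file,
column and, where possible, the offending rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_plates_csv",
    "read_samples_csv",
    "read_peaks_csv",
    "read_survey_csv",
]

PLATE_COLUMNS = ["plate_id", "well", "sample_id", "role", "known_copies", "cq"]
SAMPLE_COLUMNS = ["sample_id", "volume_ml"]
PEAK_COLUMNS = ["sample_id", "position", "called_base",
                "height_A", "height_C", "height_G", "height_T"]
SURVEY_COLUMNS = ["site_id", "river", "shore", "date", "edna_detected",
                  "edna_copies", "species_call", "ichthyo_count",
                  "adult_present"]

ROLES = {"standard", "unknown", "ntc", "cooler_blank", "spike_control"}


class SchemaError(ValueError):
    """An input file does not conform to its documented schema."""


def _read(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if not len(df):
        raise SchemaError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    try:
        return pd.to_numeric(df[col])
    except (ValueError, TypeError):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                       & df[col].notna()].tolist()[:5]
        raise SchemaError(f"{path}: column {col!r} not numeric (rows {bad})")


def read_plates_csv(path) -> pd.DataFrame:
    df = _read(path, PLATE_COLUMNS)
    bad = df.index[~df["role"].isin(ROLES)].tolist()
    if bad:
        raise SchemaError(f"{path}: unknown role values in rows {bad[:5]}")
    df["cq"] = _numeric(df, "cq", path)
    df["known_copies"] = _numeric(df, "known_copies", path)
    std = df["role"] == "standard"
    if (std & df["known_copies"].isna()).any():
        rows = df.index[std & df["known_copies"].isna()].tolist()[:5]
        raise SchemaError(f"{path}: standard wells missing known_copies "
                          f"(rows {rows})")
    return df


def read_samples_csv(path) -> pd.DataFrame:
    df = _read(path, SAMPLE_COLUMNS)
    df["volume_ml"] = _numeric(df, "volume_ml", path)
    if (df["volume_ml"] <= 0).any():
        rows = df.index[df["volume_ml"] <= 0].tolist()[:5]
        raise SchemaError(f"{path}: nonpositive volume_ml (rows {rows})")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:5]
        raise SchemaError(f"{path}: duplicated sample ids {dups}")
    if "date" in df.columns:
        try:
            pd.to_datetime(df["date"], format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: dates must be ISO-8601: {exc}")
    return df


def read_peaks_csv(path) -> pd.DataFrame:
    df = _read(path, PEAK_COLUMNS)
    for col in ("position", "height_A", "height_C", "height_G", "height_T"):
        df[col] = _numeric(df, col, path)
    heights = df[[f"height_{b}" for b in "ACGT"]]
    if (heights < 0).any().any():
        raise SchemaError(f"{path}: negative peak heights")
    for sid, grp in df.groupby("sample_id"):
        pos = grp["position"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise SchemaError(f"{path}: positions not strictly increasing "
                              f"for sample {sid!r}")
    return df


def read_survey_csv(path) -> pd.DataFrame:
    df = _read(path, SURVEY_COLUMNS)
    try:
        pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: dates must be ISO-8601: {exc}")
    for col in ("edna_detected", "adult_present"):
        vals = df[col]
        if vals.dtype == object:
            mapped = vals.astype(str).str.lower().map(
                {"true": True, "false": False, "1": True, "0": False})
            if mapped.isna().any():
                raise SchemaError(f"{path}: column {col!r} must be boolean")
            df[col] = mapped
        else:
            df[col] = vals.astype(bool)
    df["edna_copies"] = _numeric(df, "edna_copies", path)
    df["ichthyo_count"] = _numeric(df, "ichthyo_count", path)
    if (df["ichthyo_count"].fillna(0) < 0).any():
        raise SchemaError(f"{path}: negative ichthyoplankton counts")
    bad = df["edna_copies"].notna() & ~df["edna_detected"]
    if bad.any():
        raise SchemaError(f"{path}: edna_copies present without detection "
                          f"(rows {df.index[bad].tolist()[:5]})")
    return df
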