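"""Sample-table readers/writers with validation.

CSV dialect: comma-separated, UTF-8, '.' decimal.  Coordinates are decimal
degrees WGS84.  Rows with missing coordinates or isotope values are flagged
in a ``flag`` column, never silently dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "tissue", "sex", "year", "lon", "lat")
ISOTOPE_COLUMNS = ("sr87_86", "d18O_carb_vsmow", "d13C_vpdb")
NUMERIC_COLUMNS = ("year", "lon", "lat") + ISOTOPE_COLUMNS

__all__ = ["read_sample_table", "write_sample_table", "REQUIRED_COLUMNS"]


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate a tissue sample table.

    Required columns: sample_id, tissue, sex, year, lon, lat; isotope columns
    are taken when present.  Blank sex parses as "U" (unknown).  Non-numeric
    entries in numeric columns are rejected with their row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: no rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame()
    out["sample_id"] = df["sample_id"].str.strip()
    out["tissue"] = df["tissue"].str.strip().str.lower()
    bad_tissue = ~out["tissue"].isin(["bone", "antler"])
    if bad_tissue.any():
        raise ValueError(
            f"{path}: unknown tissue type(s) in rows {np.nonzero(bad_tissue.to_numpy())[0].tolist()}"
        )
    sex = df["sex"].str.strip().str.upper().replace("", "U")
    out["sex"] = sex.where(sex.isin(["M", "F", "U"]), "U")
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col].str.strip().replace("", "nan")
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & (raw != "nan")
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col}, row {row}")
        out[col] = parsed
    flags = []
    for _, r in out.iterrows():
        missing_bits = [
            c for c in ("lon", "lat") + ISOTOPE_COLUMNS
            if c in out.columns and not np.isfinite(r.get(c, np.nan))
        ]
        flags.append(";".join(f"missing_{c}" for c in missing_bits))
    out["flag"] = flags
    return out


def write_sample_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
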