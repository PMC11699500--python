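"""CSV readers/writers for the pipeline's table dialects.

Schemas (all plain CSV with a header row):

* ibi.csv          participant_id, t_ms, ibi_ms
* actigraphy.csv   participant_id, epoch_start_ms, count
* wrist.csv        participant_id, t_ms, on_wrist (0/1)
* ecg.csv          participant_id, ecg_start_ms, ecg_end_ms, ecg_rhr_bpm, quality
* steps.csv        participant_id, date, steps, wear_minutes
* participants.csv participant_id, sex, age
* covariates.csv   participant_id, covariate, domain, type, value (long)
* rhr.csv          participant_id, verdict, n_retained, device_rhr_bpm,
                   ecg_rhr_bpm, sex, age
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .covariates import CovariateTable
from .exceptions import DataError

_SCHEMAS = {
    "ibi": ["participant_id", "t_ms", "ibi_ms"],
    "actigraphy": ["participant_id", "epoch_start_ms", "count"],
    "wrist": ["participant_id", "t_ms", "on_wrist"],
    "ecg": ["participant_id", "ecg_start_ms", "ecg_end_ms", "ecg_rhr_bpm", "quality"],
    "steps": ["participant_id", "date", "steps", "wear_minutes"],
    "participants": ["participant_id", "sex", "age"],
}
_NUMERIC = {
    "ibi": ["t_ms", "ibi_ms"],
    "actigraphy": ["epoch_start_ms", "count"],
    "wrist": ["t_ms", "on_wrist"],
    "ecg": ["ecg_start_ms", "ecg_end_ms", "ecg_rhr_bpm"],
    "steps": ["steps", "wear_minutes"],
    "participants": ["age"],
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing input file: {path}")
    df = pd.read_csv(path)
    missing = set(_SCHEMAS[kind]) - set(df.columns)
    if missing:
        raise DataError(f"{path.name}: missing columns {sorted(missing)}")
    for col in _NUMERIC[kind]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            raise DataError(f"{path.name}: corrupt value in column {col!r} at row {int(bad.idxmax()) + 2}")
        if values.isna().any():
            raise DataError(f"{path.name}: empty value in column {col!r} at row {int(values.isna().idxmax()) + 2}")
        df[col] = values
    return df


def read_input_dir(in_dir: str | Path) -> dict:
    """Read the full sensor-table bundle from a directory."""
    in_dir = Path(in_dir)
    out = {kind: read_table(in_dir / f"{kind}.csv", kind) for kind in _SCHEMAS}
    cov_path = in_dir / "covariates.csv"
    out["covariates"] = (
        CovariateTable.from_long(pd.read_csv(cov_path)) if cov_path.exists() else None
    )
    return out


def read_rhr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant_id", "verdict", "device_rhr_bpm", "ecg_rhr_bpm"} - set(df.columns)
    if missing:
        raise DataError(f"{Path(path).name}: missing columns {sorted(missing)}")
    return df
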