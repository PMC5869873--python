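"""CSV dialects and strict readers for the pipeline's input tables.

ecg.csv: replicate-level Holter extractions with columns
(subject_id, day, time_h, replicate, qt_ms, rr_s, hr_bpm, pr_ms, qrs_ms).
pk.csv: plasma concentrations with columns
(subject_id, day, time_h, analyte, conc_nM), analyte in {parent, M1, M2}.
truth.csv (optional): generator sidecar (subject_id, parameter, value).

Units are enforced: QT/PR/QRS in milliseconds, RR in seconds, concentration
in nM.  Row-level problems are collected and reported together in a single
validation error rather than one at a time.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .pk_nca import ANALYTES

ECG_COLUMNS = ["subject_id", "day", "time_h", "replicate",
               "qt_ms", "rr_s", "hr_bpm", "pr_ms", "qrs_ms"]
PK_COLUMNS = ["subject_id", "day", "time_h", "analyte", "conc_nM"]

#: an RR interval above this is assumed to be in the wrong unit (ms, not s)
_RR_UNIT_GUARD_S = 10.0


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_ecg_csv(path) -> pd.DataFrame:
    """Read and validate a replicate-level ECG table."""
    df = pd.read_csv(path)
    _require_columns(df, ECG_COLUMNS, path)
    errors = []
    bad_qt = df.index[df["qt_ms"] <= 0]
    if len(bad_qt):
        errors.append(f"non-positive qt_ms at rows {list(bad_qt[:10])}")
    bad_rr = df.index[df["rr_s"] <= 0]
    if len(bad_rr):
        errors.append(f"non-positive rr_s at rows {list(bad_rr[:10])}")
    unit_rr = df.index[df["rr_s"] > _RR_UNIT_GUARD_S]
    if len(unit_rr):
        errors.append(
            f"rr_s above {_RR_UNIT_GUARD_S} s at rows {list(unit_rr[:10])}: "
            "RR looks like milliseconds; expected seconds"
        )
    key = ["subject_id", "day", "time_h", "replicate"]
    dupes = df[df.duplicated(key, keep=False)]
    if len(dupes):
        keys = dupes[key].drop_duplicates().to_dict("records")
        errors.append(f"duplicate replicate keys: {keys[:10]}")
    if errors:
        raise ValidationError(f"{path}:\n" + "\n".join(errors))
    return df


def read_pk_csv(path) -> pd.DataFrame:
    """Read and validate a long-format plasma-concentration table."""
    df = pd.read_csv(path)
    _require_columns(df, PK_COLUMNS, path)
    errors = []
    unknown = sorted(set(df["analyte"].unique()) - set(ANALYTES))
    if unknown:
        errors.append(f"unknown analytes {unknown}; expected {list(ANALYTES)}")
    bad_conc = df.index[df["conc_nM"] < 0]
    if len(bad_conc):
        errors.append(f"negative conc_nM at rows {list(bad_conc[:10])}")
    bad_t = df.index[df["time_h"] < 0]
    if len(bad_t):
        errors.append(f"negative time_h at rows {list(bad_t[:10])}")
    key = ["subject_id", "day", "time_h", "analyte"]
    dupes = df[df.duplicated(key, keep=False)]
    if len(dupes):
        keys = dupes[key].drop_duplicates().to_dict("records")
        errors.append(f"duplicate sample keys: {keys[:10]}")
    if errors:
        raise ValidationError(f"{path}:\n" + "\n".join(errors))
    return df


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "parameter", "value"], path)
    return df


def truth_covariates(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-subject covariate frame (sex, bmi, ecog) from a truth sidecar."""
    wide = truth.pivot_table(index="subject_id", columns="parameter", values="value")
    cols = [c for c in ("sex", "bmi", "ecog") if c in wide]
    return wide[cols].reset_index()


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path
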