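"""Replicate averaging, heart-rate correction of QT, and time-matched baseline changes.

The QT interval of the surface ECG shortens as heart rate rises, so raw QT
cannot be compared across time points with different RR intervals.  Two
corrections are supported as primary methods:

* Fridericia: ``QTcF = QT / RR**(1/3)`` (RR in seconds),
* individual: ``QTcI = QT / RR**b`` with the exponent ``b`` estimated per
  subject from drug-free data (baseline day plus the first-day predose
  extraction) by ordinary least squares of log(QT) on log(RR).

Bazett's correction (``QT / RR**(1/2)``) is available as an optional third
method but is never used as a primary endpoint.

Conventions: RR is carried in seconds, QT/QTc in milliseconds, heart rate in
beats per minute (derived as 60/RR when absent).  The correction exponent is
estimated from replicate-level (QT, RR) pairs, while corrected values used in
downstream change-from-baseline analyses are computed on the replicate-averaged
point (average first, then correct).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SingularFitError, ValidationError

log = logging.getLogger(__name__)

#: long-format value columns carried through averaging
_ECG_VALUE_COLS = ["qt_ms", "rr_s", "hr_bpm", "pr_ms", "qrs_ms"]

BASELINE_DAY = -1


@dataclass(frozen=True)
class EcgPoint:
    """One replicate-averaged ECG observation at a subject/day/nominal time."""

    subject_id: str
    day: int
    time_h: float
    qt_ms: float
    rr_s: float
    hr_bpm: float
    pr_ms: float
    qrs_ms: float
    n_replicates: int


@dataclass(frozen=True)
class SubjectCorrection:
    """Per-subject QT/RR power-law exponent estimated from drug-free pairs."""

    subject_id: str
    exponent_b: float
    n_pairs: int
    r_squared: float


def average_replicates(replicates: pd.DataFrame) -> EcgPoint:
    """Average same-time replicate extractions into a single ECG point.

    Each field is the arithmetic mean of the available non-missing replicate
    values.  All rows must share one (subject, day, nominal time) key.
    """
    if len(replicates) == 0:
        raise InsufficientDataError("no replicates supplied")
    keys = replicates[["subject_id", "day", "time_h"]].drop_duplicates()
    if len(keys) > 1:
        raise ValidationError(
            f"replicates span multiple subject/day/time keys: {keys.to_dict('records')}"
        )
    row = keys.iloc[0]
    means = {c: float(replicates[c].mean()) for c in _ECG_VALUE_COLS}
    return EcgPoint(
        subject_id=row["subject_id"],
        day=int(row["day"]),
        time_h=float(row["time_h"]),
        n_replicates=int(replicates["qt_ms"].notna().sum()),
        **means,
    )


def average_replicates_frame(ecg: pd.DataFrame) -> pd.DataFrame:
    """Vectorised replicate averaging over a full replicate-level table.

    Returns one row per (subject_id, day, time_h) with the mean of each ECG
    field and the count of non-missing QT replicates.
    """
    grouped = ecg.groupby(["subject_id", "day", "time_h"], sort=True)
    out = grouped[_ECG_VALUE_COLS].mean()
    out["n_replicates"] = grouped["qt_ms"].count()
    return out.reset_index()


def fridericia(qt_ms, rr_s):
    """Fridericia-corrected QT: QT / RR**(1/3), RR in seconds."""
    return individual_correction(qt_ms, rr_s, 1.0 / 3.0)


def bazett(qt_ms, rr_s):
    """Bazett-corrected QT: QT / RR**(1/2), RR in seconds (optional method)."""
    return individual_correction(qt_ms, rr_s, 0.5)


def individual_correction(qt_ms, rr_s, b: float):
    """Individually corrected QT: QT / RR**b, RR in seconds."""
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_s, dtype=float)
    if np.any(rr <= 0):
        raise ValidationError("RR must be strictly positive (seconds)")
    out = qt / rr**b
    if out.ndim == 0:
        return float(out)
    return out


def estimate_individual_exponent(
    qt_ms, rr_s, subject_id: str = ""
) -> SubjectCorrection:
    """OLS slope of log(QT) on log(RR) over drug-free replicate-level pairs.

    The slope is the exponent ``b`` of the subject's QT = a * RR**b
    relationship; r_squared is the usual coefficient of determination of the
    log-log regression.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_s, dtype=float)
    mask = np.isfinite(qt) & np.isfinite(rr)
    qt, rr = qt[mask], rr[mask]
    if len(qt) < 2:
        raise InsufficientDataError(
            f"subject {subject_id!r}: need >=2 (QT, RR) pairs, got {len(qt)}"
        )
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise ValidationError("QT and RR must be strictly positive")
    if np.allclose(rr, rr[0]):
        raise SingularFitError(
            f"subject {subject_id!r}: all RR values identical; exponent not identifiable"
        )
    res = stats.linregress(np.log(rr), np.log(qt))
    return SubjectCorrection(
        subject_id=subject_id,
        exponent_b=float(res.slope),
        n_pairs=int(len(qt)),
        r_squared=float(res.rvalue**2),
    )


def baseline_pairs(ecg: pd.DataFrame, subject_id) -> pd.DataFrame:
    """Drug-free replicate-level rows for exponent estimation.

    All baseline-day rows plus the first drug day's predose (time 0)
    extraction for the given subject.
    """
    sub = ecg[ecg["subject_id"] == subject_id]
    drug_free = (sub["day"] == BASELINE_DAY) | (
        (sub["day"] == 1) & (sub["time_h"] == 0.0)
    )
    return sub[drug_free]


def estimate_exponents(ecg: pd.DataFrame) -> pd.DataFrame:
    """Per-subject individual-correction exponents from a replicate-level table.

    Returns a frame (subject_id, exponent_b, n_pairs, r_squared).
    """
    rows = []
    for sid in sorted(ecg["subject_id"].unique()):
        pairs = baseline_pairs(ecg, sid)
        corr = estimate_individual_exponent(
            pairs["qt_ms"].to_numpy(), pairs["rr_s"].to_numpy(), subject_id=sid
        )
        rows.append(
            {
                "subject_id": sid,
                "exponent_b": corr.exponent_b,
                "n_pairs": corr.n_pairs,
                "r_squared": corr.r_squared,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "exponent_b", "n_pairs", "r_squared"])


def apply_corrections(
    points: pd.DataFrame,
    exponents: pd.DataFrame | None = None,
    include_bazett: bool = False,
) -> pd.DataFrame:
    """Attach corrected-QT columns to a replicate-averaged point table.

    Adds ``qtcf_ms`` always, ``qtci_ms`` when per-subject exponents are given,
    and ``qtcb_ms`` (Bazett) optionally.  Missing heart rate is filled with
    60/RR.
    """
    out = points.copy()
    out["qtcf_ms"] = fridericia(out["qt_ms"].to_numpy(), out["rr_s"].to_numpy())
    if include_bazett:
        out["qtcb_ms"] = bazett(out["qt_ms"].to_numpy(), out["rr_s"].to_numpy())
    if exponents is not None:
        merged = out.merge(exponents[["subject_id", "exponent_b"]], on="subject_id", how="left")
        if merged["exponent_b"].isna().any():
            missing = merged.loc[merged["exponent_b"].isna(), "subject_id"].unique()
            raise ValidationError(f"no exponent for subjects: {list(missing)}")
        out["qtci_ms"] = merged["qt_ms"].to_numpy() / merged["rr_s"].to_numpy() ** merged[
            "exponent_b"
        ].to_numpy()
    if "hr_bpm" not in out or out["hr_bpm"].isna().any():
        hr = 60.0 / out["rr_s"]
        out["hr_bpm"] = out.get("hr_bpm", hr).fillna(hr)
    return out


_METRIC_COLUMN = {
    "QTcI": "qtci_ms",
    "QTcF": "qtcf_ms",
    "QTcB": "qtcb_ms",
    "HR": "hr_bpm",
    "PR": "pr_ms",
    "QRS": "qrs_ms",
}


def to_long_metrics(points: pd.DataFrame, metrics=("QTcI", "QTcF", "HR", "PR", "QRS")) -> pd.DataFrame:
    """Tidy long view (subject_id, day, time_h, metric, value) of corrected points."""
    frames = []
    for m in metrics:
        col = _METRIC_COLUMN[m]
        if col not in points:
            continue
        frames.append(
            points[["subject_id", "day", "time_h", col]]
            .rename(columns={col: "value"})
            .assign(metric=m)
        )
    return pd.concat(frames, ignore_index=True)[
        ["subject_id", "day", "time_h", "metric", "value"]
    ]


def time_matched_delta(
    values: pd.DataFrame,
    baseline_day: int = BASELINE_DAY,
    drug_days: tuple = (1, 10),
) -> pd.DataFrame:
    """Change from the time-matched baseline-day value, per metric.

    ``values`` is a long frame (subject_id, day, time_h, metric, value) of
    replicate-averaged, corrected observations.  For every (subject, drug day,
    time, metric) present on both the drug day and the baseline day, the
    output row carries ``delta = value(drug day) - value(baseline day)``.
    Times without a baseline counterpart are dropped (and logged), which is
    the contract, not an error.
    """
    base = values[values["day"] == baseline_day][
        ["subject_id", "time_h", "metric", "value"]
    ].rename(columns={"value": "baseline"})
    drug = values[values["day"].isin(list(drug_days))]
    merged = drug.merge(base, on=["subject_id", "time_h", "metric"], how="left")
    dropped = merged["baseline"].isna()
    if dropped.any():
        log.info(
            "time_matched_delta: dropped %d drug-day records without a baseline counterpart",
            int(dropped.sum()),
        )
    merged = merged[~dropped].copy()
    merged["delta"] = merged["value"] - merged["baseline"]
    return merged[["subject_id", "day", "time_h", "metric", "value", "baseline", "delta"]]
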