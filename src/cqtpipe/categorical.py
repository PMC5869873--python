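"""Threshold-based categorical (outlier) analyses of ECG parameters.

Flags per observation, all with strict inequalities:

* absolute corrected QT above 450, 480 and 500 ms (per correction method);
* change from time-matched baseline in QTc above 30 and 60 ms;
* PR interval above 200 ms AND more than 25% above baseline (compound rule);
* QRS duration above 110 ms AND more than 25% above baseline.

The 25% relative rules compare against the time-matched baseline-day value;
when a time-matched value is absent the subject's baseline-day mean is used
instead (and the substitution is logged).  Incidence tables count each
subject at most once per category and day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoricalThresholds:
    qtc_abs_ms: tuple = (450.0, 480.0, 500.0)
    dqtc_ms: tuple = (30.0, 60.0)
    pr_abs_ms: float = 200.0
    qrs_abs_ms: float = 110.0
    rel_increase_pct: float = 25.0


def _baseline_lookup(values: pd.DataFrame, metric: str) -> tuple[pd.DataFrame, pd.Series]:
    """Time-matched baseline values and per-subject baseline means for one metric."""
    base = values[(values["day"] == -1) & (values["metric"] == metric)]
    matched = base[["subject_id", "time_h", "value"]].rename(columns={"value": "baseline"})
    per_subject = base.groupby("subject_id")["value"].mean()
    return matched, per_subject


def flag_observations(
    values: pd.DataFrame,
    deltas: pd.DataFrame,
    thresholds: CategoricalThresholds = CategoricalThresholds(),
    qtc_metrics: tuple = ("QTcI", "QTcF"),
) -> pd.DataFrame:
    """Per-observation boolean flags for every categorical rule.

    ``values`` is the long corrected-observation frame (subject_id, day,
    time_h, metric, value) across all days; ``deltas`` the change-from-
    baseline frame for the drug days.  Returns one row per (subject, day,
    time, metric) with the applicable flags; relative flags are missing
    (NA) when no baseline at all is available for the subject.
    """
    rows = []
    for metric in qtc_metrics:
        v = values[values["metric"] == metric]
        for _, r in v.iterrows():
            row = {"subject_id": r["subject_id"], "day": int(r["day"]),
                   "time_h": float(r["time_h"]), "metric": metric}
            for thr in thresholds.qtc_abs_ms:
                row[f"qtc_gt_{int(thr)}"] = bool(r["value"] > thr)
            rows.append(row)
        d = deltas[deltas["metric"] == metric]
        for _, r in d.iterrows():
            rows.append({
                "subject_id": r["subject_id"], "day": int(r["day"]),
                "time_h": float(r["time_h"]), "metric": metric,
                **{f"dqtc_gt_{int(thr)}": bool(r["delta"] > thr) for thr in thresholds.dqtc_ms},
            })
    for metric, abs_thr, flag in (
        ("PR", thresholds.pr_abs_ms, "pr_flag"),
        ("QRS", thresholds.qrs_abs_ms, "qrs_flag"),
    ):
        v = values[(values["metric"] == metric) & (values["day"] != -1)]
        matched, per_subject = _baseline_lookup(values, metric)
        merged = v.merge(matched, on=["subject_id", "time_h"], how="left")
        fallback = merged["baseline"].isna() & merged["subject_id"].isin(per_subject.index)
        if fallback.any():
            log.info("%s relative rule: %d records use the subject baseline-day mean",
                     metric, int(fallback.sum()))
            merged.loc[fallback, "baseline"] = merged.loc[fallback, "subject_id"].map(per_subject)
        for _, r in merged.iterrows():
            row = {"subject_id": r["subject_id"], "day": int(r["day"]),
                   "time_h": float(r["time_h"]), "metric": metric}
            if np.isfinite(r["baseline"]):
                rel = 100.0 * (r["value"] - r["baseline"]) / r["baseline"]
                row[flag] = bool(r["value"] > abs_thr and rel > thresholds.rel_increase_pct)
            else:
                row[flag] = pd.NA
            rows.append(row)
    out = pd.DataFrame(rows)
    flag_cols = [c for c in out.columns if c not in ("subject_id", "day", "time_h", "metric")]
    # idempotent de-duplication by observation key
    out = out.groupby(["subject_id", "day", "time_h", "metric"], as_index=False)[flag_cols].max()
    return out


def tabulate(flags: pd.DataFrame) -> pd.DataFrame:
    """Incidence table: n and % of subjects with >=1 flagged value, per day.

    The denominator is the number of subjects with at least one observation
    of the flag's metric on that day.
    """
    flag_cols = [c for c in flags.columns if c.startswith(("qtc_gt", "dqtc_gt", "pr_", "qrs_"))]
    rows = []
    for (metric, day), g in flags.groupby(["metric", "day"], sort=True):
        for col in flag_cols:
            if col not in g or g[col].isna().all():
                continue
            observed = g.dropna(subset=[col])
            denom = observed["subject_id"].nunique()
            if denom == 0:
                continue
            hit = observed[observed[col].astype(bool)]["subject_id"].nunique()
            rows.append({
                "metric": metric, "day": int(day), "category": col,
                "n_flagged": hit, "n_subjects": denom,
                "pct": 100.0 * hit / denom,
            })
    return pd.DataFrame(rows)
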