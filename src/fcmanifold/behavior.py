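"""Behavioral preprocessing and performance measures for the reaching task.

Trial tables hold center-out reaches under a 45 degree clockwise cursor
rotation.  Preprocessing removes flagged trials (early start, timeout,
cursor jump), reaction times under a floor, and extreme movement /
reaction times above a pooled across-subject quantile.  Errors are
signed angular differences (counterclockwise positive) wrapped to
(-180, 180]; epoch summaries use the median of absolute error.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "subject_id", "scan_label", "trial_index", "target_angle",
    "endpoint_angle", "reaction_time", "movement_time",
    "early_start", "timeout", "cursor_jump", "report_angle",
]

#: behavioral scans and the trial windows defining the six task epochs
EPOCH_TRIALS = 32


def angular_error(target_angle, endpoint_angle):
    """Signed shortest angular difference endpoint - target, in (-180, 180].

    Positive values are counterclockwise of the target.  Accepts scalars
    or arrays.
    """
    t = np.asarray(target_angle, dtype=float)
    e = np.asarray(endpoint_angle, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(e))):
        raise ValueError("angles must be finite")
    d = np.mod(e - t + 180.0, 360.0) - 180.0
    d = np.where(d == -180.0, 180.0, d)
    return float(d) if d.ndim == 0 else d


def filter_trials(
    trials: pd.DataFrame,
    rt_floor: float = 100.0,
    extreme_quantile: float = 0.0005,
):
    """Apply the trial exclusion cascade; returns (kept, exclusion report).

    Order (no double counting): early_start flag, timeout flag,
    cursor_jump flag, reaction time below ``rt_floor`` ms, then reaction
    and movement times above the ``1 - extreme_quantile`` quantile
    computed on the surviving trials pooled across all subjects.
    ``extreme_quantile = 0`` disables the quantile trim.
    """
    report = {
        "total": len(trials), "early_start": 0, "timeout": 0, "cursor_jump": 0,
        "rt_floor": 0, "rt_extreme": 0, "mt_extreme": 0, "retained": 0,
    }
    if len(trials) == 0:
        return trials.copy(), report

    df = trials.copy()
    excluded = pd.Series(False, index=df.index)
    for flag in ("early_start", "timeout", "cursor_jump"):
        hit = df[flag].astype(bool) & ~excluded
        report[flag] = int(hit.sum())
        excluded |= hit

    hit = (df["reaction_time"] < rt_floor) & ~excluded
    report["rt_floor"] = int(hit.sum())
    excluded |= hit

    if extreme_quantile > 0:
        surviving = df[~excluded]
        rt_cut = np.quantile(surviving["reaction_time"], 1.0 - extreme_quantile)
        mt_cut = np.quantile(surviving["movement_time"], 1.0 - extreme_quantile)
        hit = (df["reaction_time"] > rt_cut) & ~excluded
        report["rt_extreme"] = int(hit.sum())
        excluded |= hit
        hit = (df["movement_time"] > mt_cut) & ~excluded
        report["mt_extreme"] = int(hit.sum())
        excluded |= hit

    kept = df[~excluded].copy()
    report["retained"] = len(kept)
    return kept, report


def _epoch_window(scan_df: pd.DataFrame, which: str) -> pd.DataFrame:
    """Surviving trials inside an epoch's trial-index window.

    Windows are defined on the original trial indices (first
    ``EPOCH_TRIALS`` or last ``EPOCH_TRIALS`` of the scan), matching the
    scanning periods the imaging epochs cover; filtered-out trials
    simply leave gaps.
    """
    if len(scan_df) == 0:
        return scan_df
    if which == "first":
        return scan_df[scan_df["trial_index"] <= EPOCH_TRIALS]
    last_start = scan_df["trial_index"].max() - EPOCH_TRIALS
    return scan_df[scan_df["trial_index"] > last_start]


_EPOCH_WINDOWS = {
    "LH_Baseline": ("LH_Baseline", "first"),
    "RH_Baseline": ("RH_Baseline", "first"),
    "RH_Learn_Early": ("RH_Learning", "first"),
    "RH_Learn_Late": ("RH_Learning", "last"),
    "LH_Transfer_Early": ("LH_Transfer", "first"),
    "LH_Transfer_Late": ("LH_Transfer", "last"),
}


def epoch_error_summary(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-subject median absolute angular error per task epoch.

    Epoch windows are the first/last 32 trials of the relevant scan.
    An epoch with no surviving trials is NaN (missing), never zero.
    Includes ``transfer_rate = early_transfer_error -
    late_learning_error`` (exactly).
    """
    rows = []
    for subject, sdf in filtered.groupby("subject_id"):
        rec = {"subject_id": subject}
        err = angular_error(
            sdf["target_angle"].to_numpy(), sdf["endpoint_angle"].to_numpy()
        )
        sdf = sdf.assign(_abs_err=np.abs(err))
        for epoch, (scan, which) in _EPOCH_WINDOWS.items():
            window = _epoch_window(sdf[sdf["scan_label"] == scan], which)
            rec[epoch] = float(window["_abs_err"].median()) if len(window) else np.nan
        rec["early_learning_error"] = rec["RH_Learn_Early"]
        rec["late_learning_error"] = rec["RH_Learn_Late"]
        rec["early_transfer_error"] = rec["LH_Transfer_Early"]
        rec["late_transfer_error"] = rec["LH_Transfer_Late"]
        rec["transfer_rate"] = rec["early_transfer_error"] - rec["late_learning_error"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("subject_id")


def learning_curve(filtered: pd.DataFrame, scan_label: str, bin_size: int = 8
                   ) -> pd.DataFrame:
    """Per-subject median absolute error in consecutive trial bins."""
    rows = []
    for subject, sdf in filtered.groupby("subject_id"):
        sdf = sdf[sdf["scan_label"] == scan_label]
        err = np.abs(angular_error(
            sdf["target_angle"].to_numpy(), sdf["endpoint_angle"].to_numpy()
        ))
        bins = (sdf["trial_index"].to_numpy() - 1) // bin_size
        for b in np.unique(bins):
            rows.append({
                "subject_id": subject, "bin": int(b),
                "median_abs_error": float(np.median(err[bins == b])),
                "n_trials": int(np.sum(bins == b)),
            })
    return pd.DataFrame(rows)


def report_strategy(report_trials: pd.DataFrame, keep_last: int = 8) -> float:
    """Mean reported aim direction relative to the target, in degrees.

    Uses the final ``keep_last`` report trials (the first reports are
    typically unreliable while subjects learn the reporting interface).
    With fewer trials than ``keep_last``, all are used with a warning.
    """
    df = report_trials.dropna(subset=["report_angle"]).sort_values("trial_index")
    if len(df) == 0:
        raise ValueError("no report trials with a report angle")
    if len(df) < keep_last:
        warnings.warn(
            f"only {len(df)} report trials available; using all of them"
        )
    else:
        df = df.tail(keep_last)
    rel = angular_error(df["target_angle"].to_numpy(), df["report_angle"].to_numpy())
    return float(np.mean(rel))


def behavior_summary(
    filtered: pd.DataFrame, keep_last_reports: int = 8
) -> pd.DataFrame:
    """Epoch error summary plus the per-subject explicit-strategy report."""
    summary = epoch_error_summary(filtered[filtered["scan_label"] != "Report"])
    strategies = {}
    for subject, sdf in filtered.groupby("subject_id"):
        reports = sdf[sdf["scan_label"] == "Report"]
        strategies[subject] = (
            report_strategy(reports, keep_last=keep_last_reports)
            if reports["report_angle"].notna().any() else np.nan
        )
    summary["report_strategy"] = pd.Series(strategies)
    return summary
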