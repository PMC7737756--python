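"""Longitudinal progression monitoring from plasma feature trajectories.

Each genomic feature series (ERBB2 copy-number fold, TCL, TMB) is
normalized to its cutoff (1.4, 2, 8.5) so a relative fold > 1 means
"above cutoff".  Scanning post-baseline samples in date order, a feature
elevated strictly beyond its cutoff at two consecutive time points marks a
molecular progression; the FIRST point of the earliest qualifying run is
the ctDNA-based PD date.  The same rule applied to CEA / (5 ng/mL) yields
the CEA-based PD.  Lead time is the day count by which a molecular call
precedes the imaging (CT) PD date; a patient counts as "ahead" only with a
strictly positive lead.

Baseline itself can never be the PD point: progression is a change on
therapy, so runs are evaluated from the first post-baseline draw onward.
Patients with fewer than three samples are excluded from PD monitoring
with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .io import add_variant_keys

#: Fixed tie-break order when several features qualify on the same date.
FEATURE_PRIORITY = ("erbb2_cnv", "tcl", "tmb")

MIN_SAMPLES_FOR_MONITORING = 3


@dataclass(frozen=True)
class ProgressionCall:
    patient_id: str
    source: str  # ctdna | cea | ct
    date: pd.Timestamp
    trigger: str  # erbb2_cnv | tcl | tmb | cea | imaging
    lead_days: int | None = None  # vs CT-PD; positive = earlier


class TimelineError(ValueError):
    """Patient timeline violates an invariant (order, sample count...)."""


def relative_fold_series(values, cutoff: float) -> np.ndarray:
    """Normalize a feature series to relative folds of its cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return np.asarray(values, dtype=float) / cutoff


def first_sustained_run(above: np.ndarray, min_points: int = 2, consecutive: bool = True) -> int | None:
    """Index of the first point of the earliest qualifying run.

    ``above`` is a boolean series over post-baseline points in date order.
    With ``consecutive`` (default) a run is ``min_points`` consecutive True
    values; otherwise the ``min_points``-th True anywhere qualifies and the
    call lands on the first True.
    """
    above = np.asarray(above, dtype=bool)
    if not consecutive:
        idx = np.flatnonzero(above)
        return int(idx[0]) if len(idx) >= min_points else None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_points:
            return i - min_points + 1
    return None


def _check_timeline(timeline: pd.DataFrame, patient_id: str) -> pd.DataFrame:
    tl = timeline.sort_values("date").reset_index(drop=True)
    if tl["date"].duplicated().any():
        raise TimelineError(f"{patient_id}: duplicate sample dates")
    if not tl["date"].is_monotonic_increasing:
        raise TimelineError(f"{patient_id}: dates not strictly increasing")
    return tl


def call_ctdna_pd(
    timeline: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
    consecutive: bool = True,
) -> ProgressionCall | None:
    """Call ctDNA-based PD from a per-patient feature timeline.

    ``timeline`` needs columns date, erbb2_fold, tcl, tmb (one row per
    plasma draw, baseline first).  Any of the three features strictly above
    its cutoff at >= 2 consecutive post-baseline points triggers the call;
    the earliest run wins, same-date ties broken by the fixed feature
    order (erbb2_cnv, tcl, tmb).
    """
    thresholds = thresholds or ThresholdConfig()
    patient_id = str(timeline["patient_id"].iloc[0]) if "patient_id" in timeline else ""
    tl = _check_timeline(timeline, patient_id)
    if len(tl) < MIN_SAMPLES_FOR_MONITORING:
        raise TimelineError(
            f"{patient_id}: needs >= {MIN_SAMPLES_FOR_MONITORING} samples for PD monitoring"
        )
    post = tl.iloc[1:]  # runs are evaluated from the first post-baseline draw
    cutoffs = {
        "erbb2_cnv": (post["erbb2_fold"], thresholds.cnv_gain_fold),
        "tcl": (post["tcl"], thresholds.tcl_high_cutoff),
        "tmb": (post["tmb"], thresholds.tmb_high_cutoff),
    }
    best: tuple[int, int] | None = None  # (post-index, priority)
    for prio, feat in enumerate(FEATURE_PRIORITY):
        series, cutoff = cutoffs[feat]
        ratios = relative_fold_series(series, cutoff)
        idx = first_sustained_run(ratios > 1.0, consecutive=consecutive)
        if idx is not None and (best is None or (idx, prio) < best):
            best = (idx, prio)
    if best is None:
        return None
    return ProgressionCall(
        patient_id=patient_id,
        source="ctdna",
        date=post["date"].iloc[best[0]],
        trigger=FEATURE_PRIORITY[best[1]],
    )


def call_cea_pd(
    timeline: pd.DataFrame,
    cea_cutoff: float = 5.0,
    consecutive: bool = True,
) -> ProgressionCall | None:
    """CEA-based PD: the same sustained-elevation rule on CEA / cutoff."""
    patient_id = str(timeline["patient_id"].iloc[0]) if "patient_id" in timeline else ""
    tl = _check_timeline(timeline, patient_id)
    cea = tl["cea_ng_ml"].astype(float)
    if (cea <= 0).any():
        raise TimelineError(f"{patient_id}: non-positive CEA concentration")
    post = tl.iloc[1:]
    ratios = relative_fold_series(post["cea_ng_ml"], cea_cutoff)
    idx = first_sustained_run(ratios > 1.0, consecutive=consecutive)
    if idx is None:
        return None
    return ProgressionCall(
        patient_id=patient_id, source="cea", date=post["date"].iloc[idx], trigger="cea"
    )


def cea_log2_index(cea_series, cea_cutoff: float = 5.0) -> np.ndarray:
    """log2(CEA / cutoff) display index for trajectory plots."""
    return np.log2(relative_fold_series(cea_series, cea_cutoff))


def compute_lead_time(molecular_pd_date, ct_pd_date) -> int:
    """Days by which the molecular call precedes imaging PD (positive = earlier)."""
    return int((pd.Timestamp(ct_pd_date) - pd.Timestamp(molecular_pd_date)).days)


def summarize_lead_times(lead_days: list[int]) -> dict:
    """Cohort lead-time summary over patients with both PD dates.

    "Ahead" means a strictly positive lead; the mean advancement averages
    over ahead patients only.
    """
    n = len(lead_days)
    ahead = [d for d in lead_days if d > 0]
    return {
        "n_evaluable": n,
        "n_ahead": len(ahead),
        "ahead_fraction": len(ahead) / n if n else float("nan"),
        "mean_advancement_days": float(np.mean(ahead)) if ahead else float("nan"),
    }


def detect_emerging_alterations(
    baseline_variants: pd.DataFrame,
    progression_variants: pd.DataFrame,
    baseline_cnv: pd.DataFrame | None = None,
    progression_cnv: pd.DataFrame | None = None,
) -> dict:
    """New alterations at progression relative to baseline.

    Variants are compared by site key (chrom, pos, ref, alt); CNV gains and
    losses (tables with gene/call columns) are compared by (gene, call) and
    reported separately.
    """
    bl_keys = set(add_variant_keys(baseline_variants)["key"])
    pd_keys = add_variant_keys(progression_variants)
    new_mask = [k not in bl_keys for k in pd_keys["key"]]
    new_variants = progression_variants[np.array(new_mask, dtype=bool)] if len(
        progression_variants
    ) else progression_variants.copy()

    new_cnv = pd.DataFrame(columns=["gene", "call"])
    if progression_cnv is not None:
        prog = progression_cnv[progression_cnv["call"] != "neutral"]
        bl_calls = set()
        if baseline_cnv is not None:
            bl = baseline_cnv[baseline_cnv["call"] != "neutral"]
            bl_calls = set(zip(bl["gene"], bl["call"]))
        mask = [not (g, c) in bl_calls for g, c in zip(prog["gene"], prog["call"])]
        new_cnv = prog.loc[mask, ["gene", "call"]].reset_index(drop=True)
    return {"variants": new_variants.reset_index(drop=True), "cnv": new_cnv}


def monitor_patient(
    timeline: pd.DataFrame,
    ct_pd_date=None,
    thresholds: ThresholdConfig | None = None,
) -> dict:
    """Run all PD calls for one patient and attach lead times vs CT-PD."""
    thresholds = thresholds or ThresholdConfig()
    ctdna = call_ctdna_pd(timeline, thresholds)
    cea = call_cea_pd(timeline, thresholds.cea_cutoff)
    calls = {"ctdna": ctdna, "cea": cea, "ct": None}
    if ct_pd_date is not None:
        pid = str(timeline["patient_id"].iloc[0]) if "patient_id" in timeline else ""
        calls["ct"] = ProgressionCall(
            patient_id=pid, source="ct", date=pd.Timestamp(ct_pd_date),
            trigger="imaging", lead_days=0,
        )
        for src in ("ctdna", "cea"):
            call = calls[src]
            if call is not None:
                calls[src] = ProgressionCall(
                    patient_id=call.patient_id, source=call.source, date=call.date,
                    trigger=call.trigger,
                    lead_days=compute_lead_time(call.date, ct_pd_date),
                )
    return calls
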