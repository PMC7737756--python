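"""Cohort-level stratified outcome analysis.

Patients are stratified by baseline ERBB2 amplification × TMB class (the
four ``EhighThigh``... labels) and by baseline→first-point dynamics per
feature (``dn`` high→low, ``up`` low→high, ``remainL``, ``remainH``).
Per stratum the module reports the objective response rate (ORR = PR+CR
over evaluable patients), disease control rate (DCR = PR+CR+SD), and the
Kaplan–Meier PFS curve with median and two-group log-rank test
(lifelines).  Plasma/tissue HER2 agreement is quantified with percent
agreement and unweighted Cohen's kappa on the 2×2 table; feature–CEA
association with Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .config import ThresholdConfig

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
OBJECTIVE_RESPONSES = ("CR", "PR")
DISEASE_CONTROL = ("CR", "PR", "SD")

DYNAMICS_TABLE = {
    ("high", "low"): "dn",
    ("low", "high"): "up",
    ("low", "low"): "remainL",
    ("high", "high"): "remainH",
}


def assign_baseline_stratum(
    erbb2_fold: float, tmb: float, thresholds: ThresholdConfig | None = None
) -> dict:
    """Baseline ERBB2 × TMB stratum label for one patient."""
    thresholds = thresholds or ThresholdConfig()
    e = "high" if erbb2_fold >= thresholds.cnv_gain_fold else "low"
    t = "high" if tmb >= thresholds.tmb_high_cutoff else "low"
    return {"erbb2": e, "tmb": t, "combined": f"E{e}T{t}"}


def assign_dynamics_category(bl_class: str, fp_class: str) -> str:
    """Baseline→first-point dynamics: dn, up, remainL or remainH."""
    try:
        return DYNAMICS_TABLE[(bl_class, fp_class)]
    except KeyError:
        raise ValueError(f"classes must be high/low, got ({bl_class}, {fp_class})")


def compute_orr_dcr(responses) -> dict:
    """Objective response and disease control rates with their counts.

    ORR counts PR (and CR, none in a typical anti-HER2 gastric cohort);
    DCR adds SD.  Rates are percentages; an empty stratum reports NaN.
    """
    resp = [str(r) for r in responses]
    bad = set(resp) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories: {sorted(bad)}")
    n = len(resp)
    n_obj = sum(r in OBJECTIVE_RESPONSES for r in resp)
    n_dc = sum(r in DISEASE_CONTROL for r in resp)
    return {
        "n": n,
        "orr_count": n_obj,
        "dcr_count": n_dc,
        "orr_pct": 100.0 * n_obj / n if n else float("nan"),
        "dcr_pct": 100.0 * n_dc / n if n else float("nan"),
    }


def km_estimate(times, events) -> dict:
    """Kaplan–Meier product-limit estimate with right censoring.

    Returns the survival table (time, survival), the median survival time
    (earliest t with S(t) <= 0.5; NaN = not reached) and the fitted
    lifelines object for plotting.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_.reset_index()
    surv.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):  # never reached
        median = float("nan")
    return {"survival": surv, "median": median, "model": kmf}


def logrank_two_groups(times_a, events_a, times_b, events_b) -> dict:
    """Two-sample log-rank test (chi-square statistic and p-value)."""
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return {"chi_sq": float(res.test_statistic), "p_value": float(res.p_value)}


def concordance_stats(table) -> dict:
    """Percent agreement and unweighted Cohen's kappa for a 2×2 table.

    ``table`` is [[both-positive, plasma+/tissue-], [plasma-/tissue+,
    both-negative]] counts.  Kappa = (p_o − p_e) / (1 − p_e) with expected
    agreement from the row/column margins; significance via the
    large-sample variance approximation.  Degenerate margins (p_e = 1)
    leave kappa undefined (NaN).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    n = t.sum()
    if n < 1:
        raise ValueError("need at least one matched pair")
    p_o = np.trace(t) / n
    rows = t.sum(axis=1) / n
    cols = t.sum(axis=0) / n
    p_e = float(rows @ cols)
    if np.isclose(p_e, 1.0):
        kappa = float("nan")
        p_value = float("nan")
    else:
        kappa = (p_o - p_e) / (1 - p_e)
        # large-sample SE of kappa under H0: kappa = 0
        se0 = np.sqrt(p_e / (n * (1 - p_e)))
        z = kappa / se0 if se0 > 0 else float("nan")
        p_value = float(2 * stats.norm.sf(abs(z)))
    return {
        "n_pairs": int(n),
        "agreement_pct": 100.0 * p_o,
        "kappa": float(kappa),
        "p_value": p_value,
    }


def feature_cea_correlation(feature_values, cea_values) -> dict:
    """Spearman rank correlation between one feature series and CEA."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(cea_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": float("nan"), "p_value": float("nan"), "n": len(x)}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "n": len(x)}


def stratified_outcomes(patients: pd.DataFrame, group_col: str) -> dict:
    """ORR/DCR and KM summary per level of ``group_col``.

    ``patients`` needs columns best_response, pfs_months, pfs_event plus
    the grouping column.  Pairwise log-rank tests are reported for every
    pair of levels.
    """
    out: dict = {"strata": {}, "logrank": {}}
    levels = [lv for lv in patients[group_col].unique() if pd.notna(lv)]
    for level in sorted(levels):
        grp = patients[patients[group_col] == level]
        rates = compute_orr_dcr(grp["best_response"])
        km = km_estimate(grp["pfs_months"], grp["pfs_event"])
        out["strata"][str(level)] = {
            **rates,
            "median_pfs_months": km["median"],
        }
    for i, a in enumerate(sorted(levels)):
        for b in sorted(levels)[i + 1:]:
            ga = patients[patients[group_col] == a]
            gb = patients[patients[group_col] == b]
            if len(ga) and len(gb):
                out["logrank"][f"{a}_vs_{b}"] = logrank_two_groups(
                    ga["pfs_months"], ga["pfs_event"], gb["pfs_months"], gb["pfs_event"]
                )
    return out
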