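"""End-to-end orchestration: raw tables -> denoised features -> cohort report.

``run_pipeline`` consumes a cohort directory (healthy pool, WBC database,
per-sample variant tables, copy-ratio TSV, clinical CSV, optional
panel.json) and produces the features TSV, progression-calls TSV, outcome
JSON and a human-readable summary.  Every filtering step logs counts
in/out to stderr; patients violating timeline invariants are excluded with
a logged reason, never silently dropped.  Output is deterministic given
the inputs.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import PanelDefinition, ThresholdConfig
from .denoise import WBCDatabase, build_background_model, denoise_sample
from .features import (
    compute_blood_indexes,
    extract_sample_features,
    features_to_frame,
)
from .monitor import (
    MIN_SAMPLES_FOR_MONITORING,
    TimelineError,
    detect_emerging_alterations,
    monitor_patient,
    summarize_lead_times,
)
from .outcomes import (
    assign_baseline_stratum,
    assign_dynamics_category,
    compute_orr_dcr,
    concordance_stats,
    feature_cea_correlation,
    stratified_outcomes,
)

logger = logging.getLogger("ctdnamon")

DAYS_PER_MONTH = 30.4375


def load_panel(path: str | Path) -> PanelDefinition:
    with open(path) as fh:
        data = json.load(fh)
    return PanelDefinition(
        genes=tuple(data["genes"]),
        coding_footprint_mb=float(data["coding_footprint_mb"]),
        driver_sites=frozenset(tuple(k) for k in data.get("driver_sites", [])),
        driver_hotspots=frozenset(tuple(p) for p in data.get("driver_hotspots", [])),
    )


def _best_response(post_responses: list[str]) -> str:
    for level in ("CR", "PR", "SD"):
        if level in post_responses:
            return level
    return "PD"


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    panel: PanelDefinition | None = None,
    thresholds: ThresholdConfig | None = None,
) -> dict:
    """Run denoising, feature extraction, monitoring and outcome analysis.

    Returns the report dict that is also written to ``outcomes.json``.
    """
    inp = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or ThresholdConfig()
    if panel is None:
        panel_path = inp / "panel.json"
        panel = load_panel(panel_path) if panel_path.exists() else PanelDefinition()

    # --- denoising setup -------------------------------------------------
    healthy_paths = sorted((inp / "healthy").glob("healthy_*.tsv"))
    healthy = [cio.read_variant_table(p) for p in healthy_paths]
    model = build_background_model(healthy)
    wbc_tab, wbc_total = cio.read_wbc_database(inp / "wbc_database.tsv")
    wbc_db = WBCDatabase.from_table(wbc_tab, wbc_total)
    logger.info("stage=background_model sites=%d pool=%d", len(model.sites), model.pool_size)

    folds_all = cio.read_copy_ratios(inp / "copy_ratios.tsv")
    clinical = cio.read_clinical_table(inp / "clinical.csv")

    # --- per-sample denoise + features -----------------------------------
    feature_list, blood_map, logs = [], {}, []
    denoised_by_sample: dict[str, pd.DataFrame] = {}
    for _, row in clinical.sort_values(["patient_id", "date"]).iterrows():
        sid = row["sample_id"]
        vpath = inp / "variants" / f"{sid}.tsv"
        variants = cio.read_variant_table(vpath)
        kept, log = denoise_sample(variants, wbc_db, model)
        logger.info(
            "stage=denoise sample=%s in=%d out=%d removed=%d",
            sid, len(variants), len(kept), len(log),
        )
        log.insert(0, "sample_id", sid)
        logs.append(log)
        denoised_by_sample[sid] = kept
        folds = folds_all[folds_all["sample_id"] == sid]
        feature_list.append(
            extract_sample_features(sid, kept, folds, panel, thresholds)
        )
        if row["alc"] > 0:
            blood_map[sid] = compute_blood_indexes(row["anc"], row["amc"], row["alc"])

    features = features_to_frame(feature_list, blood_map)
    features.to_csv(out / "features.tsv", sep="\t", index=False)
    pd.concat(logs, ignore_index=True).to_csv(out / "removal_log.tsv", sep="\t", index=False)

    merged = clinical.merge(features, on="sample_id", how="left")

    # --- longitudinal monitoring -----------------------------------------
    calls_rows, lead_days_ct, lead_days_cea, excluded = [], [], [], []
    emerging_count = 0
    for pid, tl in merged.groupby("patient_id"):
        tl = tl.sort_values("date").reset_index(drop=True)
        ct_rows = tl[tl["response"] == "PD"]
        ct_pd_date = ct_rows["date"].iloc[0] if len(ct_rows) else None
        if len(tl) < MIN_SAMPLES_FOR_MONITORING:
            excluded.append({"patient_id": pid, "reason": "fewer_than_3_samples"})
            logger.info("stage=monitor patient=%s excluded=fewer_than_3_samples", pid)
            continue
        try:
            calls = monitor_patient(tl, ct_pd_date, thresholds)
        except TimelineError as exc:
            excluded.append({"patient_id": pid, "reason": str(exc)})
            logger.info("stage=monitor patient=%s excluded=%s", pid, exc)
            continue
        for src, call in calls.items():
            if call is None:
                continue
            calls_rows.append(
                {
                    "patient_id": pid, "source": src,
                    "date": pd.Timestamp(call.date).strftime("%Y-%m-%d"),
                    "trigger": call.trigger,
                    "lead_days": call.lead_days if call.lead_days is not None else "",
                }
            )
        if ct_pd_date is not None:
            if calls["ctdna"] is not None:
                lead_days_ct.append(calls["ctdna"].lead_days)
            if calls["cea"] is not None:
                lead_days_cea.append(calls["cea"].lead_days)
            # emerging alterations: first progression sample vs baseline;
            # an AF floor keeps residual background noise out of the count
            bl_sid, pd_sid = tl["sample_id"].iloc[0], ct_rows["sample_id"].iloc[0]
            new = detect_emerging_alterations(
                denoised_by_sample[bl_sid], denoised_by_sample[pd_sid]
            )
            if (new["variants"]["af"] >= 0.01).any():
                emerging_count += 1

    calls_df = pd.DataFrame(
        calls_rows, columns=["patient_id", "source", "date", "trigger", "lead_days"]
    )
    calls_df.to_csv(out / "progression_calls.tsv", sep="\t", index=False)
    lead_summary = {
        "ctdna": summarize_lead_times([d for d in lead_days_ct if d is not None]),
        "cea": summarize_lead_times([d for d in lead_days_cea if d is not None]),
        "patients_with_emerging_alterations": emerging_count,
    }

    # --- cohort outcomes --------------------------------------------------
    patients = []
    for pid, tl in merged.groupby("patient_id"):
        tl = tl.sort_values("date").reset_index(drop=True)
        bl, post = tl.iloc[0], tl.iloc[1:]
        responses = [r for r in post["response"] if r in ("CR", "PR", "SD", "PD")]
        if not responses:
            continue
        stratum = assign_baseline_stratum(bl["erbb2_fold"], bl["tmb"], thresholds)
        ct_rows = tl[tl["response"] == "PD"]
        if len(ct_rows):
            pfs_months = (ct_rows["date"].iloc[0] - bl["date"]).days / DAYS_PER_MONTH
            event = True
        else:
            pfs_months = (tl["date"].iloc[-1] - bl["date"]).days / DAYS_PER_MONTH
            event = False
        rec = {
            "patient_id": pid,
            "best_response": _best_response(list(responses)),
            "pfs_months": pfs_months,
            "pfs_event": event,
            "erbb2_bl": stratum["erbb2"],
            "tmb_bl": stratum["tmb"],
            "stratum": stratum["combined"],
            "tissue_her2": bl["tissue_her2"],
            "erbb2_status_bl": bl["erbb2_status"],
        }
        if len(tl) >= 2:
            fp = tl.iloc[1]
            for feat in ("erbb2", "tmb", "tcl"):
                col = {"erbb2": "erbb2_status", "tmb": "tmb_class", "tcl": "tcl_class"}[feat]
                bl_cls = "high" if bl[col] in ("high", "amplified") else "low"
                fp_cls = "high" if fp[col] in ("high", "amplified") else "low"
                rec[f"{feat}_dynamics"] = assign_dynamics_category(bl_cls, fp_cls)
        patients.append(rec)
    patients_df = pd.DataFrame(patients)

    report: dict = {
        "thresholds": thresholds.to_dict(),
        "n_samples": len(features),
        "n_patients": int(patients_df["patient_id"].nunique()) if len(patients_df) else 0,
        "excluded_patients": excluded,
        "lead_time": lead_summary,
    }
    if len(patients_df):
        report["cohort"] = compute_orr_dcr(patients_df["best_response"])
        report["baseline_strata"] = stratified_outcomes(patients_df, "stratum")
        report["erbb2_bl"] = stratified_outcomes(patients_df, "erbb2_bl")
        report["tmb_bl"] = stratified_outcomes(patients_df, "tmb_bl")
        for feat in ("erbb2", "tmb", "tcl"):
            col = f"{feat}_dynamics"
            if col in patients_df:
                report[f"{feat}_dynamics"] = stratified_outcomes(patients_df, col)

        tissue = patients_df[patients_df["tissue_her2"].isin(["positive", "negative"])]
        if len(tissue):
            plasma_amp = tissue["erbb2_status_bl"] == "amplified"
            tissue_pos = tissue["tissue_her2"] == "positive"
            table = [
                [int((plasma_amp & tissue_pos).sum()), int((plasma_amp & ~tissue_pos).sum())],
                [int((~plasma_amp & tissue_pos).sum()), int((~plasma_amp & ~tissue_pos).sum())],
            ]
            report["erbb2_tissue_concordance"] = {**concordance_stats(table), "table": table}

        corr = {}
        paired = merged.dropna(subset=["cea_ng_ml"])
        for feat in ("erbb2_fold", "tcl", "tmb"):
            vals = paired[[feat, "cea_ng_ml"]].dropna()
            if len(vals) >= 3:
                corr[feat] = feature_cea_correlation(vals[feat], vals["cea_ng_ml"])
        report["feature_cea_spearman"] = corr

    _strip = lambda o: json.loads(json.dumps(o, default=_json_default))
    report = _strip(report)
    with open(out / "outcomes.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(_render_summary(report))
    logger.info(
        "stage=report patients=%d samples=%d", report["n_patients"], report["n_samples"]
    )
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating, float)) and math.isnan(o):
        return None
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, pd.Timestamp):
        return o.strftime("%Y-%m-%d")
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(o)}")


def _render_summary(report: dict) -> str:
    lines = [
        "ctDNA monitoring cohort report",
        "==============================",
        f"patients: {report['n_patients']}  plasma samples: {report['n_samples']}",
    ]
    if "cohort" in report:
        c = report["cohort"]
        lines.append(
            f"cohort ORR {c['orr_pct']:.1f}% ({c['orr_count']}/{c['n']}), "
            f"DCR {c['dcr_pct']:.1f}% ({c['dcr_count']}/{c['n']})"
        )
    lt = report["lead_time"]["ctdna"]
    if lt["n_evaluable"]:
        frac = 100 * lt["ahead_fraction"]
        mean_adv = lt["mean_advancement_days"]
        mean_txt = f"{mean_adv:.1f}" if mean_adv is not None else "n/a"
        lines.append(
            f"ctDNA PD ahead of imaging in {lt['n_ahead']}/{lt['n_evaluable']} "
            f"({frac:.1f}%), mean advancement {mean_txt} days"
        )
    if "erbb2_tissue_concordance" in report:
        cc = report["erbb2_tissue_concordance"]
        lines.append(
            f"plasma/tissue HER2 agreement {cc['agreement_pct']:.1f}% "
            f"(kappa {cc['kappa']:.2f}, n={cc['n_pairs']})"
        )
    return "\n".join(lines) + "\n"
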