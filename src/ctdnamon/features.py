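"""Per-sample genomic features from denoised variant and copy-ratio tables.

Features computed per plasma sample:

* **TMB** — coding substitutions and indels per megabase of assayed coding
  sequence.  Synonymous variants are counted (they damp sampling noise);
  known driver alterations are excluded; splice and "other" effects are
  excluded by default.  High iff TMB >= 8.5 mut/Mb.
* **Gene CNV calls** — fold >= 1.4 is a gain, fold <= 0.65 a loss
  (inclusive boundaries), otherwise neutral.
* **TCL** — total copy-number load, the count of genes called gain or
  loss.  High iff TCL >= 2.
* **ERBB2 status** — amplified iff the ERBB2 fold reaches the gain cutoff.
* **MaxiVAF** — the highest allele fraction among surviving somatic
  variants, a tumor-fraction proxy; NaN when no variant survives.
* **NLR / MLR** — absolute neutrophil (monocyte) count over absolute
  lymphocyte count.

Fixed cutoffs are the primary classification mode; cohort-tertile cutoffs
(top 33.3% = high) can be recomputed as a secondary mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PanelDefinition, ThresholdConfig, TMB_EFFECTS
from .io import add_variant_keys


@dataclass(frozen=True)
class BloodIndexes:
    anc: float
    amc: float
    alc: float

    def __post_init__(self) -> None:
        if not self.alc > 0:
            raise ValueError("absolute lymphocyte count must be > 0")

    @property
    def nlr(self) -> float:
        return self.anc / self.alc

    @property
    def mlr(self) -> float:
        return self.amc / self.alc


@dataclass
class SampleFeatures:
    """Genomic feature bundle for one plasma sample."""

    sample_id: str
    tmb: float
    tcl: int
    erbb2_fold: float
    maxivaf: float  # NaN when undefined (no surviving variant)
    cnv_calls: pd.DataFrame  # gene, fold, call
    thresholds: ThresholdConfig

    @property
    def tmb_class(self) -> str:
        return "high" if self.tmb >= self.thresholds.tmb_high_cutoff else "low"

    @property
    def tcl_class(self) -> str:
        return "high" if self.tcl >= self.thresholds.tcl_high_cutoff else "low"

    @property
    def erbb2_status(self) -> str:
        return (
            "amplified"
            if self.erbb2_fold >= self.thresholds.cnv_gain_fold
            else "not_amplified"
        )


def compute_blood_indexes(anc: float, amc: float, alc: float) -> BloodIndexes:
    return BloodIndexes(anc=anc, amc=amc, alc=alc)


def compute_tmb(
    variants: pd.DataFrame,
    panel: PanelDefinition,
    include_splice_other: bool = False,
) -> float:
    """Mutations per megabase over the panel's coding footprint.

    Counts coding substitutions and indels (synonymous included), excludes
    variants matching the driver catalogue by site key or (gene,
    protein_change) hotspot, and divides by ``coding_footprint_mb``.
    """
    if panel.coding_footprint_mb <= 0:
        raise ValueError("coding footprint must be positive")
    if len(variants) == 0:
        return 0.0
    effects = set(TMB_EFFECTS)
    if include_splice_other:
        effects |= {"splice", "other"}
    keyed = add_variant_keys(variants)
    counted = keyed["effect"].isin(effects)
    counted &= ~keyed["key"].isin(panel.driver_sites)
    if "protein_change" in keyed.columns and panel.driver_hotspots:
        hotspot = [
            (g, p) in panel.driver_hotspots
            for g, p in zip(keyed["gene"], keyed["protein_change"].fillna(""))
        ]
        counted &= ~np.array(hotspot)
    return float(counted.sum()) / panel.coding_footprint_mb


def call_gene_cnv(fold: float, thresholds: ThresholdConfig) -> str:
    """Classify one gene fold: gain (>= 1.4), loss (<= 0.65) or neutral."""
    if fold < 0:
        raise ValueError("copy-ratio fold must be non-negative")
    if fold >= thresholds.cnv_gain_fold:
        return "gain"
    if fold <= thresholds.cnv_loss_fold:
        return "loss"
    return "neutral"


def call_cnv_table(folds: pd.DataFrame, thresholds: ThresholdConfig) -> pd.DataFrame:
    """Per-gene CNV calls for one sample (columns gene, fold -> + call)."""
    if folds["gene"].duplicated().any():
        dup = folds["gene"][folds["gene"].duplicated()].iloc[0]
        raise ValueError(f"duplicate copy-ratio entry for gene {dup}")
    out = folds[["gene", "fold"]].copy()
    out["call"] = [call_gene_cnv(f, thresholds) for f in out["fold"]]
    return out


def compute_tcl(cnv_calls: pd.DataFrame) -> int:
    """Total copy-number load: number of genes called gain or loss."""
    return int((cnv_calls["call"] != "neutral").sum())


def compute_maxivaf(variants: pd.DataFrame) -> float:
    """Highest AF among surviving variants; NaN when none survive."""
    if len(variants) == 0:
        return float("nan")
    return float(variants["af"].max())


def extract_sample_features(
    sample_id: str,
    denoised_variants: pd.DataFrame,
    copy_ratios: pd.DataFrame,
    panel: PanelDefinition,
    thresholds: ThresholdConfig | None = None,
) -> SampleFeatures:
    """Compute the full feature bundle for one sample.

    ``copy_ratios`` holds this sample's per-gene folds; a missing ERBB2 row
    is treated as diploid (fold 1.0).
    """
    thresholds = thresholds or ThresholdConfig()
    cnv = call_cnv_table(copy_ratios, thresholds)
    erbb2 = cnv.loc[cnv["gene"] == "ERBB2", "fold"]
    return SampleFeatures(
        sample_id=sample_id,
        tmb=compute_tmb(denoised_variants, panel),
        tcl=compute_tcl(cnv),
        erbb2_fold=float(erbb2.iloc[0]) if len(erbb2) else 1.0,
        maxivaf=compute_maxivaf(denoised_variants),
        cnv_calls=cnv,
        thresholds=thresholds,
    )


def features_to_frame(features: list[SampleFeatures], blood: dict | None = None) -> pd.DataFrame:
    """Flatten feature bundles to the features TSV layout.

    ``blood`` optionally maps sample_id -> BloodIndexes to fill NLR/MLR.
    """
    rows = []
    for f in features:
        b = (blood or {}).get(f.sample_id)
        rows.append(
            {
                "sample_id": f.sample_id,
                "tmb": f.tmb,
                "tmb_class": f.tmb_class,
                "tcl": f.tcl,
                "tcl_class": f.tcl_class,
                "erbb2_fold": f.erbb2_fold,
                "erbb2_status": f.erbb2_status,
                "maxivaf": f.maxivaf,
                "nlr": b.nlr if b else float("nan"),
                "mlr": b.mlr if b else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def tertile_cutoff(values) -> float:
    """Cohort-specific "high" cutoff: the smallest value inside the top third.

    With n samples the top tertile holds floor(n/3) samples; the cutoff is
    the (n - floor(n/3))-th order statistic (1-based), so values >= cutoff
    are classified high.  Requires n >= 3.
    """
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n < 3:
        raise ValueError("tertile classification needs at least 3 samples")
    k = n // 3
    return vals[n - k]


def classify_tertile(values) -> pd.Series:
    """Secondary classification mode: top-33.3% of the cohort is high."""
    cutoff = tertile_cutoff(values)
    return pd.Series(["high" if float(v) >= cutoff else "low" for v in values])
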