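"""Two-stage artifact elimination for plasma variant calls.

Stage 1 removes variants recurrent in a white-blood-cell (WBC) database —
clonal-hematopoiesis and technical artifacts — when they occur in strictly
more than 10% of the WBC samples.  Stage 2 keeps a variant only when its
allele fraction exceeds, strictly, the healthy-plasma mean AF at that site
by more than three standard deviations (sample SD, n-1); sites never
observed in the healthy pool fall back to statistics pooled over all
site-observations.  Both thresholds are allele-specific: the site key is
(chrom, pos, ref, alt).

An optional, off-by-default binomial-tail check on supporting reads is
provided for the under-specified "distinct supporting reads" criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import add_variant_keys

WBC_RECURRENCE_CUTOFF = 0.10  # strict: removed iff occurrence fraction > 10%
SD_MULTIPLIER = 3.0  # retained iff af > mean + 3*SD (strict)


@dataclass(frozen=True)
class WBCDatabase:
    """Occurrence counts of variants across a WBC cohort."""

    total_samples: int
    occurrence: dict  # variant key -> number of WBC samples carrying it

    def __post_init__(self) -> None:
        if self.total_samples < 1:
            raise ValueError("WBC database needs total_samples >= 1")
        bad = [k for k, v in self.occurrence.items() if v > self.total_samples]
        if bad:
            raise ValueError(f"occurrence exceeds total_samples for {bad[0]}")

    @classmethod
    def from_table(cls, df: pd.DataFrame, total_samples: int) -> "WBCDatabase":
        keyed = add_variant_keys(df)
        return cls(total_samples, dict(zip(keyed["key"], keyed["count"].astype(int))))

    def recurrence(self, key: tuple) -> float:
        return self.occurrence.get(key, 0) / self.total_samples


@dataclass
class BackgroundErrorModel:
    """Per-site healthy-plasma AF statistics backing the 3-SD retention rule.

    ``sites`` maps site key -> (mean_af, sd_af, n_obs).  ``fallback`` holds
    (mean, sd) pooled over every site-observation, used for panel sites with
    no healthy record.  SDs use the sample convention (ddof=1); a healthy
    individual with no call at a site is counted as AF 0, so n_obs equals
    the pool size everywhere.
    """

    sites: dict
    fallback: tuple[float, float]
    pool_size: int
    sd_convention: str = "sample (ddof=1)"

    def threshold(self, key: tuple) -> float:
        """Retention threshold mean + 3*SD at this site (fallback if unseen)."""
        mean, sd, _ = self.sites.get(key, (*self.fallback, self.pool_size))
        return mean + SD_MULTIPLIER * sd

    def site_mean(self, key: tuple) -> float:
        return self.sites.get(key, (*self.fallback, self.pool_size))[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
             "mean_af": m, "sd_af": s, "n_obs": n}
            for k, (m, s, n) in sorted(self.sites.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "mean_af", "sd_af", "n_obs"])


def build_background_model(healthy_tables: list[pd.DataFrame]) -> BackgroundErrorModel:
    """Assemble per-site AF mean/SD from a pool of healthy plasma samples.

    Every site seen in any healthy sample gets a record over the full pool,
    with absent observations imputed as AF 0.  The fallback statistic pools
    all site-observations (again with zeros for absences).
    """
    n = len(healthy_tables)
    if n == 0:
        raise ValueError("healthy pool is empty")
    per_sample: list[dict] = []
    all_sites: set = set()
    for tab in healthy_tables:
        keyed = add_variant_keys(tab)
        obs = dict(zip(keyed["key"], keyed["af"].astype(float)))
        per_sample.append(obs)
        all_sites.update(obs)

    sites: dict = {}
    pooled: list[np.ndarray] = []
    for key in all_sites:
        afs = np.array([obs.get(key, 0.0) for obs in per_sample])
        sd = float(afs.std(ddof=1)) if n > 1 else 0.0
        sites[key] = (float(afs.mean()), sd, n)
        pooled.append(afs)
    if pooled:
        flat = np.concatenate(pooled)
        fb_sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
        fallback = (float(flat.mean()), fb_sd)
    else:
        fallback = (0.0, 0.0)
    return BackgroundErrorModel(sites=sites, fallback=fallback, pool_size=n)


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "gene", "af", "reason", "detail"]
    )


def wbc_artifact_filter(
    variants: pd.DataFrame, wbc_db: WBCDatabase
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop variants recurrent in >10% (strict) of WBC samples.

    Returns (retained variants, removal log); unknown variants pass.
    """
    if len(variants) == 0:
        return variants.copy(), _empty_log()
    keyed = add_variant_keys(variants)
    frac = keyed["key"].map(wbc_db.recurrence)
    removed_mask = frac > WBC_RECURRENCE_CUTOFF
    removed = keyed[removed_mask]
    log = removed[["chrom", "pos", "ref", "alt", "gene", "af"]].copy()
    log["reason"] = "wbc_recurrent"
    log["detail"] = [f"recurrence={f:.4f}" for f in frac[removed_mask]]
    retained = variants[~removed_mask.to_numpy()].reset_index(drop=True)
    return retained, log.reset_index(drop=True)


def background_denoise(
    variants: pd.DataFrame,
    model: BackgroundErrorModel,
    read_support_alpha: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep variants whose AF strictly exceeds the site mean + 3*SD.

    With ``read_support_alpha`` set, a variant must additionally have
    alt_reads significantly beyond the site's mean error rate under a
    one-sided binomial tail test at that alpha (off by default).
    """
    if (variants["af"] < 0).any():
        raise ValueError("negative AF in variant table")
    if len(variants) == 0:
        return variants.copy(), _empty_log()
    keyed = add_variant_keys(variants)
    thresholds = keyed["key"].map(model.threshold)
    keep = keyed["af"].to_numpy() > thresholds.to_numpy()

    detail = [f"threshold={t:.6g}" for t in thresholds]
    if read_support_alpha is not None:
        means = keyed["key"].map(model.site_mean).to_numpy()
        pvals = stats.binom.sf(
            keyed["alt_reads"].to_numpy() - 1, keyed["depth"].to_numpy(), means
        )
        keep &= pvals < read_support_alpha

    log = keyed.loc[~keep, ["chrom", "pos", "ref", "alt", "gene", "af"]].copy()
    log["reason"] = "background_noise"
    log["detail"] = [d for d, k in zip(detail, keep) if not k]
    retained = variants[keep].reset_index(drop=True)
    return retained, log.reset_index(drop=True)


def denoise_sample(
    variants: pd.DataFrame,
    wbc_db: WBCDatabase,
    model: BackgroundErrorModel,
    read_support_alpha: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply both filters (WBC recurrence, then background 3-SD rule).

    The two criteria are disjoint, so the order does not change the
    surviving set; the log records each removal with its rule and value.
    """
    kept, log1 = wbc_artifact_filter(variants, wbc_db)
    kept, log2 = background_denoise(kept, model, read_support_alpha)
    logs = [l for l in (log1, log2) if len(l)] or [log1]
    return kept, pd.concat(logs, ignore_index=True)
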