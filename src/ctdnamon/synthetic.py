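"""Synthetic ctDNA cohort generator with ground-truth progression times.

The generator emulates the statistical structure the downstream analysis
assumes, so every pipeline stage is testable without patient data:

* a healthy-plasma pool (default 50 individuals) reporting per-site
  sequencing-noise allele fractions drawn from a Beta distribution;
* a WBC artifact database (default 400 samples) with a configurable
  fraction of panel sites planted as recurrent artifacts (>10% occurrence);
* longitudinal patient series sampled every two treatment cycles
  (42 days). Tumor fraction follows piecewise-exponential kinetics:
  responders decay as f0*exp(-k*t) until a resistance time t_r, then
  regrow as f(t_r)*exp(g*(t-t_r)); non-responders grow monotonically.
  Observed variant AF is c_i*f(t)/2 + site noise (heterozygous clonal
  variant, diploid background), the observed gene copy ratio is
  1 + f(t)*(CN_g/2 - 1) + noise, and CEA follows an affine link to f with
  lognormal noise.  Emergent variants appear only from t_r onward.

Imaging progression is detected at the first scheduled scan where f
reaches the imaging detection threshold and exceeds baseline by 20%,
encoding the detection lag that gives ctDNA its lead time; the molecular
progression truth applies the sustained-elevation rule to the noiseless
feature series on the sampling grid.  All latent quantities are stored in
a truth record so recovery tests are exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_PANEL_GENES, PanelDefinition, ThresholdConfig, TMB_EFFECTS
from . import io as cio

START_DATE = pd.Timestamp("2020-01-06")
DEPTH = 3000  # nominal ctDNA sequencing depth

_EFFECT_CYCLE = (
    "missense", "missense", "synonymous", "missense", "nonsense",
    "missense", "synonymous", "frameshift_indel", "missense", "splice",
    "missense", "inframe_indel", "synonymous", "missense", "other", "missense",
)
_ALLELE_CYCLE = (("A", "C"), ("C", "T"), ("G", "A"), ("T", "G"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a 40-patient anti-HER2 cohort drawn every two 21-day
    treatment cycles over a ~10-month horizon (8 draws/patient, ~320
    samples), half of whom respond.  ``site_error_shape`` are Beta
    parameters of the per-site noise AF (mean 0.002); ``None`` disables
    noise entirely (every noise draw is exactly 0).
    """

    n_patients: int = 40
    n_healthy_pool: int = 50
    n_wbc_samples: int = 400
    panel_sites: int = 300
    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    sampling_interval_days: int = 42  # two 21-day treatment cycles
    horizon_days: int = 294  # 8 draws counting baseline
    responder_fraction: float = 0.5
    decay_rate: float = 0.03  # per-day tumor-fraction decline on response
    regrowth_rate: float = 0.025  # per-day rise after resistance
    baseline_tumor_fraction: tuple[float, float] = (0.10, 0.40)
    site_error_shape: tuple[float, float] | None = (16.0, 7984.0)
    cnv_noise_sd: float = 0.04
    cea_noise_sd: float = 0.10
    cea_elevated_fraction: float = 0.6  # baseline CEA above 5 ng/mL
    cea_beta: float = 8.0  # affine CEA link: C0 * (1 + beta * f)
    ct_detection_threshold: float = 0.20
    artifact_rate: float = 0.05  # fraction of panel sites planted in WBC db
    artifact_carrier_rate: float = 0.6
    caller_min_af: float = 0.003  # emission limit of the upstream caller
    tissue_fraction: float = 0.45  # patients with matched baseline tissue
    emergent_probability: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.decay_rate, self.regrowth_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.ct_detection_threshold < 1:
            raise ValueError("imaging detection threshold must be in (0, 1)")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in [0, 1]")
        if not self.panel_genes or "ERBB2" not in self.panel_genes:
            raise ValueError("panel_genes must be non-empty and include ERBB2")
        if self.n_healthy_pool < 1 or self.n_wbc_samples < 1:
            raise ValueError("pool sizes must be positive")
        if self.horizon_days < self.sampling_interval_days:
            raise ValueError("horizon shorter than one sampling interval")

    def zero_noise(self) -> "SimulationConfig":
        """Variant of this config with every noise source switched off."""
        return SimulationConfig(
            **{
                **asdict(self),
                "site_error_shape": None,
                "cnv_noise_sd": 0.0,
                "cea_noise_sd": 0.0,
                "caller_min_af": 0.0,
            }
        )

    @property
    def sample_offsets(self) -> np.ndarray:
        """Days of each plasma draw relative to treatment start (BL = 0)."""
        return np.arange(0, self.horizon_days + 1, self.sampling_interval_days)

    def noise_mean_sd(self) -> tuple[float, float]:
        if self.site_error_shape is None:
            return 0.0, 0.0
        a, b = self.site_error_shape
        mean = a / (a + b)
        sd = float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))
        return mean, sd


def panel_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic assayable-site table (chrom, pos, ref, alt, gene, effect).

    Sites are distributed round-robin over the panel genes; the layout
    depends only on the config fields, never on the seed, so the healthy
    pool, WBC database and patient samples share the same coordinates.
    """
    genes = list(config.panel_genes)
    rows = []
    for i in range(config.panel_sites):
        g = i % len(genes)
        ref, alt = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        rows.append(
            {
                "chrom": f"chr{(g % 22) + 1}",
                "pos": 1_000_000 * (g + 1) + 137 * (i // len(genes) + 1),
                "ref": ref,
                "alt": alt,
                "gene": genes[g],
                "effect": _EFFECT_CYCLE[i % len(_EFFECT_CYCLE)],
            }
        )
    df = pd.DataFrame(rows)
    return cio.add_variant_keys(df)


def driver_site_keys(layout: pd.DataFrame) -> list[tuple]:
    """Catalogue of known driver hotspots: first site of TP53/KRAS/PIK3CA."""
    keys = []
    for gene in ("TP53", "KRAS", "PIK3CA"):
        rows = layout[layout["gene"] == gene]
        if len(rows):
            keys.append(rows["key"].iloc[0])
    return keys


def panel_definition_for(config: SimulationConfig) -> PanelDefinition:
    layout = panel_layout(config)
    return PanelDefinition(
        genes=tuple(config.panel_genes),
        coding_footprint_mb=1.2,
        driver_sites=frozenset(driver_site_keys(layout)),
    )


def _noise_draws(config: SimulationConfig, rng: np.random.Generator, size) -> np.ndarray:
    if config.site_error_shape is None:
        return np.zeros(size)
    a, b = config.site_error_shape
    return rng.beta(a, b, size=size)


def generate_background_pool(
    config: SimulationConfig, seed: int | None = None
) -> list[pd.DataFrame]:
    """Healthy-plasma pool: one noise-AF table per healthy individual."""
    if config.n_healthy_pool < 1:
        raise ValueError("healthy pool size must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = panel_layout(config)[cio.VARIANT_COLUMNS[:6]]
    tables = []
    for _ in range(config.n_healthy_pool):
        tab = layout.copy()
        af = _noise_draws(config, rng, len(tab))
        tab["af"] = af
        tab["alt_reads"] = np.round(af * DEPTH).astype(int)
        tab["depth"] = DEPTH
        tables.append(tab)
    return tables


def generate_wbc_database(
    config: SimulationConfig,
    seed: int | None = None,
    planted: dict | None = None,
):
    """WBC occurrence table with planted recurrent artifacts.

    Returns (table, total_samples, artifact keys).  A fraction
    ``artifact_rate`` of panel sites is planted with occurrence fractions
    drawn in (0.12, 0.40) — above the 10% removal cutoff; the remaining
    sites get sporadic counts capped strictly at 10% of the cohort.
    ``planted`` may pin explicit site-key -> occurrence-fraction pairs.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = panel_layout(config)
    total = config.n_wbc_samples
    n_art = int(round(config.artifact_rate * config.panel_sites))
    art_idx = rng.choice(len(layout), size=n_art, replace=False) if n_art else np.array([], int)
    counts = rng.binomial(total, 0.02, size=len(layout))
    counts = np.minimum(counts, int(np.floor(0.10 * total)))  # sporadic sites stay below cutoff
    for i in art_idx:
        counts[i] = int(round(rng.uniform(0.12, 0.40) * total))
    tab = layout[["chrom", "pos", "ref", "alt"]].copy()
    tab["count"] = counts
    artifact_keys = set(layout["key"].iloc[art_idx])
    if planted:
        key_to_row = {k: i for i, k in enumerate(layout["key"])}
        for key, frac in planted.items():
            tab.loc[key_to_row[key], "count"] = int(round(frac * total))
            if frac > 0.10:
                artifact_keys.add(key)
    return tab, total, artifact_keys


def tumor_fraction(
    t: np.ndarray,
    f0: float,
    responder: bool,
    t_r: float | None,
    decay: float,
    regrowth: float,
) -> np.ndarray:
    """Piecewise-exponential tumor-fraction trajectory, capped at 0.95."""
    t = np.asarray(t, dtype=float)
    if responder:
        f = f0 * np.exp(-decay * t)
        if t_r is not None:
            nadir = f0 * np.exp(-decay * t_r)
            late = t >= t_r
            f[late] = nadir * np.exp(regrowth * (t[late] - t_r))
    else:
        f = f0 * np.exp(regrowth * t)
    return np.clip(f, 0.0, 0.95)


def _variant_detected(af_true: float, config: SimulationConfig) -> bool:
    """Noiseless detection rule: caller emission + 3-SD background gate."""
    mean, sd = config.noise_mean_sd()
    af_obs = af_true + mean
    return (
        af_true > 3.0 * sd
        and af_obs >= config.caller_min_af
        and round(af_obs * DEPTH) >= 1
    )


@dataclass
class PatientTruth:
    """Latent ground truth for one simulated patient."""

    patient_id: str
    responder: bool
    f0: float
    decay_rate: float  # realised per-patient rates
    regrowth_rate: float
    t_r: float | None  # resistance time, days (None: none within horizon)
    sample_days: list
    sample_dates: list
    f_trajectory: list
    clonal_variants: list  # dicts with site fields + clonal fraction c
    emergent_variants: list
    gene_copy_numbers: dict
    baseline_cea: float
    tissue_her2: str
    true_features: dict  # noiseless erbb2_fold/tcl/tmb/maxivaf series
    molecular_pd_date: str | None
    radiologic_pd_date: str | None
    best_response: str
    pfs_months: float
    pfs_event: bool


def _true_feature_series(
    config: SimulationConfig,
    f_series: np.ndarray,
    variants: list,
    emergent: list,
    copy_numbers: dict,
    days: np.ndarray,
    t_r: float | None,
    driver_keys: set,
    footprint_mb: float,
) -> dict:
    thr = ThresholdConfig()
    erbb2 = 1.0 + f_series * (copy_numbers["ERBB2"] / 2.0 - 1.0)
    tcl = []
    for f in f_series:
        n = 0
        for cn in copy_numbers.values():
            ratio = 1.0 + f * (cn / 2.0 - 1.0)
            if ratio >= thr.cnv_gain_fold or ratio <= thr.cnv_loss_fold:
                n += 1
        tcl.append(n)
    tmb, maxivaf = [], []
    for day, f in zip(days, f_series):
        present = list(variants)
        if t_r is not None and day >= t_r:
            present += emergent
        count = 0
        best = float("nan")
        for v in present:
            af = v["c"] * f / 2.0
            if _variant_detected(af, config):
                best = af if np.isnan(best) else max(best, af)
                if v["effect"] in TMB_EFFECTS and tuple(v["key"]) not in driver_keys:
                    count += 1
        tmb.append(count / footprint_mb)
        maxivaf.append(best)
    return {
        "erbb2_fold": [float(x) for x in erbb2],
        "tcl": tcl,
        "tmb": tmb,
        "maxivaf": maxivaf,
    }


def _truth_molecular_pd(true_features: dict, dates: list) -> str | None:
    """Sustained-elevation rule on the noiseless series (post-baseline)."""
    thr = ThresholdConfig()
    series = {
        "erbb2_fold": (np.array(true_features["erbb2_fold"]), thr.cnv_gain_fold),
        "tcl": (np.array(true_features["tcl"], dtype=float), thr.tcl_high_cutoff),
        "tmb": (np.array(true_features["tmb"]), thr.tmb_high_cutoff),
    }
    best = None
    for vals, cutoff in series.values():
        above = (vals / cutoff > 1.0)[1:]
        run = 0
        for i, flag in enumerate(above):
            run = run + 1 if flag else 0
            if run >= 2:
                start = i - 1
                if best is None or start < best:
                    best = start
                break
    return None if best is None else dates[best + 1]


def simulate_patient(
    config: SimulationConfig,
    patient_index: int,
    rng: np.random.Generator,
    layout: pd.DataFrame,
    artifact_keys: set,
    driver_keys: set,
    footprint_mb: float = 1.2,
):
    """Simulate one patient; returns (PatientTruth, emitted sample tables).

    Emitted tables carry observed values only (AF with site noise, noisy
    copy ratios, noisy CEA); every latent quantity lives in the truth.
    """
    pid = f"P{patient_index + 1:03d}"
    days = config.sample_offsets
    start = START_DATE + pd.Timedelta(days=3 * patient_index)
    dates = [start + pd.Timedelta(days=int(d)) for d in days]
    date_strs = [d.strftime("%Y-%m-%d") for d in dates]

    f0 = rng.uniform(*config.baseline_tumor_fraction)
    responder = rng.random() < config.responder_fraction
    # resistance time: responders acquire it on therapy; non-responders are
    # resistant from the start (t_r = 0, monotone growth, no emergent clone).
    # Per-patient kinetic heterogeneity: responders clear fast enough to
    # reach a partial response by the first evaluation; non-responder growth
    # spans slow (stable disease first) to fast (progression at first scan).
    t_r = float(rng.uniform(0.15, 0.9) * config.horizon_days) if responder else 0.0
    decay_i = config.decay_rate * float(rng.uniform(1.0, 1.6))
    regrowth_i = config.regrowth_rate * float(rng.uniform(0.3, 1.3))
    f_series = tumor_fraction(days, f0, responder, t_r, decay_i, regrowth_i)

    # --- latent genome ---------------------------------------------------
    candidate = layout[~layout["key"].isin(artifact_keys)]
    n_mut = int(rng.poisson(8) + 2)
    rows = candidate.iloc[rng.choice(len(candidate), size=min(n_mut + 4, len(candidate)), replace=False)]
    clonal, used = [], set()
    for _, site in rows.iterrows():
        if len(clonal) >= n_mut:
            break
        c = 1.0 if not clonal else float(rng.uniform(0.05, 1.0))  # one truncal variant
        clonal.append(
            {
                "key": tuple(site["key"]), "chrom": site["chrom"], "pos": int(site["pos"]),
                "ref": site["ref"], "alt": site["alt"], "gene": site["gene"],
                "effect": site["effect"], "c": c,
            }
        )
        used.add(tuple(site["key"]))

    copy_numbers = {g: 2.0 for g in config.panel_genes}
    if rng.random() < 0.70:  # ERBB2-amplified subgroup
        copy_numbers["ERBB2"] = min(40.0, 2.0 + (0.8 / f0) * rng.uniform(1.2, 2.2))
    for gene in config.panel_genes:
        if gene == "ERBB2":
            continue
        u = rng.random()
        if u < 0.08:  # strong gain, detectable at baseline
            copy_numbers[gene] = min(40.0, 2.0 + (0.8 / f0) * rng.uniform(1.05, 2.0))
        elif u < 0.13:  # weak gain, surfaces only at high tumor fraction
            copy_numbers[gene] = rng.uniform(2.5, 3.5)
        elif u < 0.17:  # homozygous deletion
            copy_numbers[gene] = 0.0

    emergent = []
    emerges = responder and t_r < config.horizon_days
    if emerges and rng.random() < config.emergent_probability:
        pool = candidate[~candidate["key"].isin(used)]
        picks = pool.iloc[rng.choice(len(pool), size=int(rng.integers(1, 4)), replace=False)]
        for _, site in picks.iterrows():
            emergent.append(
                {
                    "key": tuple(site["key"]), "chrom": site["chrom"], "pos": int(site["pos"]),
                    "ref": site["ref"], "alt": site["alt"], "gene": site["gene"],
                    "effect": site["effect"], "c": float(rng.uniform(0.2, 0.8)),
                }
            )

    carries_artifact = {
        k: rng.random() < config.artifact_carrier_rate for k in artifact_keys
    }
    artifact_af = {k: float(rng.uniform(0.01, 0.04)) for k in artifact_keys}

    # baseline CEA placed above/below the 5 ng/mL cutoff per the configured
    # proportion; the affine link C0*(1 + beta*f) is inverted at f0 so the
    # pre-noise baseline concentration lands in the intended range
    link = 1 + config.cea_beta * f0
    if rng.random() < config.cea_elevated_fraction:
        baseline_cea = float(rng.uniform(5.5, 60.0)) / link
    else:
        baseline_cea = float(rng.uniform(0.5, 4.5)) / link

    # --- emitted samples -------------------------------------------------
    samples = []
    layout_by_key = {k: i for i, k in enumerate(layout["key"])}
    for j, (day, f, date) in enumerate(zip(days, f_series, date_strs)):
        recs = []
        present = list(clonal) + (list(emergent) if emerges and day >= t_r else [])
        for v in present:
            af_true = v["c"] * f / 2.0
            if af_true <= 0:
                continue
            af_obs = float(np.clip(af_true + _noise_draws(config, rng, 1)[0], 0, 1))
            alt_reads = int(round(af_obs * DEPTH))
            if af_obs >= config.caller_min_af and alt_reads >= 1:
                recs.append(
                    {
                        "chrom": v["chrom"], "pos": v["pos"], "ref": v["ref"],
                        "alt": v["alt"], "gene": v["gene"], "effect": v["effect"],
                        "af": af_obs, "alt_reads": alt_reads, "depth": DEPTH,
                    }
                )
        for k in sorted(artifact_keys, key=lambda k: layout_by_key[k]):
            if not carries_artifact[k]:
                continue
            site = layout.iloc[layout_by_key[k]]
            af_obs = float(
                np.clip(artifact_af[k] + _noise_draws(config, rng, 1)[0], 0, 1)
            )
            recs.append(
                {
                    "chrom": site["chrom"], "pos": int(site["pos"]), "ref": site["ref"],
                    "alt": site["alt"], "gene": site["gene"], "effect": site["effect"],
                    "af": af_obs, "alt_reads": int(round(af_obs * DEPTH)), "depth": DEPTH,
                }
            )
        if config.site_error_shape is not None:
            noise = _noise_draws(config, rng, len(layout))
            # pure-noise rows never land on this patient's somatic coordinates
            somatic_sites = {v["key"] for v in clonal} | {v["key"] for v in emergent}
            for i_site, af_obs in enumerate(noise):
                site = layout.iloc[i_site]
                if tuple(site["key"]) in somatic_sites:
                    continue
                alt_reads = int(round(af_obs * DEPTH))
                if af_obs >= config.caller_min_af and alt_reads >= 1:
                    recs.append(
                        {
                            "chrom": site["chrom"], "pos": int(site["pos"]),
                            "ref": site["ref"], "alt": site["alt"],
                            "gene": site["gene"], "effect": site["effect"],
                            "af": float(af_obs), "alt_reads": alt_reads, "depth": DEPTH,
                        }
                    )
        variants = pd.DataFrame(recs, columns=cio.VARIANT_COLUMNS)

        folds = {}
        for gene, cn in copy_numbers.items():
            ratio = 1.0 + f * (cn / 2.0 - 1.0)
            if config.cnv_noise_sd > 0:
                ratio += rng.normal(0, config.cnv_noise_sd)
            folds[gene] = max(0.0, float(ratio))

        cea = baseline_cea * (1 + config.cea_beta * f)
        if config.cea_noise_sd > 0:
            cea *= float(np.exp(rng.normal(0, config.cea_noise_sd)))
        anc = max(0.5, rng.normal(4.5, 1.2)) * (1 + 0.5 * f)
        amc = max(0.05, rng.normal(0.5, 0.12)) * (1 + 0.3 * f)
        alc = max(0.5, rng.normal(1.8, 0.4))

        samples.append(
            {
                "sample_id": f"{pid}_T{j}",
                "patient_id": pid,
                "date": date,
                "day": int(day),
                "timepoint": "BL" if j == 0 else ("FP" if j == 1 else f"T{j}"),
                "variants": variants,
                "folds": folds,
                "cea_ng_ml": float(cea),
                "anc": float(anc),
                "amc": float(amc),
                "alc": float(alc),
            }
        )

    # --- truth: responses, progression dates -----------------------------
    # imaging PD needs the tumor fraction both above the imaging detection
    # threshold and 1.7x baseline (a 20% diameter increase, volume-cubed)
    pd_threshold = max(config.ct_detection_threshold, 1.7 * f0)
    radiologic_idx = next(
        (j for j in range(1, len(days)) if f_series[j] >= pd_threshold), None
    )
    for j, s in enumerate(samples):
        if j == 0:
            s["response"] = ""
        elif radiologic_idx is not None and j >= radiologic_idx:
            s["response"] = "PD"
        elif f_series[j] <= 0.3 * f0:
            s["response"] = "PR"
        else:
            s["response"] = "SD"

    post = [s["response"] for s in samples[1:]]
    if "PR" in post:
        best_response = "PR"
    elif "SD" in post:
        best_response = "SD"
    else:
        best_response = "PD"

    if radiologic_idx is not None:
        pfs_days = float(days[radiologic_idx])
        pfs_event = True
        radiologic_pd_date = date_strs[radiologic_idx]
    else:
        pfs_days = float(config.horizon_days)
        pfs_event = False
        radiologic_pd_date = None

    true_features = _true_feature_series(
        config, f_series, clonal, emergent, copy_numbers, days,
        t_r if emerges else None, set(driver_keys), footprint_mb,
    )
    molecular_pd_date = _truth_molecular_pd(true_features, date_strs)

    erbb2_bl = true_features["erbb2_fold"][0]
    if rng.random() < config.tissue_fraction:
        concordant = rng.random() < 0.95
        plasma_amp = erbb2_bl >= ThresholdConfig().cnv_gain_fold
        tissue = plasma_amp if concordant else not plasma_amp
        tissue_her2 = "positive" if tissue else "negative"
    else:
        tissue_her2 = ""

    truth = PatientTruth(
        patient_id=pid,
        responder=responder,
        f0=float(f0),
        decay_rate=decay_i,
        regrowth_rate=regrowth_i,
        t_r=float(t_r),
        sample_days=[int(d) for d in days],
        sample_dates=date_strs,
        f_trajectory=[float(x) for x in f_series],
        clonal_variants=[{**v, "key": list(v["key"])} for v in clonal],
        emergent_variants=[{**v, "key": list(v["key"])} for v in emergent],
        gene_copy_numbers={g: float(c) for g, c in copy_numbers.items()},
        baseline_cea=baseline_cea,
        tissue_her2=tissue_her2,
        true_features=true_features,
        molecular_pd_date=molecular_pd_date,
        radiologic_pd_date=radiologic_pd_date,
        best_response=best_response,
        pfs_months=pfs_days / 30.4375,
        pfs_event=pfs_event,
    )
    return truth, samples


@dataclass
class CohortData:
    config: SimulationConfig
    healthy_pool: list
    wbc_table: pd.DataFrame
    wbc_total: int
    artifact_keys: set
    truths: list
    samples: list  # flattened over patients
    panel: PanelDefinition


def generate_cohort(config: SimulationConfig) -> CohortData:
    """Generate the full synthetic study: pools, database and patients."""
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.n_patients + 2)
    layout = panel_layout(config)
    panel = panel_definition_for(config)
    healthy = generate_background_pool(config, seed=child[0])
    wbc_table, total, artifact_keys = generate_wbc_database(config, seed=child[1])
    truths, all_samples = [], []
    for i in range(config.n_patients):
        rng = np.random.default_rng(child[i + 2])
        truth, samples = simulate_patient(
            config, i, rng, layout, artifact_keys, set(panel.driver_sites),
            footprint_mb=panel.coding_footprint_mb,
        )
        truths.append(truth)
        all_samples.extend(samples)
    return CohortData(
        config=config, healthy_pool=healthy, wbc_table=wbc_table,
        wbc_total=total, artifact_keys=artifact_keys, truths=truths,
        samples=all_samples, panel=panel,
    )


def emit_cohort(cohort: CohortData, out_dir: str | Path) -> dict:
    """Write the cohort to disk in the pipeline's input formats.

    Layout: ``healthy/healthy_###.tsv``, ``wbc_database.tsv``,
    ``variants/<sample_id>.tsv``, ``copy_ratios.tsv``, ``clinical.csv``
    and ``truth.json``.  Returns the path map.
    """
    if not cohort.truths:
        raise ValueError("cannot emit an empty cohort")
    out = Path(out_dir)
    (out / "healthy").mkdir(parents=True, exist_ok=True)
    (out / "variants").mkdir(exist_ok=True)

    for i, tab in enumerate(cohort.healthy_pool):
        cio.write_variant_table(tab, out / "healthy" / f"healthy_{i:03d}.tsv")
    cio.write_wbc_database(cohort.wbc_table, cohort.wbc_total, out / "wbc_database.tsv")

    clin_rows, fold_rows = [], []
    for s in cohort.samples:
        cio.write_variant_table(s["variants"], out / "variants" / f"{s['sample_id']}.tsv")
        for gene, fold in s["folds"].items():
            fold_rows.append({"sample_id": s["sample_id"], "gene": gene, "fold": fold})
        truth = next(t for t in cohort.truths if t.patient_id == s["patient_id"])
        clin_rows.append(
            {
                "patient_id": s["patient_id"], "sample_id": s["sample_id"],
                "date": s["date"], "timepoint": s["timepoint"],
                "response": s["response"], "cea_ng_ml": round(s["cea_ng_ml"], 3),
                "anc": round(s["anc"], 3), "amc": round(s["amc"], 3),
                "alc": round(s["alc"], 3), "tissue_her2": truth.tissue_her2,
            }
        )
    cio.write_copy_ratios(pd.DataFrame(fold_rows), out / "copy_ratios.tsv")
    cio.write_clinical_table(pd.DataFrame(clin_rows), out / "clinical.csv")

    truth_json = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cohort.config).items()
        },
        "patients": [asdict(t) for t in cohort.truths],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    panel_json = {
        "genes": list(cohort.panel.genes),
        "coding_footprint_mb": cohort.panel.coding_footprint_mb,
        "driver_sites": [list(k) for k in sorted(cohort.panel.driver_sites)],
        "driver_hotspots": [list(p) for p in sorted(cohort.panel.driver_hotspots)],
    }
    with open(out / "panel.json", "w") as fh:
        json.dump(panel_json, fh, indent=1)
    return {
        "healthy_dir": out / "healthy",
        "wbc_database": out / "wbc_database.tsv",
        "variants_dir": out / "variants",
        "copy_ratios": out / "copy_ratios.tsv",
        "clinical": out / "clinical.csv",
        "truth": out / "truth.json",
    }
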