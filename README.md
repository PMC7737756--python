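# ctdnamon

Longitudinal plasma ctDNA monitoring analytics for targeted-therapy
cohorts — built for translational researchers who have per-sample somatic
variant calls and gene copy-ratio tables from serial liquid biopsies and
want reproducible denoising, feature tracking, molecular progression
calls and stratified outcome statistics.

## What it computes

**Denoising.** Plasma variant calls are cleaned in two stages: a variant
seen in > 10% of a white-blood-cell artifact database is removed
(clonal hematopoiesis / technical artifacts), and a variant survives only
if its allele fraction AF satisfies

    AF > μ_site + 3·σ_site

where μ and σ are the mean and SD of noise AFs at that site across a
healthy-plasma pool.

**Per-sample features.** TMB (coding substitutions + indels per megabase,
synonymous included, known drivers excluded; high iff ≥ 8.5 mut/Mb), gene
CNV calls (fold ≥ 1.4 gain, ≤ 0.65 loss), TCL (count of gained + lost
genes; high iff ≥ 2), ERBB2 amplification status, MaxiVAF (maximum
surviving AF, a tumor-fraction proxy) and NLR/MLR blood ratios.

**Progression monitoring.** Each feature series is normalized to its
cutoff; a feature strictly above cutoff at two consecutive post-baseline
draws marks ctDNA-based progression at the first point of the run. The
same rule on CEA/(5 ng/mL) gives CEA-based progression. Lead time is the
day count by which a molecular call precedes imaging-based progression.

**Cohort outcomes.** ORR/DCR with counts, Kaplan–Meier PFS with log-rank
contrasts, baseline ERBB2 × TMB strata, first-point dynamics categories
(dn/up/remainL/remainH), plasma-vs-tissue HER2 concordance (percent
agreement + Cohen's kappa) and feature–CEA Spearman correlation.

**Synthetic cohorts.** A generator produces healthy pools, WBC databases
and longitudinal patient series with piecewise-exponential tumor-fraction
kinetics and full ground truth, so the entire pipeline is testable
without patient data. See `docs/methods.md` for the model.

## Worked example

```bash
ctdnamon simulate --out cohort --seed 1          # 40 patients, 320 samples
ctdnamon run --input-dir cohort --out report
cat report/summary.txt
```

which prints (seed 1):

```
ctDNA monitoring cohort report
==============================
patients: 40  plasma samples: 320
cohort ORR 55.0% (22/40), DCR 67.5% (27/40)
ctDNA PD ahead of imaging in 10/23 (43.5%), mean advancement 96.6 days
plasma/tissue HER2 agreement 94.4% (kappa 0.88, n=18)
```

Reading: 22 of 40 simulated patients reached a partial response (ORR);
among the 23 patients with both a molecular and an imaging progression
date, the ctDNA call came strictly earlier in 10, by 96.6 days on
average; and of the 18 patients with matched baseline tissue, plasma
ERBB2 copy-ratio status agreed with tissue HER2 in 17. `report/` also
holds `features.tsv` (per-sample features), `progression_calls.tsv`
(per-patient ctDNA/CEA/CT calls with lead days), `removal_log.tsv`
(every filtered variant with its rule and value) and `outcomes.json`
(stratified ORR/DCR/median-PFS, concordance, correlations).

The same steps are available as library calls:

```python
from ctdnamon import SimulationConfig, generate_cohort, emit_cohort, run_pipeline

cohort = generate_cohort(SimulationConfig(seed=1))
emit_cohort(cohort, "cohort")
report = run_pipeline("cohort", "report")
```

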