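# Methods

`ctdnamon` implements the analytical core of longitudinal plasma ctDNA
monitoring for targeted-therapy cohorts: somatic variant denoising,
per-sample genomic feature extraction, molecular progression calling, and
stratified outcome analysis, together with a synthetic-cohort generator
that makes every stage testable against known ground truth.

## Variant denoising

Plasma variant calls are cleaned in two stages, both allele-specific on
the site key (chrom, pos, ref, alt):

1. **WBC recurrence filter.** A variant present in strictly more than 10%
   of the white-blood-cell database samples is removed as a likely
   clonal-hematopoiesis or technical artifact. The boundary is strict:
   occurrence 40/400 (exactly 10%) is retained, 41/400 removed.
2. **Background error model.** For every panel site, the healthy-plasma
   pool yields a mean and standard deviation of noise allele fractions.
   A variant is retained only when its AF strictly exceeds
   `mean + 3·SD` at its site. SDs use the sample convention (n−1);
   healthy individuals with no call at a site are imputed as AF 0, so
   every site's statistics cover the full pool. Sites absent from the
   pool fall back to statistics pooled over all site-observations — the
   per-site versus pooled behaviour at unseen sites is a documented
   choice, recorded on the model object.

The two criteria are disjoint, so filter order does not affect the
surviving set (property-tested). An optional one-sided binomial-tail check
of supporting reads against the site's mean error rate is available but
off by default: the retention criterion that is unambiguous is the AF
rule, and the read-support variant is exposed as an option rather than
guessed at.

## Per-sample features

* **TMB** (mut/Mb): coding substitutions and indels — missense, nonsense,
  synonymous, frameshift and in-frame indels — divided by the panel's
  coding footprint. Synonymous variants are counted deliberately: they
  damp sampling noise in small-panel TMB. Splice and "other" effects are
  excluded by default (flag to include). Variants matching the driver
  catalogue (site keys or gene/protein-change hotspots) are excluded.
  The coding footprint defaults to 1.2 Mb for a 425-gene panel and must
  be set explicitly for any real panel; TMB is undefined without it.
* **Gene CNV**: fold ≥ 1.4 is a gain, ≤ 0.65 a loss, both inclusive;
  the inclusive reading treats the stated cutoff as the first value
  inside the class, consistent with the explicitly inclusive TMB/TCL
  cutoffs.
* **TCL**: count of genes called gain or loss (gene-level counting).
* **ERBB2 status**: amplified iff the ERBB2 fold reaches the gain cutoff.
* **MaxiVAF**: maximum surviving-variant AF, a tumor-fraction proxy;
  undefined (NaN) when nothing survives denoising.
* **NLR/MLR**: neutrophil or monocyte count over lymphocyte count.

Fixed cutoffs (TMB 8.5 mut/Mb, TCL 2) are the primary classification
mode; a cohort-tertile mode (top 33.3% = high, cutoff = the smallest
value inside the top third) is provided as the secondary derivation.

## Progression monitoring

Feature series are normalized to relative folds of their cutoffs
(ERBB2/1.4, TCL/2, TMB/8.5), so ratio > 1 means above cutoff. Scanning
post-baseline samples in date order, any feature strictly above its
cutoff at **two consecutive** time points marks molecular progression;
the first point of the earliest qualifying run is the ctDNA-PD date.
Decisions embedded here:

* *Strictness*: "elevated beyond the cutoff" is ratio > 1 strictly, even
  though static classification at exactly the cutoff is "high". The
  distinction is pinned by tests.
* *Consecutiveness*: sustained progression requires consecutive
  qualifying points; a non-consecutive interpretation is available via
  `consecutive=False` for sensitivity analysis.
* *Baseline*: BL can never be the PD point — progression is a change on
  therapy — so runs are evaluated from the first post-baseline draw.
  A patient elevated continuously from baseline is called at the first
  post-baseline point.
* *Ties*: the earliest run wins; same-date ties break by the fixed order
  ERBB2-CNV, TCL, TMB.
* Patients with fewer than three samples are excluded from monitoring
  with a logged reason; duplicate sample dates invalidate the timeline
  (tables are date-sorted on ingest, so ordering itself is normalized).

CEA-based PD applies the same rule to CEA/(5 ng/mL); the log2 of that
ratio is emitted for trajectory display. Lead time is the integer day
difference `ct_pd_date − molecular_pd_date`; a patient counts as "ahead"
only for strictly positive lead, and the cohort mean advancement averages
ahead patients only. Emerging alterations are the set difference of
denoised variant keys between a progression sample and baseline; the
cohort-level count of patients with emerging clones applies an AF ≥ 1%
floor so residual background leakage is not mistaken for a new clone.

## Outcome analysis

ORR = (CR+PR)/n and DCR = (CR+PR+SD)/n as percentages with their counts
(CR is accepted though typical anti-HER2 gastric cohorts have none).
Survival uses the Kaplan–Meier product-limit estimator with right
censoring (lifelines); the median is the earliest time with S(t) ≤ 0.5
and is reported as undefined when never reached. Group contrasts use the
two-sample log-rank test; multi-level strata reduce to pairwise tests.
Plasma/tissue HER2 agreement is percent agreement plus unweighted
Cohen's kappa on the 2×2 table, with significance from the large-sample
variance approximation; degenerate margins leave kappa undefined.
Feature–CEA association is Spearman rank correlation.

Baseline strata combine ERBB2 amplification and TMB class into four
labels; first-point dynamics per feature are the four categories
dn (high→low), up (low→high), remainL, remainH, determined solely by the
BL and FP classes.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes. Default
configuration (all configurable):

| parameter | default | meaning |
|---|---|---|
| n_patients | 40 | cohort size |
| sampling_interval_days | 42 | plasma draw every two 21-day cycles |
| horizon_days | 294 | 8 draws including baseline (~320 samples) |
| n_healthy_pool | 50 | healthy-plasma background pool |
| n_wbc_samples | 400 | WBC artifact database size |
| responder_fraction | 0.5 | probability of response (cohort ORR target) |
| baseline_tumor_fraction | U(0.10, 0.40) | f0 |
| decay_rate | 0.03/day | on-response decline (×U(1.0, 1.6) per patient) |
| regrowth_rate | 0.025/day | post-resistance rise (×U(0.3, 1.3) per patient) |
| site_error_shape | Beta(16, 7984) | per-site noise AF, mean 0.002, SD 5·10⁻⁴ |
| ct_detection_threshold | 0.20 | imaging detection floor on f |
| artifact_rate | 0.05 | panel sites planted as recurrent WBC artifacts |
| caller_min_af | 0.003 | upstream caller emission limit |

Tumor fraction follows the simplest monotone-by-phase kinetic: responders
decay exponentially until a resistance time t_r ~ U(0.15, 0.9)·horizon,
then regrow exponentially; non-responders grow from the start (t_r = 0).
Responder decay multipliers guarantee a partial response by the first
evaluation, so cohort ORR converges to `responder_fraction`; growth-rate
heterogeneity lets slow growers pass through SD before PD, giving
DCR > ORR.

Observed quantities: variant AF = c·f/2 + Beta site noise (heterozygous
clonal variant, diploid background, clonal fraction c), copy ratio =
1 + f·(CN/2 − 1) + Gaussian noise, CEA = C0·(1 + 8f)·lognormal noise with
C0 placed so that 60% of patients start above 5 ng/mL. Emergent variants
(probability 0.4 per resistant responder, 1–3 sites) have AF exactly 0
before t_r. Planted WBC artifacts appear in patient samples at AF
0.01–0.04 independent of tumor fraction, as clonal hematopoiesis does.
Imaging PD is the first scheduled scan where f exceeds both the detection
threshold and 1.7× baseline (a 20% RECIST diameter increase, cubed to
volume/fraction scale) — the scan-grid quantization encodes the detection
lag that gives ctDNA its lead time. The truth record stores every latent
quantity (trajectory, clonal fractions, copy numbers, noiseless feature
series, molecular and radiologic PD dates), and the latent molecular PD
applies the same sustained-elevation rule to the noiseless series, so
noise-free recovery tests are exact.

What the generator does **not** emulate: read-level error profiles (UMI
structure, strand bias, fragment-length signal), clonal phylogenies,
inter-lesion heterogeneity, pharmacokinetics, or informative censoring.
Passing recovery tests therefore demonstrate the correctness of the
decision rules under the stated statistical model, not clinical
performance on real plasma data.

## Numerical choices and degenerate inputs

* Strict inequalities at the WBC 10% and 3-SD thresholds; inclusive
  boundaries for the static CNV/TMB/TCL classes.
* Single-sample healthy pools give SD 0 at every site, so the retention
  threshold degenerates to "AF above the pool mean"; empty pools are
  rejected.
* Samples with no surviving variants report TMB 0 and undefined MaxiVAF.
* KM medians never reached, kappa under degenerate margins and Spearman
  on constant series are all reported as undefined rather than coerced.
* Seeds: all randomness flows from one integer through
  `numpy.random.SeedSequence` spawns (one child per patient), so cohorts
  are reproducible byte-for-byte and patients are independently seeded.

## Known limitations

* Panel TMB near its cutoff is noise-sensitive: with a 3-SD gate on
  Beta-distributed noise, roughly one background site per sample leaks
  through, adding ~0.8 mut/Mb. Patients whose latent TMB sits just below
  8.5 mut/Mb can therefore trigger early TMB-based progression calls;
  across seeds, the fraction of progressors recovered within one sampling
  interval ranges roughly 83–96% at the default noise level.
* The problem sizes used in the test suite (6–40 patients, 60–300 panel
  sites, pools of 8–50) were chosen to exercise every code path at
  interactive runtimes; the generator scales linearly in patients × sites.
* Log-rank is implemented for two groups; four-curve displays reduce to
  pairwise contrasts.
* PFS censoring is plain right-censoring at the last observed draw;
  lost-to-follow-up conventions of any particular study cannot be
  recovered from summary statistics.
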