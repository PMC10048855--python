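# telotrack

A tested, reusable implementation of the computational chain behind
multi-cohort child telomere studies: relative leukocyte telomere length
(TL) from qPCR, parent-reported sedentary-behaviour (SB) exposures, a
rank-based telomere-tracking statistic between two follow-up ages, and a
robust-regression association ladder with percent-change reporting — all
exercised end to end on a synthetic cohort generator with known ground
truth, so every stage is verifiable without any external data.

It is aimed at epidemiologists and lab bioinformaticians who need (a) a
transparent CNRQ pipeline for qPCR T/S ratios, (b) a principled way to
compare telomere dynamics across cohorts measured with different assay
chemistries, and (c) a simulation harness to check that an analysis
pipeline actually recovers effects of the size it reports.

## The models at the core

**Quantification.** TL is a calibrated normalised relative quantity
(CNRQ). Per target (telomere T, single-copy gene S), with amplification
efficiency E from a dilution standard curve (E = 10^(−1/slope)):

    RQ   = E^(ref Cq − mean Cq)          (ref = per-cohort sample mean Cq)
    NRQ  = RQ_T / RQ_S                   (the T/S ratio)
    CNRQ = NRQ / CF_run                  (inter-run calibration)

where CF_run is the geometric mean, over the inter-run calibrators (IRCs)
re-measured on every run, of each IRC's NRQ relative to its across-run
geometric mean. Reliability is summarised by one-way random-effects ICCs
of triplicates and of IRC CNRQs across runs.

**Exposure.** Daily SB hours = ((weekday × 5) + (weekend × 2)) / 7 for
screen time and other sedentary activities, summed into total SB, each cut
into tertiles at the empirical 1/3 and 2/3 quantiles.

**Tracking.** Within cohort, TL is ranked longest (1) to shortest (n) at
each age; the tracking statistic is ΔR = (R₁ − R₂)/(n − 1) × 100
percentage points, negative = decline in ranking. It is invariant to
monotone transforms of TL, hence comparable across assay chemistries.

**Association.** Huber M-estimation (≈95% Gaussian efficiency) of
log₁₀(TL) (cross-sectional; β reported as (10^β − 1)×100 percent change)
and of ΔR (reported in points), exposure tertiles vs the lowest, over a
nested covariate ladder M1–M4, with p < 0.2 bivariate screening plus 10%
change-in-estimate covariate selection, fixed-effect I² heterogeneity
across cohorts, descriptive tables and a sensitivity suite.

See `docs/methods.md` for assumptions, defaults, numerical choices and
limitations.

## Worked example

Simulate a three-cohort study (300 children per cohort; the generator
plants a −4% TL deficit at age 4 and a −2-point tracking shift for the
highest screen-time tertile, plus an ultra-processed-food confounder) and
run the full chain — plates → CNRQ → tertiles → ranks → models:

```python
from telotrack import SimConfig, run_study

cfg = SimConfig(seed=42, n_per_cohort=300)
res = run_study(cfg, models=("M1", "M3"), tracking_models=("M1", "M4"))
print(res.estimates[["outcome", "model", "term", "pct_change",
                     "ci_low", "ci_high", "p_value", "n"]].round(2))
```

```
 outcome model          term  pct_change  ci_low  ci_high  p_value   n
log10_TL    M1 screen:middle       -2.86   -6.97     1.43     0.19 900
log10_TL    M1   screen:high       -6.50  -10.45    -2.37     0.00 900
log10_TL    M3 screen:middle       -2.61   -6.70     1.66     0.23 900
log10_TL    M3   screen:high       -5.34   -9.34    -1.15     0.01 900
 delta_R    M1 screen:middle        1.05   -2.72     4.82     0.59 756
 delta_R    M1   screen:high       -3.41   -7.18     0.36     0.08 756
 delta_R    M4 screen:middle        0.08   -3.48     3.64     0.97 756
 delta_R    M4   screen:high       -4.38   -7.96    -0.79     0.02 756
```

Reading the output: children in the highest screen-time tertile show a
5.3% shorter TL at age 4 after full adjustment (M1 is larger, −6.5%,
because the planted ultra-processed-food confounder is uncontrolled
there), and a 3–4-point decline in telomere ranking between the ages —
single-replicate draws around the planted −4% and −2 under this seed; the
acceptance script averages replicates to show calibration. QC from the
same run: Spearman tracking correlation 0.72, triplicate T/S ICC 0.86,
estimated T-assay efficiency 108% (true value 107%).

The same stages are available from the shell:

```bash
telotrack simulate --out study/ --seed 42
telotrack quantify --plates study/plates.csv --out study/
telotrack exposures --sb study/sb.csv --out study/
telotrack associate --data study/ --model M1 --model M3 --out study/results/
```

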