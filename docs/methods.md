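# Methods

`telotrack` implements the computational chain of a multi-cohort child
telomere study: relative telomere length (TL) from qPCR, sedentary-behaviour
(SB) exposures, a rank-based tracking statistic between two ages, and a
robust-regression association ladder. A synthetic cohort generator with
known ground truth drives all validation; this note records the models, the
defaults and why, the numerical choices, and what the simulations do and do
not establish.

## Relative quantification (CNRQ)

TL is expressed as a T/S ratio: the telomere-repeat signal (T) over a
single-copy gene signal (S), each measured in triplicate qPCR wells. The
chain per cohort:

1. **Efficiency.** Each target's amplification factor per cycle, `E`, is
   estimated from a serial dilution standard curve by least squares of mean
   Cq on log10 relative quantity: `E = 10^(-1/slope)`. Perfect doubling
   gives slope −3.3219 and 100% efficiency. Estimated efficiencies are
   applied in quantification by default; fixed values can be supplied
   instead (`quantify_cohort(efficiencies={"T": ..., "S": ...})`).
2. **Replicates.** Triplicate Cq values are combined by arithmetic mean. No
   automatic outlier rejection is performed; a replicate spread above 0.5
   cycles or fewer than 2 replicates raises a non-blocking QC flag.
3. **RQ.** `RQ = E^(refCq − meanCq)` with the reference taken as the
   arithmetic mean Cq over all analysed study samples of that target in the
   cohort. Using the sample mean rather than a designated calibrator sample
   avoids inflating every quantity's error with one sample's measurement
   error.
4. **NRQ.** `NRQ = RQ_T / RQ_S`. Per-sample DNA input cancels here.
5. **Inter-run calibration.** Samples span several runs; each run carries
   the same physical inter-run calibrator (IRC) aliquots (8 by default).
   The per-run correction factor is the geometric mean over IRCs of that
   run's IRC NRQ divided by the IRC's across-run geometric mean, and
   `CNRQ = NRQ / CF_run`. By construction the CFs multiply to 1 across
   runs. An IRC missing from any run is excluded (flagged); at least two
   complete IRCs must remain. With balanced runs (equal sample counts) an
   additive per-run Cq shift leaves every CNRQ exactly unchanged; with
   unbalanced runs the invariance holds up to one global scale factor,
   which is irrelevant in the (arbitrary) T/S units.
6. **Batches.** Each cohort — and each assay wave within a cohort, such as
   the two study ages — is normalised as its own experiment; cohorts are
   never mixed, which also absorbs between-cohort differences in extraction
   kits or primer chemistry because only within-cohort order is used
   downstream.

**Reliability.** Intraclass correlation coefficients use the one-way
random-effects, single-measurement, absolute-agreement model computed from
ANOVA mean squares, with the unbalanced-design average group size `k0`, an
exact F-distribution 95% CI and an F-test p-value. Zero within-subject
variance returns ICC = 1; absent between-subject variance can produce a
negative ICC, reported as computed. Intra-assay ICCs are computed on
replicate-level T, S and per-replicate T/S relative quantities (subjects =
samples); the inter-assay ICC uses IRC CNRQs across runs (subjects = IRC
aliquots).

## Exposures

Parent-reported weekday/weekend hours for screen time and other sedentary
activities are combined as `((wd × 5) + (we × 2)) / 7`; total SB is the sum
of the two daily means. Each variable is categorised into tertiles at the
empirical 1/3 and 2/3 quantiles of the analysis sample, using
linear-interpolation sample quantiles; values equal to a cut-point go to
the lower category. Both conventions matter with coarse questionnaire data
(hours are reported to 0.1 h), so cut-points, quantile method and group
sizes are always reported; heavy ties legitimately produce unequal tertile
sizes. Tertiles are cut once, on the baseline analysis sample where SB was
measured; the tracking analysis inherits those labels rather than
re-cutting on the follow-up subset, so a child's exposure category does
not depend on later drop-out (and the reported cut-point ranges are the
same for both outcomes, while group sizes differ).

## Rank tracking

Within cohort, TL is ranked from longest (1) to shortest (n) at each age,
ties averaged. The tracking statistic is

    delta_R = (R1 − R2) / (n − 1) × 100,

negative when a child declines in the cohort's ranking. Tie-averaged ranks
make the cohort mean exactly zero over a complete paired ranking (the exact
identity is on rank sums; the scaled statistic carries ~1e−13 of float
rounding), and the statistic is invariant to any strictly monotone
transform of TL — the property that makes cross-assay comparison sound. By
default both rankings use the children measured at both ages, which
preserves the zero-mean identity; `rank_on_full_baseline=True` ranks
baseline on everyone with a baseline TL instead (each ranking is then
rescaled to [0, 1]). The pooled Spearman correlation between the two
rankings is reported as a tracking QC statistic.

## Association ladder

Cross-sectional: log10(TL) at the first age, so a coefficient β converts to
percent change by `(10^β − 1) × 100`. Longitudinal: delta_R, reported
directly in percentage points. Exposure tertiles enter as a factor with
the low tertile as reference. The ladder: M1 = blood storage date +
cohort; M2 = M1 + energy intake + ultra-processed food (UPF) intake + age;
M3 = M2 + sex; M4 (tracking only) = M3 + follow-up time + baseline TL.

Fits are M-estimates with the Huber loss at the conventional tuning
(c = 1.345, ≈95% efficiency under Gaussian errors), iteratively
reweighted, MAD scale, with asymptotic Wald standard errors and
normal-approximation 95% CIs — no small-sample correction, as the target
sample sizes are in the hundreds. Complete-case per model with the n used
reported on every estimate; fits are refused when n < parameters + 10 or
the design is rank-deficient. No multiple-testing adjustment is applied.

**Covariate selection.** Stage 1 keeps candidates with p < 0.2 in a
univariable regression against the outcome (an OLS fit; its model F-test
also covers categorical candidates). Stage 2 is a change-in-estimate
backward elimination on the robust exposure model — repeatedly dropping the
covariate whose removal changes the high-vs-low exposure coefficient least,
while that relative change is below 10% — with a forward re-check that
re-admits dropped candidates moving the coefficient by ≥ 10%. Every
decision is recorded in an audit trail. Near-zero reference coefficients
make the relative change unstable; the denominator is floored at 1e−12,
which under a null simply retains covariates (harmless for confounding
control).

**Heterogeneity.** Cohort-specific fits (cohort term removed) are pooled
by inverse-variance fixed effect; Cochran's Q and `I² = max(0, (Q − df)/Q)`
are reported, and I² < 50% sets a flag recommending a pooled analysis with
a cohort covariate — the design actually used by the main models.

**Descriptives.** Continuous variables are routed by a Lilliefors
(KS-type, estimated parameters) normality check: mean (SD) with one-way
ANOVA when normal, median (IQR) with Kruskal–Wallis otherwise; categorical
variables get counts (%) and a chi-square test; constant variables are
skipped with a flag.

**Sensitivity suite.** Re-fits of the main model adding other-SB tertiles,
diet score, BMI, season, extracurricular physical activity, or the
maternal block (periconceptional BMI, smoking, education); boys-only /
girls-only subsets; excluding preterm children; and an exposure-by-sex
interaction tested by a joint Wald test. Subgroups under 50 observations
are skipped with a flag.

## Synthetic cohort generator

The generator emulates a three-cohort study of 500 children per cohort with
follow-up for 80% of them.

* **TL model.** Baseline TL is lognormal (µ = 0, σ = 0.25 on the natural
  log scale; T/S units are arbitrary) — a skew-positive biomarker.
  Attrition to the second age is multiplicative and lognormal (mean 0.9,
  SD 0.15). The top screen-time tertile carries a −4% baseline deficit
  (middle: −2%), the default planted cross-sectional effect.
* **Confounding.** UPF intake rises by 80 g/day from the low to the high
  screen tertile (SD 180 g within tertile) and independently shortens TL
  by 2% per 100 g/day; energy intake shares the gradient and correlates
  with UPF (r = 0.3) but has no TL effect of its own — giving the
  selection procedure a true confounder to keep and a correlated decoy to
  drop. Extracurricular activity carries a small gradient with no TL
  effect.
* **Rank effect calibration.** The planted tracking contrast (default −2
  points, high vs low) is realised as an extra multiplicative attrition for
  the exposed tertiles. Because the statistic lives in rank space, the
  required log-scale shift follows from the expected percentile of a
  normal draw inside an equal-variance normal mixture,
  `E[F(X_g)] = (1/3) Σ_h Φ((µ_g − µ_h)/(s√2))`: the expected group
  tracking mean is 100 × (percentile at the second age − percentile at the
  first), and the shift is solved by root finding so that the high-vs-low
  contrast equals the requested value. The calculation includes the
  baseline-effect carryover (a −4% group is ranked low at both ages, which
  partially cancels), the UPF path, and the qPCR measurement noise
  (triplicate-mean Cq noise through both targets plus the IRC correction
  error), all of which would otherwise bias the planted value by a few
  tenths of a point. A second calibration stage then adjusts for the
  estimator itself: the bounded-influence Huber fit trims the group tails
  of the tracking statistic, which carry genuine signal (under a log-scale
  shift, children in the middle of the pack move many ranks while children
  at the extremes move few, skewing the within-group law), leaving the
  robust functional about a tenth of a point shy of the mean contrast. A
  deterministic pilot simulation — fixed internal RNG stream, condensed
  Gaussian measurement model, the study's ranking-within-cohort geometry,
  cached per configuration — measures this residual and the shift is
  re-solved against it. The parameter is therefore defined as the expected
  high-vs-low contrast *as estimated by the study's robust regression on
  measured data*, which is the quantity the recovery checks compare
  against.
* **qPCR model.** `Cq = base − ln(q)/ln(E) + run shift + replicate noise`,
  with E = 2.07 (T) and 2.00 (S), replicate noise SD 0.15 cycles, per-(run,
  target) shifts SD 0.3 cycles, lognormal per-sample DNA input (σ = 0.3,
  cancelling in T/S), runs of 100 samples, 8 IRC aliquots re-measured on
  every run, and a 6-point 2-fold dilution series per run and target.
  Fluorescence curves and Cq calling are not simulated; Cq values are
  drawn directly.
* **Covariates** follow plausible questionnaire/anthropometric
  distributions (ages ≈ 4.4 and 8.5 y, BMI median 16, maternal age ≈ 37,
  24% smoking, 40/40/20 education split, 4.5% preterm, storage dates over
  ~3 years with season derived from the date). SB hours are gamma
  distributed, rounded to 0.1 h — which produces ties and hence unequal
  tertile sizes, as real questionnaires do.
* **Streams.** Each output table has its own RNG stream derived from the
  master seed, so adding a table never shifts existing draws; a fixed seed
  reproduces byte-identical CSVs.

**What the generator does not emulate:** selection into follow-up related
to exposure or TL (drop-out is completely at random), DNA-extraction batch
effects beyond per-cohort normalisation, item-level questionnaire error
that is differential by outcome, and non-multiplicative attrition. Passing
recovery tests therefore shows the pipeline is correct and calibrated
under these stated conditions, not that any real-world estimate is
unbiased.

## Validation design and problem sizes

* Exact oracles: single-plate CNRQ against the classic `2^(−ΔΔCq)` (to
  1e−12), correction-factor geometric mean 1 (1e−12), run-shift invariance
  (1e−9), dilution slope/efficiency closed forms (1e−6), ICC degenerate
  limits (1e−9), tracking-statistic arithmetic (exact), percent-change and
  I² worked examples.
* Recovery: 100 replicate studies at 3 × 500 children through the full
  measurement chain; mean recovered effects must land within 2 simulation
  SEs of the planted −4% (cross-sectional, M3) and −2 points (tracking,
  M1), and the UPF confounder must be retained in every replicate.
* Null calibration: 200 replicate studies with all effects zero; the
  empirical type-I error of the high-vs-low Wald test must lie in
  [0.02, 0.08].

Replicate counts and cohort sizes were chosen so the simulation SE is small
against the planted effects while the whole suite stays comfortably
desk-runnable; `scripts/acceptance.py` reuses the same machinery at 20
recovery and 100 null replicates for a quicker end-to-end reproduction.

## Known limitations

* The CNRQ run-shift invariance is exact only for balanced runs; the final
  partial run of an unbalanced batch converts a run shift into a global
  scale factor (harmless downstream, where only within-cohort order and
  log-scale contrasts are used).
* The rank-effect calibration is closed-form under normal mixtures; strong
  departures (heavy-tailed attrition, massive tertile imbalance from ties)
  would bias the planted contrast by more than the ~0.1-point accuracy the
  recovery test demonstrates.
* Huber M-estimation protects against outlying responses, not high-leverage
  design points; the simulated covariates are well-behaved, so this
  distinction is untested here.
* The bivariate screening stage uses OLS p-values even though final models
  are robust fits; with p < 0.2 as the gate this is inconsequential in the
  simulated regimes.
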