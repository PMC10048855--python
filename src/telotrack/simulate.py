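"""Synthetic multi-cohort generator with known ground truth.

Produces (i) a truth table of per-child true telomere lengths (T/S ratio
units) at ages 4 and 8, (ii) a cohort covariate table, (iii) a sedentary
behaviour questionnaire table, and (iv) raw qPCR plate data (triplicate Cq
wells with inter-run calibrators and a serial dilution series per run), so
every downstream stage of the pipeline can be tested against known effects.

Effect placement
----------------
Baseline TL is lognormal. Children in the top screen-time tertile get a
fractional TL deficit at age 4 (``effect_tl4_high_screen``, half of it for
the middle tertile); UPF intake is drawn with a gradient across tertiles and
independently shortens TL, planting a genuine confounder. TL at age 8 is
TL4 times a lognormal attrition factor plus an exposure-dependent attrition
shift calibrated (see :func:`rank_attrition_shift`) so that the expected
high-vs-low contrast in the rank-tracking statistic equals
``effect_rank_high_screen`` percentage points under the full measurement
model.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .config import SimConfig, TERTILE_WEIGHT
from .exposure import assign_tertiles, daily_mean

SEASONS = np.array(["winter", "spring", "summer", "autumn"])


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # one independent stream per output table, all derived from the master seed
    return np.random.default_rng([stream, config.seed])


def _gamma_hours(rng, mean, sd, size):
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    h = rng.gamma(shape, scale, size)
    return np.clip(np.round(h, 1), 0.0, 24.0)  # questionnaire granularity 0.1 h


# ---------------------------------------------------------------------------
# calibration of the attrition shift behind the planted rank effect
# ---------------------------------------------------------------------------

def _measurement_ln_sigma(config: SimConfig, n_samples: int) -> float:
    """Approximate sd of the measurement error on ln(CNRQ).

    Triplicate-mean Cq noise propagates through both targets
    (sd ``ln(E) * cq_noise_sd / sqrt(3)`` each, independent), and the
    inter-run correction factor contributes its own error, averaged over
    ``n_irc`` calibrators and shrunk by the across-run centring.
    """
    assay_var = (math.log(config.efficiency_T) ** 2 +
                 math.log(config.efficiency_S) ** 2) * config.cq_noise_sd ** 2 / config.n_replicates
    n_runs = max(1, math.ceil(n_samples / config.samples_per_run))
    cf_var = assay_var / config.n_irc * (1.0 - 1.0 / n_runs)
    return math.sqrt(assay_var + cf_var)


def expected_rank_contrast(config: SimConfig, delta_a: float) -> float:
    """Expected high-vs-low contrast (percentage points) in the tracking
    statistic when the extra ln-attrition of the top tertile is ``delta_a``.

    Uses the closed form for the expected percentile of a normal draw within
    an equal-variance three-component normal mixture:
    ``E[F(X_g)] = (1/3) * sum_h Phi((mu_g - mu_h) / (s * sqrt(2)))``.
    The tracking statistic of a child is, up to O(1/n), 100 times the change
    in TL percentile between the two ages, so group contrasts follow from
    the per-tertile percentile means at each age.
    """
    d4 = math.log1p(config.effect_tl4_high_screen)
    du = config.upf_ln_effect_per_g
    m = np.array([0.0, 0.5, 1.0])  # low, middle, high
    mu4 = d4 * m + du * config.upf_gradient * m
    s4_true = math.sqrt(config.tl4_lognormal_sigma ** 2 +
                        (du * config.upf_sd) ** 2)
    s8_true = math.sqrt(s4_true ** 2 + config.ln_attrition_sigma ** 2)

    n4 = len(config.cohorts) * config.n_per_cohort
    n8 = int(n4 * config.followup_rate)
    s4 = math.sqrt(s4_true ** 2 + _measurement_ln_sigma(config, n4) ** 2)
    s8 = math.sqrt(s8_true ** 2 + _measurement_ln_sigma(config, n8) ** 2)
    mu8 = mu4 + delta_a * m

    def pct(mu, s):
        diff = mu[:, None] - mu[None, :]
        return norm.cdf(diff / (s * math.sqrt(2.0))).mean(axis=1)

    p4, p8 = pct(mu4, s4), pct(mu8, s8)
    dr = 100.0 * (p8 - p4)
    return float(dr[2] - dr[0])


def _solve_closed_form(config: SimConfig, target: float) -> float:
    return brentq(lambda d: expected_rank_contrast(config, d) - target,
                  -3.0, 3.0, xtol=1e-10)


def _mc_robust_contrast(config: SimConfig, delta_a: float,
                        reps: int = 1500) -> float:
    """Monte-Carlo expectation of the Huber-regression high-vs-low contrast
    of the measured tracking statistic under the generating model.

    Mirrors the study geometry — ranking within cohorts of the paired-sample
    size, pooled fit with cohort dummies — with a condensed measurement
    model (Gaussian ln-scale noise of the size implied by the qPCR
    parameters). A fixed internal bit stream makes the calibration a
    deterministic function of the configuration.
    """
    import statsmodels.api as sm
    from scipy.stats import rankdata

    rng = np.random.default_rng(987654321)
    d4 = math.log1p(config.effect_tl4_high_screen)
    du = config.upf_ln_effect_per_g
    n_coh = len(config.cohorts)
    n_block = max(50, int(round(config.n_per_cohort * config.followup_rate)))
    n = n_coh * n_block
    sm_noise = _measurement_ln_sigma(config, n_block)
    coh = np.repeat(np.arange(n_coh), n_block)
    betas = np.empty(reps)
    for k in range(reps):
        m = rng.integers(0, 3, n) / 2.0
        upf_dev = config.upf_gradient * (m - 0.5) + config.upf_sd * rng.standard_normal(n)
        ln4 = (config.tl4_lognormal_sigma * rng.standard_normal(n)
               + d4 * m + du * upf_dev)
        ln8 = ln4 + rng.normal(config.ln_attrition_mu, config.ln_attrition_sigma, n) \
            + delta_a * m
        y4 = ln4 + sm_noise * rng.standard_normal(n)
        y8 = ln8 + sm_noise * rng.standard_normal(n)
        dr = np.empty(n)
        for c in range(n_coh):
            sel = coh == c
            r1 = rankdata(-y4[sel])
            r2 = rankdata(-y8[sel])
            dr[sel] = (r1 - r2) / (n_block - 1) * 100.0
        X = np.column_stack([np.ones(n), m == 0.5, m == 1.0]
                            + [coh == c for c in range(1, n_coh)]).astype(float)
        res = sm.RLM(dr, X, M=sm.robust.norms.HuberT()).fit()
        betas[k] = res.params[2]
    return float(betas.mean())


_CALIBRATION_CACHE: dict = {}


def rank_attrition_shift(config: SimConfig) -> float:
    """Extra ln-scale attrition for the top tertile realising the planted
    rank-tracking contrast; zero when no rank effect is requested.

    The parameter is defined as the expected high-vs-low contrast estimated
    by the study's robust regression on the measured tracking statistic.
    The shift is first solved in closed form for the mean contrast, then
    adjusted once for the robust-estimator functional (Huber trimming
    discards part of the rank signal carried by the group tails) using a
    deterministic pilot simulation; the result is cached per configuration.
    """
    if config.effect_rank_high_screen == 0.0:
        return 0.0
    key = (config.effect_rank_high_screen, config.effect_tl4_high_screen,
           config.tl4_lognormal_sigma, config.attrition_mean, config.attrition_sd,
           config.upf_gradient, config.upf_sd, config.upf_tl_pct_per_100g,
           config.cq_noise_sd, config.efficiency_T, config.efficiency_S,
           config.n_replicates, config.n_irc, config.samples_per_run,
           config.n_per_cohort, config.followup_rate, len(config.cohorts))
    if key not in _CALIBRATION_CACHE:
        target = config.effect_rank_high_screen
        delta0 = _solve_closed_form(config, target)
        residual = _mc_robust_contrast(config, delta0) - target
        _CALIBRATION_CACHE[key] = _solve_closed_form(config, target - residual)
    return _CALIBRATION_CACHE[key]


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the truth table, cohort covariate table and SB questionnaire.

    Returns
    -------
    truth : DataFrame
        ``child_id, cohort, tl4_true, tl8_true, screen_tertile_true,
        in_followup`` — true telomere lengths in T/S-ratio units.
    cohort_table : DataFrame
        One row per child with all study covariates.
    sb : DataFrame
        ``child_id, screen_wd, screen_we, other_wd, other_we`` (hours/day).
    """
    config.validate()
    n_total = config.n_per_cohort * len(config.cohorts)
    ids = np.array([f"C{i:05d}" for i in range(n_total)])
    cohort = np.repeat(list(config.cohorts), config.n_per_cohort)

    # --- sedentary behaviour questionnaire ---
    rng_sb = _rng(config, 1)
    sb = pd.DataFrame({
        "child_id": ids,
        "screen_wd": _gamma_hours(rng_sb, config.screen_wd_mean, config.screen_wd_sd, n_total),
        "screen_we": _gamma_hours(rng_sb, config.screen_we_mean, config.screen_we_sd, n_total),
        "other_wd": _gamma_hours(rng_sb, config.other_wd_mean, config.other_sd, n_total),
        "other_we": _gamma_hours(rng_sb, config.other_we_mean, config.other_sd, n_total),
    })
    screen_daily = daily_mean(sb["screen_wd"], sb["screen_we"])
    tert = assign_tertiles(screen_daily).labels.astype(str).to_numpy()
    m = np.array([TERTILE_WEIGHT[t] for t in tert])

    # --- covariates (energy and UPF intake carry the confounding gradient) ---
    rng_cov = _rng(config, 2)
    z1 = rng_cov.standard_normal(n_total)
    z2 = (config.energy_upf_corr * z1 +
          math.sqrt(1 - config.energy_upf_corr ** 2) * rng_cov.standard_normal(n_total))
    energy = np.clip(config.energy_mean + config.energy_gradient * (m - 0.5)
                     + config.energy_sd * z1, 300, None)
    upf = np.clip(config.upf_mean + config.upf_gradient * (m - 0.5)
                  + config.upf_sd * z2, 0, None)
    pa = np.clip(config.pa_mean + config.pa_gradient * m
                 + config.pa_sd * rng_cov.standard_normal(n_total), 0, None)
    age4 = rng_cov.normal(config.age4_mean, config.age4_sd, n_total)
    fu_time = np.clip(rng_cov.normal(config.followup_time_mean,
                                     config.followup_time_sd, n_total), 2.0, None)
    storage = rng_cov.uniform(0, config.storage_days_max, n_total)
    season = SEASONS[(storage % 365.25 // 91.3125).astype(int) % 4]
    sex = np.where(rng_cov.random(n_total) < config.p_male, "male", "female")
    bmi = np.exp(rng_cov.normal(math.log(config.bmi_median), config.bmi_sigma, n_total))
    rmed = np.clip(np.round(rng_cov.normal(config.rmed_mean, config.rmed_sd, n_total)), 0, 18)
    preterm = rng_cov.random(n_total) < config.p_preterm
    mother_age = rng_cov.normal(config.mother_age_mean, config.mother_age_sd, n_total)
    mother_bmi = np.exp(rng_cov.normal(math.log(config.mother_bmi_median),
                                       config.mother_bmi_sigma, n_total))
    smoking = np.where(rng_cov.random(n_total) < config.p_smoking, "yes", "no")
    edu = rng_cov.choice(["university", "secondary", "primary"], n_total, p=config.edu_probs)
    origin = np.where(rng_cov.random(n_total) < config.p_origin_spain, "spain", "other")
    in_followup = rng_cov.random(n_total) < config.followup_rate

    # --- true telomere lengths ---
    rng_tl = _rng(config, 3)
    d4 = math.log1p(config.effect_tl4_high_screen)
    du = config.upf_ln_effect_per_g
    ln_tl4 = (config.tl4_lognormal_mu
              + config.tl4_lognormal_sigma * rng_tl.standard_normal(n_total)
              + d4 * m + du * (upf - config.upf_mean))
    delta_a = rank_attrition_shift(config)
    ln_att = rng_tl.normal(config.ln_attrition_mu, config.ln_attrition_sigma, n_total)
    ln_tl8 = ln_tl4 + ln_att + delta_a * m

    truth = pd.DataFrame({
        "child_id": ids, "cohort": cohort,
        "tl4_true": np.exp(ln_tl4), "tl8_true": np.exp(ln_tl8),
        "screen_tertile_true": tert, "in_followup": in_followup,
    })
    cohort_table = pd.DataFrame({
        "child_id": ids, "cohort": cohort, "sex": sex,
        "age4": np.round(age4, 2),
        "age8": np.where(in_followup, np.round(age4 + fu_time, 2), np.nan),
        "followup_time": np.where(in_followup, np.round(fu_time, 2), np.nan),
        "storage_date": np.round(storage, 1), "season": season,
        "energy_kcal": np.round(energy, 1), "upf_g": np.round(upf, 1),
        "bmi": np.round(bmi, 2), "rmed": rmed, "pa_met": np.round(pa, 2),
        "preterm": np.where(preterm, "yes", "no"),
        "mother_age": np.round(mother_age, 1),
        "mother_bmi": np.round(mother_bmi, 2),
        "mother_smoking": smoking, "mother_edu": edu, "mother_origin": origin,
    })
    return truth, cohort_table, sb


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate raw triplicate Cq wells for every sample, IRC and dilution point.

    Each (cohort, age) batch is assayed as its own experiment: study samples
    are chunked into runs of ``samples_per_run``; the same ``n_irc`` physical
    calibrator aliquots and a fresh serial dilution series appear on every
    run; each (run, target) gets an additive Cq shift and every well gets
    independent replicate noise. ``Cq = base - ln(q)/ln(E) + shift + noise``.

    Returns a long table with columns ``sample_id, run_id, target, replicate,
    cq, well_class, dilution_factor, cohort, age_years``.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    rng = _rng(config, 4)
    eff = {"T": config.efficiency_T, "S": config.efficiency_S}
    base = {"T": config.cq_base_T, "S": config.cq_base_S}
    chunks: list[dict] = []

    for coh in pd.unique(truth["cohort"]):
        for age in (4, 8):
            sub = truth[truth["cohort"] == coh]
            if age == 8:
                sub = sub[sub["in_followup"]]
            if len(sub) == 0:
                continue
            sample_ids = (sub["child_id"] + f"_y{age}").to_numpy()
            tl = sub[f"tl{age}_true"].to_numpy()
            dna_in = np.exp(rng.normal(0.0, config.dna_input_sigma, len(sub)))
            q = {"T": tl * dna_in, "S": dna_in}

            irc_ids = np.array([f"{coh}_y{age}_irc{i}" for i in range(config.n_irc)])
            irc_tl = np.exp(rng.normal(config.tl4_lognormal_mu,
                                       config.tl4_lognormal_sigma, config.n_irc))
            irc_in = np.exp(rng.normal(0.0, config.dna_input_sigma, config.n_irc))
            irc_q = {"T": irc_tl * irc_in, "S": irc_in}

            dil_factors = config.dilution_step ** np.arange(config.n_dilution_points)
            pool_q = {"T": math.exp(config.tl4_lognormal_mu), "S": 1.0}

            n_runs = math.ceil(len(sub) / config.samples_per_run)
            for r in range(n_runs):
                run_id = f"{coh}-y{age}-r{r:02d}"
                sel = slice(r * config.samples_per_run, (r + 1) * config.samples_per_run)
                for target in ("T", "S"):
                    shift = rng.normal(0.0, config.run_shift_sd)
                    sid = np.concatenate([sample_ids[sel], irc_ids,
                                          np.array([f"{coh}_y{age}_dil{i}"
                                                    for i in range(config.n_dilution_points)])])
                    quant = np.concatenate([q[target][sel], irc_q[target],
                                            pool_q[target] / dil_factors])
                    wclass = np.concatenate([
                        np.repeat("sample", len(sample_ids[sel])),
                        np.repeat("irc", config.n_irc),
                        np.repeat("dilution", config.n_dilution_points)])
                    dfac = np.concatenate([np.full(len(sample_ids[sel]) + config.n_irc, np.nan),
                                           dil_factors])
                    nrep = config.n_replicates
                    nwell = len(sid)
                    cq_true = base[target] - np.log(quant) / math.log(eff[target]) + shift
                    cq = (np.repeat(cq_true, nrep)
                          + rng.normal(0.0, config.cq_noise_sd, nwell * nrep))
                    chunks.append({
                        "sample_id": np.repeat(sid, nrep),
                        "run_id": np.full(nwell * nrep, run_id),
                        "target": np.full(nwell * nrep, target),
                        "replicate": np.tile(np.arange(1, nrep + 1), nwell),
                        "cq": cq,
                        "well_class": np.repeat(wclass, nrep),
                        "dilution_factor": np.repeat(dfac, nrep),
                        "cohort": np.full(nwell * nrep, coh),
                        "age_years": np.full(nwell * nrep, age),
                    })

    plates = pd.concat([pd.DataFrame(c) for c in chunks], ignore_index=True)
    return plates
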