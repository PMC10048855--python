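"""Simulation configuration for the synthetic multi-cohort telomere study.

The defaults describe a three-cohort child study: leukocyte telomere length
(TL, as a relative T/S ratio) measured by triplicate qPCR at ages 4 and 8,
parent-reported sedentary behaviour at age 4, and a confounding structure in
which ultra-processed food (UPF) intake rises across screen-time tertiles and
independently shortens TL.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

COHORTS = ("asturias", "gipuzkoa", "sabadell")

TERTILE_WEIGHT = {"low": 0.0, "middle": 0.5, "high": 1.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort and qPCR plate generator.

    All TL effect parameters are expressed on the scale used for reporting:
    ``effect_tl4_high_screen`` is the fractional TL difference at age 4 for the
    highest vs lowest screen-time tertile (e.g. ``-0.04`` for 4% shorter),
    interpolated to half that for the middle tertile;
    ``effect_rank_high_screen`` is the planted high-vs-low contrast in the
    telomere-tracking statistic (percentage points of rank change).
    """

    seed: int = 0
    n_per_cohort: int = 500

    # --- exposure effects on telomere length ---
    effect_tl4_high_screen: float = -0.04
    effect_rank_high_screen: float = -2.0

    # --- baseline TL distribution and attrition (T/S ratio, arbitrary units) ---
    tl4_lognormal_mu: float = 0.0
    tl4_lognormal_sigma: float = 0.25
    attrition_mean: float = 0.9     # multiplicative TL change 4 -> 8 y
    attrition_sd: float = 0.15

    # --- qPCR measurement model ---
    cq_noise_sd: float = 0.15       # replicate Cq noise, cycles
    run_shift_sd: float = 0.3       # per-(run, target) additive Cq offset, cycles
    efficiency_T: float = 2.07      # amplification factor per cycle (107%)
    efficiency_S: float = 2.0
    cq_base_T: float = 22.0
    cq_base_S: float = 26.0
    dna_input_sigma: float = 0.3    # lognormal sd of per-sample DNA input (cancels in T/S)
    samples_per_run: int = 100
    n_irc: int = 8                  # inter-run calibrators re-measured on every run
    n_dilution_points: int = 6
    dilution_step: float = 2.0
    n_replicates: int = 3

    # --- sedentary behaviour questionnaire (hours/day, gamma-distributed) ---
    screen_wd_mean: float = 1.2
    screen_wd_sd: float = 0.8
    screen_we_mean: float = 1.8
    screen_we_sd: float = 1.0
    other_wd_mean: float = 1.3
    other_we_mean: float = 1.5
    other_sd: float = 0.7

    # --- covariates and confounding structure ---
    energy_mean: float = 1580.0     # kcal/day
    energy_sd: float = 320.0
    energy_gradient: float = 80.0   # kcal/day difference, high vs low screen tertile
    upf_mean: float = 400.0         # g/day
    upf_sd: float = 180.0
    upf_gradient: float = 80.0      # g/day difference, high vs low screen tertile
    upf_tl_pct_per_100g: float = -2.0   # % TL change per 100 g/day UPF (planted confounder)
    energy_upf_corr: float = 0.3
    pa_mean: float = 10.0           # extracurricular PA, MET-h/day
    pa_sd: float = 4.5
    pa_gradient: float = -0.8
    age4_mean: float = 4.4
    age4_sd: float = 0.2
    followup_time_mean: float = 4.1
    followup_time_sd: float = 0.6
    followup_rate: float = 0.8
    storage_days_max: float = 1000.0
    bmi_median: float = 16.0
    bmi_sigma: float = 0.07
    rmed_mean: float = 9.0
    rmed_sd: float = 2.0
    p_male: float = 0.523
    p_preterm: float = 0.045
    mother_age_mean: float = 37.1
    mother_age_sd: float = 4.2
    mother_bmi_median: float = 22.9
    mother_bmi_sigma: float = 0.09
    p_smoking: float = 0.24
    p_origin_spain: float = 0.94
    edu_probs: tuple = (0.40, 0.40, 0.20)   # university, secondary, primary

    cohorts: tuple = COHORTS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_per_cohort <= 0:
            raise ValueError("n_per_cohort must be positive")
        for name in ("effect_tl4_high_screen",):
            if getattr(self, name) <= -1:
                raise ValueError(f"{name} must be > -1 (TL must stay positive)")
        if self.n_irc < 2:
            raise ValueError("need at least 2 inter-run calibrators")
        if self.efficiency_T <= 1 or self.efficiency_S <= 1:
            raise ValueError("amplification efficiencies must exceed 1")
        for name in ("tl4_lognormal_sigma", "attrition_sd", "cq_noise_sd",
                     "run_shift_sd", "dna_input_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.attrition_mean <= 0:
            raise ValueError("attrition_mean must be positive")
        if not 0 < self.followup_rate <= 1:
            raise ValueError("followup_rate must lie in (0, 1]")
        if self.n_dilution_points < 2 or self.dilution_step <= 1:
            raise ValueError("dilution series must have >= 2 points with step > 1")

    # -- derived quantities used by both the generator and its calibration --

    @property
    def ln_attrition_sigma(self) -> float:
        import math
        return math.sqrt(math.log(1.0 + (self.attrition_sd / self.attrition_mean) ** 2))

    @property
    def ln_attrition_mu(self) -> float:
        import math
        return math.log(self.attrition_mean) - 0.5 * self.ln_attrition_sigma ** 2

    @property
    def upf_ln_effect_per_g(self) -> float:
        """Natural-log TL effect per g/day of UPF intake."""
        import math
        return math.log(1.0 + self.upf_tl_pct_per_100g / 100.0) / 100.0

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialisation --

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cohorts"] = list(data["cohorts"])
        data["edu_probs"] = list(data["edu_probs"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "cohorts" in data:
            data["cohorts"] = tuple(data["cohorts"])
        if "edu_probs" in data:
            data["edu_probs"] = tuple(data["edu_probs"])
        return cls(**data)
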