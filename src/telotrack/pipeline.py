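"""End-to-end orchestration: simulate -> quantify -> exposures -> tracking -> models.

`run_study` drives the whole chain on one synthetic cohort realisation and
is what the replicate-based calibration checks and the acceptance script
build on. `analyse` is the simulation-free half: it takes measured TL
tables plus the cohort and questionnaire tables and fits the model ladder,
so it works identically on any data arranged in the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, exposure, qpcr, tracking
from .association import ModelSpec
from .config import SimConfig
from .simulate import simulate_cohort, simulate_qpcr


@dataclass
class StudyResult:
    estimates: pd.DataFrame                  # tidy effect estimates, all models
    spearman: tuple                          # (rho, p) of R1 vs R2, pooled
    cutpoints: dict                          # tertile cut-points per exposure/outcome set
    data4: pd.DataFrame                      # cross-sectional analysis frame
    data8: pd.DataFrame                      # tracking analysis frame
    quant: dict = field(default_factory=dict)     # cohort -> QuantResult
    truth: pd.DataFrame | None = None
    selection: association.SelectionResult | None = None
    heterogeneity: dict = field(default_factory=dict)


def _child_tl_table(quant_results: dict, age: int) -> pd.DataFrame:
    """Per-child CNRQ table for one age from per-cohort quantifications."""
    parts = []
    for coh, res in quant_results.items():
        sub = res.cnrq[res.cnrq["batch"] == str(age)].copy()
        sub["child_id"] = sub["sample_id"].str.replace(f"_y{age}", "", regex=False)
        parts.append(sub[["child_id", "cnrq"]].assign(cohort=coh))
    out = pd.concat(parts, ignore_index=True).rename(columns={"cnrq": "tl"})
    return out


def analyse(tl4: pd.DataFrame, tl8: pd.DataFrame | None, cohort_table: pd.DataFrame,
            sb: pd.DataFrame, models=("M1", "M2", "M3"),
            tracking_models=("M1", "M2", "M3", "M4"),
            exposures=("screen",),
            rank_on_full_baseline: bool = False) -> StudyResult:
    """Fit the association ladder on measured TL tables.

    Exposure tertiles are cut once, on the baseline (cross-sectional)
    analysis sample where SB was measured; the tracking analysis inherits
    those labels rather than re-cutting on the follow-up subset, so a
    child's exposure category does not depend on later drop-out.
    """
    cutpoints: dict = {}

    # cross-sectional frame
    data4 = cohort_table.merge(tl4[["child_id", "tl"]], on="child_id", how="inner")
    data4["log10_tl4"] = np.log10(data4["tl"])
    exp4, cut4 = exposure.build_exposures(sb[sb["child_id"].isin(data4["child_id"])])
    data4 = data4.merge(exp4.drop(columns=["screen_wd", "screen_we", "other_wd", "other_we"]),
                        on="child_id")
    cutpoints["cross_sectional"] = cut4

    estimates = []
    for exp_name in exposures:
        for m in models:
            spec = ModelSpec(outcome="log10_TL", exposure=exp_name, model=m)
            estimates += association.fit_robust_model(spec, data4)

    spearman = (np.nan, np.nan)
    data8 = pd.DataFrame()
    if tl8 is not None and len(tl8) > 0:
        track = tracking.build_tracking(tl4, tl8, rank_on_full_baseline=rank_on_full_baseline)
        spearman = tracking.rank_correlation(track["r1"], track["r2"])
        data8 = cohort_table.merge(track, on=["child_id", "cohort"], how="inner")
        data8 = data8.merge(tl4[["child_id", "tl"]], on="child_id")
        data8["log10_tl4"] = np.log10(data8["tl"])
        data8 = data8.merge(exp4.drop(columns=["screen_wd", "screen_we", "other_wd", "other_we"]),
                            on="child_id")
        cutpoints["tracking"] = {
            "note": "labels inherited from the baseline analysis sample",
            "sizes": {var: data8[f"{var}_tertile"].value_counts().to_dict()
                      for var in ("screen", "other", "total")}}
        for exp_name in exposures:
            for m in tracking_models:
                spec = ModelSpec(outcome="delta_R", exposure=exp_name, model=m)
                estimates += association.fit_robust_model(spec, data8)

    return StudyResult(estimates=association.estimates_frame(estimates),
                       spearman=spearman, cutpoints=cutpoints,
                       data4=data4, data8=data8)


def run_study(config: SimConfig, seed: int | None = None,
              models=("M1", "M2", "M3"), tracking_models=("M1", "M2", "M3", "M4"),
              exposures=("screen",), use_qpcr: bool = True,
              keep_quant: bool = False) -> StudyResult:
    """Simulate one cohort study and run the full analysis chain.

    With ``use_qpcr`` (the default) TL is taken through the complete
    measurement model: raw triplicate Cq wells, per-cohort CNRQ
    quantification with inter-run calibration, then ranking and regression.
    ``use_qpcr=False`` analyses the true TL values directly (useful to
    separate measurement error from sampling error).
    """
    cfg = config if seed is None else config.replace(seed=seed)
    truth, cohort_table, sb = simulate_cohort(cfg)

    if use_qpcr:
        plates = simulate_qpcr(truth, cfg)
        quant = {coh: qpcr.quantify_cohort(plates, cohort=coh)
                 for coh in cfg.cohorts}
        tl4 = _child_tl_table(quant, 4)
        tl8 = _child_tl_table(quant, 8)
    else:
        quant = {}
        tl4 = truth.rename(columns={"tl4_true": "tl"})[["child_id", "cohort", "tl"]]
        tl8 = truth[truth["in_followup"]].rename(columns={"tl8_true": "tl"})[
            ["child_id", "cohort", "tl"]]

    res = analyse(tl4, tl8, cohort_table, sb, models=models,
                  tracking_models=tracking_models, exposures=exposures)
    res.truth = truth
    if keep_quant:
        res.quant = quant
    return res


def pooled_iccs(quant_results: dict) -> dict:
    """Study-wide reliability: ICCs over replicate measures pooled across
    cohorts and batches (subjects remain individual samples / IRC aliquots)."""
    rep = pd.concat([r.replicate_rq for r in quant_results.values()], ignore_index=True)
    out = {}
    for kind, col in (("intra_T", "T"), ("intra_S", "S"), ("intra_TS", "ts")):
        sub = rep.dropna(subset=[col])
        out[kind] = qpcr.compute_icc(sub[col], sub["sample_id"], kind=kind)
    return out


def replicate_effects(config: SimConfig, n_reps: int, base_seed: int = 0,
                      tl4_model: str = "M3", tracking_model: str = "M1",
                      select: bool = False,
                      candidates=("energy_kcal", "upf_g", "age4", "sex",
                                  "bmi", "rmed", "pa_met", "mother_age")) -> pd.DataFrame:
    """Replicate-study harness: re-simulate and re-analyse ``n_reps`` cohorts.

    Per replicate the full measurement chain is run and the high- and
    middle-vs-low screen-time estimates are recorded for the cross-sectional
    (log10 TL, ``tl4_model``) and tracking (``tracking_model``) outcomes.
    With ``select=True`` the two-stage covariate selection is also run on
    the cross-sectional frame and whether the UPF-intake confounder was
    retained is recorded.

    Returns one row per replicate with columns ``seed, tl4_high_pct,
    tl4_high_p, dr_high_pct, dr_high_p`` (and ``upf_selected`` if
    requested).
    """
    rows = []
    for r in range(n_reps):
        seed = int(base_seed + r)
        res = run_study(config, seed=seed, models=(tl4_model,),
                        tracking_models=(tracking_model,) if tracking_model else ())
        e = res.estimates
        row = {"seed": seed}
        sel4 = e[(e["outcome"] == "log10_TL") & (e["model"] == tl4_model)
                 & (e["term"] == "screen:high")]
        row["tl4_high_pct"] = float(sel4["pct_change"].iloc[0])
        row["tl4_high_p"] = float(sel4["p_value"].iloc[0])
        if tracking_model:
            sel8 = e[(e["outcome"] == "delta_R") & (e["model"] == tracking_model)
                     & (e["term"] == "screen:high")]
            row["dr_high_pct"] = float(sel8["pct_change"].iloc[0])
            row["dr_high_p"] = float(sel8["p_value"].iloc[0])
        if select:
            sel = association.select_covariates(
                res.data4, "log10_tl4", "screen_tertile", list(candidates),
                always_in=["cohort", "storage_date"])
            row["upf_selected"] = "upf_g" in sel.selected
        rows.append(row)
    return pd.DataFrame(rows)
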