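"""Relative telomere length quantification from qPCR Cq values.

Implements the calibrated normalised relative quantity (CNRQ) chain used to
express leukocyte telomere length as a T/S ratio:

1. amplification efficiency per target from a serial dilution standard curve,
   ``E = 10 ** (-1 / slope)``;
2. arithmetic mean of triplicate Cq values per (sample, run, target);
3. relative quantity ``RQ = E ** (ref_Cq - Cq)`` with the reference taken as
   the arithmetic mean Cq over all analysed study samples of that target in
   the cohort (no designated calibrator sample);
4. ``NRQ = RQ_T / RQ_S``;
5. per-run correction factors from inter-run calibrators (IRCs) measured on
   every run, ``CF_r = geometric mean over IRCs of (NRQ_ir / geometric mean
   over runs of NRQ_i.)``, and ``CNRQ = NRQ / CF_run``;
6. one-way random-effects intraclass correlation coefficients (ICC) of
   triplicate measures and of IRC CNRQs across runs.

Normalisation never mixes cohorts: each cohort (and each assay batch within
a cohort) is quantified as its own experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: replicate Cq spread (cycles) above which a QC flag is raised; non-blocking
MAX_SPREAD_CYCLES = 0.5


@dataclass
class EfficiencyEstimate:
    """Standard-curve fit for one target."""
    target: str
    slope: float            # cycles per log10(relative quantity)
    E: float                # amplification factor per cycle
    efficiency_pct: float   # (E - 1) * 100
    r_squared: float
    n_points: int


@dataclass
class IccResult:
    """One-way random-effects ICC with F-based 95% CI and p-value."""
    kind: str
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    n_measures: int


@dataclass
class QuantResult:
    """Output of :func:`quantify_cohort` for one cohort."""
    cnrq: pd.DataFrame                    # per study sample: rq_T, rq_S, nrq, cnrq
    efficiencies: dict                    # (batch, target) -> EfficiencyEstimate
    iccs: dict                            # (batch, kind) -> IccResult
    correction_factors: pd.Series         # run_id -> CF
    replicate_rq: pd.DataFrame            # replicate-level RQ/TS values (for pooled ICCs)
    flags: pd.DataFrame                   # QC flags per (sample, run, target)
    excluded_samples: list = field(default_factory=list)
    excluded_ircs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# standard curve
# ---------------------------------------------------------------------------

def estimate_efficiency(dilution_wells: pd.DataFrame, target: str | None = None) -> EfficiencyEstimate:
    """Fit the standard curve of mean Cq against log10 relative quantity.

    ``dilution_wells`` needs columns ``cq`` and ``dilution_factor`` (and
    ``target`` if ``target`` is given). The relative quantity of a well is
    ``1 / dilution_factor``, so the fitted slope is in cycles per decade and
    ``E = 10 ** (-1 / slope)``.
    """
    df = dilution_wells
    if target is not None:
        df = df[df["target"] == target]
    pts = df.groupby("dilution_factor")["cq"].mean()
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct dilution points")
    x = -np.log10(pts.index.to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("zero variance in dilution factors")
    y = pts.to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    E = 10.0 ** (-1.0 / slope)
    return EfficiencyEstimate(target=target or "", slope=float(slope), E=float(E),
                              efficiency_pct=(E - 1.0) * 100.0, r_squared=r2,
                              n_points=len(pts))


# ---------------------------------------------------------------------------
# replicate handling and relative quantities
# ---------------------------------------------------------------------------

def aggregate_replicates(wells: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean Cq per (sample, run, target) with QC flags.

    No replicate is rejected automatically; a spread above
    ``MAX_SPREAD_CYCLES`` only raises a non-blocking flag, as does a group
    with fewer than 2 replicates.
    """
    if len(wells) == 0:
        raise ValueError("no replicate wells to aggregate")
    keys = ["sample_id", "run_id", "target"]
    extra = [c for c in ("well_class", "cohort") if c in wells.columns]
    g = wells.groupby(keys + extra, observed=True)["cq"]
    out = g.agg(cq_mean="mean", n_reps="count",
                spread=lambda s: s.max() - s.min()).reset_index()
    out["flag_low_replicates"] = out["n_reps"] < 2
    out["flag_spread"] = out["spread"] > MAX_SPREAD_CYCLES
    return out


def compute_rq(mean_cq, reference_cq: float, efficiency: float):
    """Relative quantity ``E ** (reference_cq - mean_cq)``.

    ``reference_cq`` is the arithmetic mean Cq over all analysed study
    samples of the target within the cohort, so RQ = 1 for an average sample.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    out = np.asarray(efficiency, dtype=float) ** (reference_cq - np.asarray(mean_cq, dtype=float))
    return float(out) if out.ndim == 0 else out


def compute_nrq(rq_t, rq_s):
    """Normalised relative quantity (T/S ratio): ``RQ_T / RQ_S``."""
    rq_s = np.asarray(rq_s, dtype=float)
    if np.any(rq_s == 0):
        raise ValueError("single-copy gene RQ must be non-zero")
    out = np.asarray(rq_t, dtype=float) / rq_s
    return float(out) if out.ndim == 0 else out


def compute_inter_run_cf(irc_nrq: pd.DataFrame) -> tuple[pd.Series, list]:
    """Per-run correction factors from inter-run calibrator NRQs.

    ``irc_nrq`` needs columns ``sample_id, run_id, nrq``. With a single run
    the CF is 1. Otherwise an IRC absent from any run is excluded (returned
    in the second element); at least two complete IRCs must remain. By
    construction the geometric mean of the CFs across runs is exactly 1.
    """
    runs = pd.unique(irc_nrq["run_id"])
    if len(runs) == 1:
        return pd.Series(1.0, index=pd.Index(runs, name="run_id"), name="cf"), []
    mat = irc_nrq.pivot_table(index="sample_id", columns="run_id", values="nrq")
    complete = mat.dropna(axis=0)
    excluded = sorted(set(mat.index) - set(complete.index))
    if len(complete) < 2:
        raise ValueError("fewer than 2 inter-run calibrators measured on every run")
    ln = np.log(complete.to_numpy())
    ln_centred = ln - ln.mean(axis=1, keepdims=True)   # centre each IRC across runs
    cf = pd.Series(np.exp(ln_centred.mean(axis=0)), index=complete.columns, name="cf")
    return cf.reindex(runs), excluded


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def compute_icc(values, subjects, kind: str = "icc", conf: float = 0.95) -> IccResult:
    """One-way random-effects, single-measurement, absolute-agreement ICC.

    Computed from the one-way ANOVA mean squares with the harmonic-style
    average group size ``k0`` for unbalanced designs; the CI and p-value come
    from the F distribution. Zero within-subject variance gives ICC = 1;
    absence of between-subject variance can give a negative ICC, which is
    reported as computed.
    """
    df = pd.DataFrame({"subject": np.asarray(subjects), "value": np.asarray(values, dtype=float)})
    df = df.dropna()
    counts = df.groupby("subject")["value"].count()
    counts = counts[counts >= 1]
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with at least 2 measures each")
    n = len(counts)
    N = int(counts.sum())
    grand = df["value"].mean()
    means = df.groupby("subject")["value"].mean()
    ssb = float((counts * (means - grand) ** 2).sum())
    ssw = float(((df["value"] - df["subject"].map(means)) ** 2).sum())
    dfb, dfw = n - 1, N - n
    msb, msw = ssb / dfb, ssw / dfw
    k0 = (N - float((counts ** 2).sum()) / N) / (n - 1)
    if msw == 0.0:
        return IccResult(kind, 1.0, 1.0, 1.0, 0.0, n, N)
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    F = msb / msw
    alpha = 1.0 - conf
    p = float(stats.f.sf(F, dfb, dfw))
    fl = F / stats.f.ppf(1 - alpha / 2, dfb, dfw)
    fu = F * stats.f.ppf(1 - alpha / 2, dfw, dfb)
    ci_low = (fl - 1) / (fl + k0 - 1)
    ci_high = (fu - 1) / (fu + k0 - 1)
    return IccResult(kind, float(icc), float(ci_low), float(ci_high), p, n, N)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def _quantify_batch(plate: pd.DataFrame, batch: str,
                    efficiencies: dict | None) -> dict:
    """CNRQ chain for one assay batch (one cohort, one experiment)."""
    eff: dict[str, float] = {}
    for target in ("T", "S"):
        if efficiencies is not None:
            eff[target] = efficiencies[target]
            est = None
        else:
            dil = plate[(plate["well_class"] == "dilution") & (plate["target"] == target)]
            est = estimate_efficiency(dil, target=target)
            eff[target] = est.E
        if est is not None:
            eff[f"_est_{target}"] = est

    wells = plate[plate["well_class"].isin(["sample", "irc"])]
    agg = aggregate_replicates(wells)

    # reference Cq: arithmetic mean over analysed study samples, per target
    ref = {t: agg.loc[(agg["target"] == t) & (agg["well_class"] == "sample"), "cq_mean"].mean()
           for t in ("T", "S")}
    agg["rq"] = np.nan
    for t in ("T", "S"):
        mask = agg["target"] == t
        agg.loc[mask, "rq"] = compute_rq(agg.loc[mask, "cq_mean"], ref[t], eff[t])

    wide = agg.pivot_table(index=["sample_id", "run_id", "well_class"],
                           columns="target", values="rq").reset_index()
    missing = wide[wide[["T", "S"]].isna().any(axis=1)]
    excluded_samples = missing["sample_id"].tolist()
    wide = wide.dropna(subset=["T", "S"]).rename(columns={"T": "rq_T", "S": "rq_S"})
    wide["nrq"] = compute_nrq(wide["rq_T"], wide["rq_S"])

    irc = wide[wide["well_class"] == "irc"]
    if len(irc) > 0:
        cf, excluded_ircs = compute_inter_run_cf(irc[["sample_id", "run_id", "nrq"]])
    else:
        cf = pd.Series(1.0, index=pd.Index(pd.unique(wide["run_id"]), name="run_id"), name="cf")
        excluded_ircs = []
    wide["cnrq"] = wide["nrq"] / wide["run_id"].map(cf).to_numpy()
    wide["batch"] = batch

    # replicate-level relative quantities for the reliability metrics
    rep = wells[wells["well_class"] == "sample"].copy()
    rep["rq"] = np.nan
    for t in ("T", "S"):
        mask = rep["target"] == t
        rep.loc[mask, "rq"] = compute_rq(rep.loc[mask, "cq"], ref[t], eff[t])
    rep_wide = rep.pivot_table(index=["sample_id", "run_id", "replicate"],
                               columns="target", values="rq").reset_index()
    rep_wide["ts"] = rep_wide["T"] / rep_wide["S"]
    rep_wide["batch"] = batch

    iccs = {}
    for kind, col in (("intra_T", "T"), ("intra_S", "S"), ("intra_TS", "ts")):
        sub = rep_wide.dropna(subset=[col])
        try:
            iccs[kind] = compute_icc(sub[col], sub["sample_id"], kind=kind)
        except ValueError:
            pass
    irc_cnrq = wide[wide["well_class"] == "irc"]
    if irc_cnrq["run_id"].nunique() >= 2:
        iccs["inter_assay"] = compute_icc(irc_cnrq["cnrq"], irc_cnrq["sample_id"],
                                          kind="inter_assay")

    return {"wide": wide, "cf": cf, "agg": agg, "rep": rep_wide, "iccs": iccs,
            "eff": eff, "excluded_samples": excluded_samples,
            "excluded_ircs": excluded_ircs}


def quantify_cohort(plate: pd.DataFrame, cohort: str | None = None,
                    efficiencies: dict | None = None,
                    batch_col: str = "age_years") -> QuantResult:
    """Run the full CNRQ chain for one cohort.

    Parameters
    ----------
    plate : DataFrame
        Long plate table (``sample_id, run_id, target, replicate, cq,
        well_class, dilution_factor`` plus optional ``cohort`` and batch
        columns).
    cohort : str, optional
        Restrict to one cohort; required if the table holds several.
    efficiencies : dict, optional
        ``{"T": E_T, "S": E_S}`` to use fixed amplification efficiencies
        instead of estimating them from the dilution series (the default).
    batch_col : str
        Column separating independent assay batches within the cohort (e.g.
        the two study ages); each batch is normalised on its own.
    """
    df = plate
    if "cohort" in df.columns:
        if cohort is not None:
            df = df[df["cohort"] == cohort]
        elif df["cohort"].nunique() > 1:
            raise ValueError("plate table holds several cohorts; pass cohort=...")
    if len(df) == 0:
        raise ValueError(f"no wells for cohort {cohort!r}")

    batches = ([(str(b), sub) for b, sub in df.groupby(batch_col)]
               if batch_col in df.columns else [("all", df)])
    parts, eff_out, icc_out = [], {}, {}
    cfs, reps, excl_s, excl_i = [], [], [], []
    for name, sub in batches:
        res = _quantify_batch(sub, name, efficiencies)
        parts.append(res["wide"])
        cfs.append(res["cf"])
        reps.append(res["rep"])
        excl_s += res["excluded_samples"]
        excl_i += res["excluded_ircs"]
        for t in ("T", "S"):
            if f"_est_{t}" in res["eff"]:
                eff_out[(name, t)] = res["eff"][f"_est_{t}"]
        for kind, icc in res["iccs"].items():
            icc_out[(name, kind)] = icc

    wide = pd.concat(parts, ignore_index=True)
    wide["cohort"] = cohort if cohort is not None else (
        df["cohort"].iloc[0] if "cohort" in df.columns else "")
    cnrq = wide[wide["well_class"] == "sample"].drop(columns=["well_class"])
    agg_flags = aggregate_replicates(df[df["well_class"].isin(["sample", "irc"])])
    flags = agg_flags[["sample_id", "run_id", "target", "n_reps",
                       "flag_low_replicates", "flag_spread"]]
    return QuantResult(cnrq=cnrq.reset_index(drop=True), efficiencies=eff_out,
                       iccs=icc_out, correction_factors=pd.concat(cfs),
                       replicate_rq=pd.concat(reps, ignore_index=True),
                       flags=flags, excluded_samples=excl_s, excluded_ircs=excl_i)
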