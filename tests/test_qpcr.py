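"""CNRQ quantification chain: standard curves, RQ/NRQ/CNRQ, IRC correction, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gmean

from telotrack import (aggregate_replicates, compute_icc, compute_inter_run_cf,
                       compute_nrq, compute_rq, estimate_efficiency,
                       quantify_cohort)


def dilution_frame(slope, intercept=30.0, factors=(1, 2, 4, 8, 16, 32), target="T"):
    """Noise-free dilution wells lying exactly on a standard curve."""
    rows = []
    for f in factors:
        x = -np.log10(f)
        for rep in (1, 2, 3):
            rows.append({"sample_id": "pool", "run_id": "r0", "target": target,
                         "replicate": rep, "cq": intercept + slope * x,
                         "well_class": "dilution", "dilution_factor": float(f)})
    return pd.DataFrame(rows)


class TestEfficiency:
    def test_perfect_doubling_chemistry(self):
        est = estimate_efficiency(dilution_frame(slope=-1 / np.log10(2)), target="T")
        assert est.slope == pytest.approx(-3.3219, abs=1e-4)
        assert est.E == pytest.approx(2.0, abs=1e-9)
        assert est.efficiency_pct == pytest.approx(100.0, abs=1e-7)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_for_arbitrary_slope(self):
        # E = 10**(1/3.10) for a -3.10 cycles/decade curve
        est = estimate_efficiency(dilution_frame(slope=-3.10))
        expected_E = 10.0 ** (1.0 / 3.10)
        assert est.E == pytest.approx(expected_E, rel=1e-10)
        assert est.efficiency_pct == pytest.approx((expected_E - 1) * 100, rel=1e-10)

    def test_too_few_dilution_points_rejected(self):
        single = dilution_frame(slope=-3.3, factors=(1,))
        with pytest.raises(ValueError):
            estimate_efficiency(single)
        two = dilution_frame(slope=-3.3, factors=(1, 2))
        with pytest.raises(ValueError):
            estimate_efficiency(two)


class TestReplicates:
    @pytest.mark.parametrize("cqs, mean, flagged", [
        ((20.0, 20.0, 20.0), 20.0, False),
        ((20.0, 20.2), 20.1, False),
        ((20.0,), 20.0, True),
    ])
    def test_arithmetic_mean_and_low_replicate_flag(self, cqs, mean, flagged):
        wells = pd.DataFrame({"sample_id": "s", "run_id": "r", "target": "T",
                              "replicate": range(1, len(cqs) + 1), "cq": cqs})
        out = aggregate_replicates(wells)
        assert out["cq_mean"].iloc[0] == pytest.approx(mean)
        assert bool(out["flag_low_replicates"].iloc[0]) is flagged

    def test_wide_spread_flagged_but_not_rejected(self):
        wells = pd.DataFrame({"sample_id": "s", "run_id": "r", "target": "T",
                              "replicate": [1, 2, 3], "cq": [20.0, 20.0, 21.0]})
        out = aggregate_replicates(wells)
        assert bool(out["flag_spread"].iloc[0])
        assert out["cq_mean"].iloc[0] == pytest.approx(61.0 / 3.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates(pd.DataFrame(columns=["sample_id", "run_id",
                                                       "target", "cq"]))


class TestRelativeQuantities:
    def test_rq_identity_and_doubling(self):
        assert compute_rq(25.0, 25.0, 2.0) == pytest.approx(1.0)
        assert compute_rq(24.0, 25.0, 2.0) == pytest.approx(2.0)
        assert compute_rq(25.5, 25.0, 2.07) == pytest.approx(2.07 ** -0.5)

    def test_rq_requires_amplification(self):
        with pytest.raises(ValueError):
            compute_rq(25.0, 25.0, 1.0)
        with pytest.raises(ValueError):
            compute_rq(25.0, 25.0, -2.0)

    def test_nrq_is_ts_ratio(self):
        assert compute_nrq(1.0, 1.0) == 1.0
        assert compute_nrq(2.0, 1.0) == 2.0
        assert compute_nrq(1.5, 0.5) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            compute_nrq(1.0, 0.0)


def irc_frame(nrq_by_run):
    """IRC NRQ table from {run: {irc: nrq}}."""
    rows = [{"sample_id": irc, "run_id": run, "nrq": v}
            for run, d in nrq_by_run.items() for irc, v in d.items()]
    return pd.DataFrame(rows)


class TestInterRunCorrection:
    def test_single_run_has_unit_cf(self):
        cf, excluded = compute_inter_run_cf(irc_frame({"r0": {"a": 1.2, "b": 0.7}}))
        assert (cf == 1.0).all()
        assert excluded == []

    def test_doubled_run_hand_example(self):
        # run2 NRQs exactly double run1: CF ratio 2, geometric mean 1, and a
        # sample's CNRQ does not depend on which run measured it
        base = {"a": 0.8, "b": 1.1, "c": 1.4}
        cf, _ = compute_inter_run_cf(irc_frame({
            "r1": base, "r2": {k: 2 * v for k, v in base.items()}}))
        assert cf["r2"] / cf["r1"] == pytest.approx(2.0, rel=1e-12)
        assert gmean(cf) == pytest.approx(1.0, rel=1e-12)
        assert 0.9 / cf["r1"] == pytest.approx(2 * 0.9 / cf["r2"], rel=1e-12)

    def test_cf_geometric_mean_is_one_for_any_input(self):
        rng = np.random.default_rng(5)
        nrq = {f"r{i}": {f"irc{j}": float(np.exp(rng.normal())) for j in range(8)}
               for i in range(4)}
        cf, _ = compute_inter_run_cf(irc_frame(nrq))
        assert gmean(cf) == pytest.approx(1.0, rel=1e-12)

    def test_incomplete_irc_excluded_then_error(self):
        # 'b' missing from r2: excluded, CF computed from the rest
        cf, excluded = compute_inter_run_cf(irc_frame({
            "r1": {"a": 1.0, "b": 2.0, "c": 0.5}, "r2": {"a": 1.1, "c": 0.6}}))
        assert excluded == ["b"]
        assert len(cf) == 2
        # fewer than 2 complete IRCs across >= 2 runs is an error
        with pytest.raises(ValueError):
            compute_inter_run_cf(irc_frame({"r1": {"a": 1.0, "b": 2.0},
                                            "r2": {"a": 1.1}}))


class TestIcc:
    def test_perfect_repeatability(self):
        subj = np.repeat(np.arange(10), 3)
        vals = np.repeat(np.linspace(1, 2, 10), 3)
        res = compute_icc(vals, subj)
        assert res.icc == pytest.approx(1.0, abs=1e-9)
        assert res.p_value < 1e-100

    def test_no_between_subject_variance_can_go_negative(self):
        rng = np.random.default_rng(0)
        subj = np.repeat(np.arange(50), 3)
        vals = rng.normal(0, 1, 150)  # subject means equal in expectation
        res = compute_icc(vals, subj)
        assert res.icc < 0.3
        assert res.ci_low <= res.icc <= res.ci_high

    def test_variance_components_recovery(self):
        rng = np.random.default_rng(42)
        n = 300
        subj_eff = rng.normal(0, 1.0, n)
        vals = (subj_eff[:, None] + rng.normal(0, 0.5, (n, 3))).ravel()
        res = compute_icc(vals, np.repeat(np.arange(n), 3))
        assert res.icc == pytest.approx(0.8, abs=0.04)
        assert res.ci_low < 0.8 < res.ci_high

    def test_matches_pingouin_one_way_random(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n = 40
        vals = (rng.normal(0, 1, n)[:, None] + rng.normal(0, 0.6, (n, 3))).ravel()
        subj = np.repeat(np.arange(n), 3)
        ours = compute_icc(vals, subj)
        df = pd.DataFrame({"targets": subj, "raters": np.tile(np.arange(3), n),
                           "ratings": vals})
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="ratings").set_index("Type")
        row = ref.loc["ICC(1,1)"] if "ICC(1,1)" in ref.index else ref.loc["ICC1"]
        assert ours.icc == pytest.approx(row["ICC"], abs=1e-6)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert ours.ci_low == pytest.approx(row[ci_col][0], abs=0.01)
        assert ours.ci_high == pytest.approx(row[ci_col][1], abs=0.01)
        assert ours.p_value == pytest.approx(row["pval"], rel=1e-4)

    def test_single_measure_subjects_rejected(self):
        with pytest.raises(ValueError):
            compute_icc([1.0, 2.0, 3.0], ["a", "b", "c"])


class TestQuantifyCohort:
    def test_noise_free_cnrq_proportional_to_truth(self, noise_free_study):
        res = quantify_cohort(noise_free_study["plates"], cohort="gipuzkoa")
        sub = res.cnrq[res.cnrq["batch"] == "4"].copy()
        sub["child_id"] = sub["sample_id"].str.replace("_y4", "", regex=False)
        truth = noise_free_study["truth"]
        m = sub.merge(truth, on="child_id")
        ratio = m["cnrq"] / m["tl4_true"]
        assert ratio.max() / ratio.min() - 1 < 1e-9

    def test_joint_vs_separate_cohort_processing_identical(self, noise_free_study):
        plates = noise_free_study["plates"]
        joint = {coh: quantify_cohort(plates, cohort=coh)
                 for coh in ("asturias", "sabadell")}
        for coh in ("asturias", "sabadell"):
            alone = quantify_cohort(plates[plates["cohort"] == coh], cohort=coh)
            pd.testing.assert_frame_equal(
                joint[coh].cnrq.sort_values("sample_id").reset_index(drop=True),
                alone.cnrq.sort_values("sample_id").reset_index(drop=True))

    def test_cnrq_invariant_to_per_run_additive_shift(self, small_study):
        # balanced runs: adding a constant to all Cq of one (run, target) must
        # leave every sample's CNRQ unchanged (run-effect removal via IRCs)
        plates = small_study["plates"].copy()
        base = quantify_cohort(plates, cohort="asturias")
        runs = plates.loc[(plates["cohort"] == "asturias") &
                          (plates["age_years"] == 4), "run_id"].unique()
        mask = (plates["run_id"] == runs[0]) & (plates["target"] == "T")
        plates.loc[mask, "cq"] += 0.73
        shifted = quantify_cohort(plates, cohort="asturias")
        a = base.cnrq.set_index(["sample_id", "run_id"])["cnrq"]
        b = shifted.cnrq.set_index(["sample_id", "run_id"])["cnrq"]
        assert float((b / a - 1).abs().max()) < 1e-9

    def test_missing_target_flagged_and_excluded(self, noise_free_study):
        plates = noise_free_study["plates"]
        sub = plates[plates["cohort"] == "asturias"].copy()
        victim = sub.loc[sub["well_class"] == "sample", "sample_id"].iloc[0]
        sub = sub[~((sub["sample_id"] == victim) & (sub["target"] == "T"))]
        res = quantify_cohort(sub, cohort="asturias")
        assert victim in res.excluded_samples
        assert victim not in set(res.cnrq["sample_id"])

    def test_mixed_cohorts_require_explicit_choice(self, noise_free_study):
        with pytest.raises(ValueError):
            quantify_cohort(noise_free_study["plates"])
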