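"""ROC/AUC machinery, AFP rules, detector combination, stratified tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seropanel import (
    AfpAnnCombiner,
    ValidationError,
    afp_negative_flag,
    afp_rule,
    combine_afp_ann,
    roc_auc,
    stratified_report,
)
from seropanel.evaluate import roc_curve_points, sens_spec_at

from conftest import toy_metadata

finite = st.floats(-100, 100, allow_nan=False)


class TestRocAuc:
    def test_examples(self):
        assert roc_auc([10, 11], [1, 2]) == 1.0
        assert roc_auc([5, 5, 5], [5, 5]) == 0.5
        assert roc_auc([3, 5], [1, 4]) == 0.75

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([], [1.0])

    @given(
        case=st.lists(finite, min_size=1, max_size=12),
        control=st.lists(finite, min_size=1, max_size=12),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_pair_counting_and_symmetry(self, case, control):
        pairs = [
            1.0 if c > k else 0.5 if c == k else 0.0 for c in case for k in control
        ]
        expected = sum(pairs) / len(pairs)
        assert roc_auc(case, control) == pytest.approx(expected)
        assert roc_auc(case, control) + roc_auc(control, case) == pytest.approx(1.0)

    @given(
        case=st.lists(finite, min_size=1, max_size=10),
        control=st.lists(finite, min_size=1, max_size=10),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_invariant_under_strictly_increasing_transform(self, case, control):
        f = lambda x: np.expm1(np.asarray(x, dtype=float) / 50.0)
        assert roc_auc(case, control) == pytest.approx(roc_auc(f(case), f(control)))


class TestAfpRules:
    def test_diagnostic_cutoff_is_strict(self):
        assert afp_rule(401.0) == "positive"
        assert afp_rule(400.0) == "negative"

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            afp_rule(-1.0)

    def test_afp_negative_flag_is_strictly_below_20(self):
        assert afp_negative_flag(19.9)
        assert not afp_negative_flag(20.0)
        flags = afp_negative_flag(np.array([0.0, 19.99, 20.0, 500.0]))
        assert flags.tolist() == [True, True, False, False]


class TestCombiner:
    def test_dominant_vote_gives_perfect_combined_auc(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(40), np.ones(40)]
        votes = np.r_[rng.uniform(0, 0.3, 40), rng.uniform(0.7, 1.0, 40)]
        afp = rng.lognormal(2, 1, 80)  # pure noise
        scores, _ = combine_afp_ann(afp, votes, y)
        assert roc_auc(scores[y == 1], scores[y == 0]) == 1.0

    def test_combination_no_worse_than_best_single_detector(self):
        deficits = []
        for seed in range(3):
            rng = np.random.default_rng(40 + seed)
            n = 150
            y = np.r_[np.zeros(n), np.ones(n)]
            votes = np.clip(np.r_[rng.normal(0.4, 0.15, n), rng.normal(0.6, 0.15, n)], 0, 1)
            afp = np.r_[rng.lognormal(1.5, 1, n), rng.lognormal(3.0, 1.5, n)]
            scores, _ = combine_afp_ann(afp, votes, y)
            best = max(
                roc_auc(votes[y == 1], votes[y == 0]), roc_auc(afp[y == 1], afp[y == 0])
            )
            deficits.append(roc_auc(scores[y == 1], scores[y == 0]) - best)
        assert min(deficits) >= -0.02

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.zeros(30), np.ones(30)]
        votes = rng.random(60)
        afp = rng.lognormal(2, 1, 60)
        a = AfpAnnCombiner().fit(afp, votes, y).coefficients
        b = AfpAnnCombiner().fit(afp, votes, y).coefficients
        pd.testing.assert_series_equal(a, b)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValidationError):
            AfpAnnCombiner().fit([1.0, 2.0], [0.1, 0.9], [1.0, 1.0])

    def test_or_rule_positive_if_either_detector_fires(self):
        calls = AfpAnnCombiner.or_rule([500.0, 10.0, 10.0], [0.1, 0.9, 0.1])
        assert calls.tolist() == [1.0, 1.0, 0.0]


@pytest.fixture()
def cohort_scores():
    rng = np.random.default_rng(9)
    groups = ["HCC"] * 60 + ["cirrhotic"] * 30 + ["healthy"] * 40
    meta = toy_metadata(groups)
    meta.loc[meta["group"] == "HCC", "afp_ng_ml"] = rng.lognormal(5, 2, 60)
    meta.loc[meta["group"] != "HCC", "afp_ng_ml"] = rng.lognormal(1.5, 0.7, 70)
    meta.loc[meta["group"] == "HCC", "bclc_stage"] = rng.choice(
        ["0", "A", "B", "C"], size=60, p=[0.1, 0.4, 0.25, 0.25]
    )
    meta.loc[meta["group"] == "HCC", "hbsag"] = rng.choice(["pos", "neg"], 60, p=[0.7, 0.3])
    votes = pd.Series(
        np.where(np.array(groups) == "HCC", rng.beta(5, 2, 130), rng.beta(2, 5, 130)),
        index=meta["sample_id"],
    )
    return meta, votes


class TestStratifiedReport:
    def test_identity_stratum_matches_direct_computation(self, cohort_scores):
        meta, votes = cohort_scores
        report = stratified_report(meta, votes).set_index(["stratum", "comparison", "detector"])
        hcc = meta["group"] == "HCC"
        for ctrl_groups, comp in [
            (("healthy", "cirrhotic"), "HCC_vs_healthy+cirrhotic"),
            (("healthy",), "HCC_vs_healthy"),
        ]:
            ctrl = meta["group"].isin(ctrl_groups)
            expected = roc_auc(votes[hcc.to_numpy()], votes[ctrl.to_numpy()])
            assert report.loc[("all", comp, "ANN"), "auc"] == pytest.approx(expected)

    def test_stage_strata_partition_staged_cases(self, cohort_scores):
        meta, votes = cohort_scores
        report = stratified_report(meta, votes)
        afp_rows = report[
            (report["detector"] == "AFP") & (report["comparison"] == "HCC_vs_healthy")
        ].set_index("stratum")
        staged = afp_rows.loc[["BCLC 0/A", "BCLC B", "BCLC C"], "n_case"].sum()
        assert staged == afp_rows.loc["all", "n_case"]

    def test_empty_stratum_yields_na_row_with_counts(self, cohort_scores):
        meta, votes = cohort_scores
        meta = meta.copy()
        meta["hbsag"] = "pos"  # no HBsAg- cases remain
        report = stratified_report(meta, votes).set_index(["stratum", "comparison", "detector"])
        row = report.loc[("HBsAg-", "HCC_vs_healthy", "ANN")]
        assert row["n_case"] == 0
        assert np.isnan(row["auc"]) and np.isnan(row["sensitivity"])

    def test_operating_points_lie_on_the_empirical_roc(self, cohort_scores):
        meta, votes = cohort_scores
        report = stratified_report(meta, votes)
        row = report[
            (report["stratum"] == "all")
            & (report["comparison"] == "HCC_vs_healthy+cirrhotic")
            & (report["detector"] == "ANN")
        ].iloc[0]
        hcc = (meta["group"] == "HCC").to_numpy()
        ctrl = ~hcc
        curve = roc_curve_points(votes[hcc], votes[ctrl])
        match = curve[
            np.isclose(curve["sensitivity"], row["sensitivity"])
            & np.isclose(curve["specificity"], row["specificity"])
        ]
        sens, spec = sens_spec_at(votes[hcc], votes[ctrl], row["operating_threshold"])
        assert len(match) >= 1 or (sens, spec) == (row["sensitivity"], row["specificity"])

    def test_afp_stratum_uses_only_flagged_cases(self, cohort_scores):
        meta, votes = cohort_scores
        report = stratified_report(meta, votes).set_index(["stratum", "comparison", "detector"])
        n_afp_neg = int(
            ((meta["group"] == "HCC") & (meta["afp_ng_ml"] < 20)).sum()
        )
        assert report.loc[("AFP-", "HCC_vs_healthy", "ANN"), "n_case"] == n_afp_neg
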