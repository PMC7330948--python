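"""Discovery and test-phase marker filters, seropositivity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seropanel import (
    LITERATURE_AUTOANTIGENS,
    ValidationError,
    assemble_focused_panel,
    discovery_filter,
    positive_ratio,
    sensitivity_at_specificity,
)
from seropanel import test_phase_filter as run_test_phase_filter
from seropanel.screening import test_phase_hits as collect_hits

from conftest import toy_metadata, toy_signal_matrix


class TestPositiveRatio:
    def test_cases_at_control_mean_are_never_positive(self):
        ratio, _ = positive_ratio([3.0, 3.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert ratio == 0.0

    def test_zero_variance_controls_degenerate_but_computed(self):
        with pytest.warns(UserWarning, match="zero control variance"):
            ratio, threshold = positive_ratio([2.0, 2.0], [1.0, 1.0, 1.0, 1.0])
        assert ratio == 1.0
        assert threshold == 1.0

    def test_mean_plus_two_sd_hand_computation(self):
        ratio, threshold = positive_ratio([7.0, 5.0, 6.2, 1.0], [1, 2, 3, 4, 5])
        assert threshold == pytest.approx(3 + 2 * np.std([1, 2, 3, 4, 5], ddof=1))
        assert threshold == pytest.approx(6.16227766, abs=1e-6)
        assert ratio == 0.5

    def test_requires_two_controls(self):
        with pytest.raises(ValidationError):
            positive_ratio([1.0], [2.0])

    @given(
        case=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        control=st.lists(st.floats(-50, 50), min_size=2, max_size=20),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_ratio_non_increasing_in_sd_multiplier(self, case, control):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratios = [positive_ratio(case, control, sd_multiplier=k)[0] for k in (0.5, 1, 2, 3)]
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))


class TestSensitivityAtSpecificity:
    def test_perfect_separation(self):
        sens, _ = sensitivity_at_specificity([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert sens == 1.0

    def test_identical_constant_groups(self):
        sens, _ = sensitivity_at_specificity([5.0, 5.0], [5.0, 5.0, 5.0])
        assert sens == 0.0

    def test_enumerated_threshold_example(self):
        sens, threshold = sensitivity_at_specificity(
            [9.5, 10.5, 8.0, 11.0], list(range(1, 11)), min_spec=0.9
        )
        assert threshold == 9.0
        assert sens == 0.75

    def test_min_spec_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_at_specificity([1.0], [2.0], min_spec=1.2)

    @given(data=st.data())
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_sensitivity_non_increasing_in_min_spec(self, data):
        case = data.draw(st.lists(st.floats(-10, 10), min_size=2, max_size=15))
        control = data.draw(st.lists(st.floats(-10, 10), min_size=2, max_size=15))
        sens = [
            sensitivity_at_specificity(case, control, min_spec=s)[0]
            for s in (0.5, 0.7, 0.9, 1.0)
        ]
        assert all(a >= b for a, b in zip(sens, sens[1:]))


class TestDiscoveryFilter:
    def _planted(self, shift, n=50, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(0.3, 0.5, size=(2 * n, 8))
        base[:n, 0] *= np.exp(shift)  # first n rows are HCC, protein 0 planted
        matrix = toy_signal_matrix(base)
        meta = toy_metadata(["HCC"] * n + ["healthy"] * n)
        return matrix, meta

    def test_overwhelming_effect_passes_all_three_criteria(self):
        matrix, meta = self._planted(2.0)
        out = discovery_filter(matrix, meta).set_index("protein_id")
        row = out.loc["M000"]
        assert row["passes_discovery"]
        assert row["p_value"] <= 0.05 and row["fold_change"] >= 1.2
        assert row["positive_ratio"] >= 0.10

    def test_small_fold_change_fails_despite_significance(self):
        rng = np.random.default_rng(1)
        n = 4000  # huge n: tiny shift is significant but FC ~ 1.05 < 1.2
        case = rng.normal(1.05, 0.2, size=(n, 1))
        control = rng.normal(1.00, 0.2, size=(n, 1))
        matrix = toy_signal_matrix(np.vstack([case, control]).clip(min=0.01))
        meta = toy_metadata(["HCC"] * n + ["healthy"] * n)
        out = discovery_filter(matrix, meta).iloc[0]
        assert out["p_value"] <= 0.05
        assert out["fold_change"] < 1.2
        assert not out["passes_discovery"]

    def test_pass_set_shrinks_under_stricter_criteria(self):
        matrix, meta = self._planted(0.4, n=40, seed=3)
        base = discovery_filter(matrix, meta)
        base_set = set(base.loc[base["passes_discovery"], "protein_id"])
        for kwargs in ({"alpha": 0.01}, {"fc_min": 1.5}, {"ratio_min": 0.3}):
            strict = discovery_filter(matrix, meta, **kwargs)
            strict_set = set(strict.loc[strict["passes_discovery"], "protein_id"])
            assert strict_set <= base_set

    def test_unnormalized_matrix_rejected(self):
        matrix, meta = self._planted(2.0)
        matrix.normalized = False
        with pytest.raises(ValidationError):
            discovery_filter(matrix, meta)

    def test_missing_group_rejected(self):
        matrix, _ = self._planted(2.0)
        meta = toy_metadata(["HCC"] * 100)
        with pytest.raises(ValidationError):
            discovery_filter(matrix, meta)


def test_welch_p_matches_permutation_oracle():
    """On a small instance the Welch p-value agrees with a permutation
    test of the same statistic within Monte-Carlo error."""
    rng = np.random.default_rng(12)
    case = rng.normal(0.8, 1.0, 12)
    control = rng.normal(0.0, 1.0, 12)
    p_welch = stats.ttest_ind(case, control, equal_var=False).pvalue
    perm = stats.permutation_test(
        (case, control),
        lambda a, b, axis=-1: stats.ttest_ind(a, b, axis=axis, equal_var=False).statistic,
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=20000,
        rng=0,
    )
    assert abs(p_welch - perm.pvalue) < 0.04


class TestTestPhaseFilter:
    def test_marker_discriminating_both_controls_labelled_both(self, small_matrix):
        matrix, metadata, truth = small_matrix  # cirrhosis_leak = 0, strong effect
        table = run_test_phase_filter(matrix, metadata)
        labels = table.drop_duplicates("protein_id").set_index("protein_id")["hit_class"]
        assert all(labels[pid] == "both" for pid in truth)

    def test_full_leak_marker_fails_versus_cirrhotic(self):
        rng = np.random.default_rng(2)
        n = 60
        values = rng.lognormal(0.3, 0.5, size=(3 * n, 6))
        values[:n, 0] *= np.e  # HCC elevated
        values[n:2 * n, 0] *= np.e  # cirrhotic equally elevated (leak = 1)
        matrix = toy_signal_matrix(values)
        meta = toy_metadata(["HCC"] * n + ["cirrhotic"] * n + ["healthy"] * n)
        table = run_test_phase_filter(matrix, meta).set_index(["protein_id", "comparison"])
        assert not table.loc[("M000", "HCC_vs_cirrhotic"), "passes_test"]
        assert table.loc[("M000", "HCC_vs_healthy"), "passes_test"]
        labels = table.reset_index().drop_duplicates("protein_id").set_index("protein_id")
        assert labels.loc["M000", "hit_class"] == "healthy-only"

    def test_planted_markers_recovered_in_both_class(self):
        """Strong planted both-type markers are recovered at large n."""
        from seropanel import SimulationConfig, generate_cohort, normalize_signals, snr_matrix

        recovered = 0
        n_truth = 0
        for seed in (21, 22):
            cfg = SimulationConfig(
                n_hcc=250, n_cirrhotic=125, n_healthy=125, n_proteins=100, n_informative=10,
                effect_size=1.5, cirrhosis_leak=0.0, seed=seed,
            )
            spots, meta, truth = generate_cohort(cfg)
            matrix = normalize_signals(snr_matrix(spots, channel="IgG"))
            table = run_test_phase_filter(matrix, meta)
            both = set(
                table.loc[table["hit_class"] == "both", "protein_id"]
            )
            recovered += len(both & truth)
            n_truth += len(truth)
        assert recovered >= 0.9 * n_truth
        assert set(collect_hits(table)) >= both


def test_focused_panel_union_deduplicates():
    screened = [f"P{i:03d}" for i in range(5)] + [LITERATURE_AUTOANTIGENS[0]]
    panel = assemble_focused_panel(screened)
    assert len(panel) == 5 + len(LITERATURE_AUTOANTIGENS)
    assert panel[:5] == screened[:5]
    assert len(set(panel)) == len(panel)
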