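"""Label analytics: proportions, pairs, hourly/cumulative curves, CV, stats."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vigilscore import (
    LabelSequence,
    coefficient_of_variance,
    cumulative_state_curve,
    difference_wave_test,
    hourly_distribution,
    state_correlogram,
    state_proportions,
    transition_pair_counts,
)

label_strings = st.text(alphabet="abclmnoN", min_size=2, max_size=300)


class TestProportions:
    def test_simple_counts(self):
        props = state_proportions(LabelSequence("aaam", 1.0))
        assert props["a"] == 0.75
        assert props["m"] == 0.25
        assert props.drop(["a", "m"]).sum() == 0

    def test_all_noise(self):
        assert state_proportions(LabelSequence("NNNN", 1.0))["N"] == 1.0

    @given(label_strings)
    def test_fractions_sum_to_one(self, labels):
        assert state_proportions(LabelSequence(labels, 1.0)).sum() == pytest.approx(1.0)

    def test_scheduled_fraction_recovered_after_scoring(self, short_recording):
        from vigilscore import score_recording

        rec, truth = short_recording
        props = state_proportions(score_recording(rec))
        want = state_proportions(truth)
        assert np.max(np.abs(props - want)) <= 0.05


class TestTransitionPairs:
    def test_pair_counts_and_conservation(self):
        mat = transition_pair_counts(LabelSequence("aab", 1.0))
        assert mat.loc["a", "a"] == 1
        assert mat.loc["a", "b"] == 1
        assert mat.to_numpy().sum() == 2

    def test_matrix_enumerates_64_ordered_pairs(self):
        mat = transition_pair_counts(LabelSequence("am", 1.0))
        assert mat.shape == (8, 8)
        assert mat.size == 64
        assert "U" not in mat.index and "U" not in mat.columns

    def test_noise_pairs_can_be_excluded_from_display(self):
        mat = transition_pair_counts(LabelSequence("aNa", 1.0), exclude_noise=True)
        assert mat.to_numpy().sum() == 0

    @given(label_strings)
    def test_total_equals_epochs_minus_one(self, labels):
        mat = transition_pair_counts(LabelSequence(labels, 1.0))
        assert mat.to_numpy().sum() == len(labels) - 1


class TestHourlyAndCumulative:
    def test_two_full_hours_of_wake(self):
        table = hourly_distribution(
            LabelSequence("a" * 7200, 1.0), datetime(2024, 5, 1, 9, 0)
        )
        assert len(table) == 2
        assert (table["a"] == 3600).all()

    def test_partial_first_hour(self):
        table = hourly_distribution(
            LabelSequence("a" * 3600, 1.0), datetime(2024, 5, 1, 9, 30)
        )
        assert table["a"].iloc[0] == 1800

    def test_dark_phase_flag_follows_lights_off(self):
        table = hourly_distribution(
            LabelSequence("a" * (6 * 3600), 1.0),
            datetime(2024, 5, 1, 12, 0),
            lights_off_hour=14,
        )
        assert list(table["phase"]) == ["light", "light", "dark", "dark", "dark", "dark"]

    def test_cumulative_curve_is_monotone_and_conserves_totals(self):
        labels = LabelSequence("am" * 3600, 1.0)  # 2 h alternating
        curve = cumulative_state_curve(labels, "m")
        assert np.all(np.diff(curve) >= 0)
        assert curve[-1] == 3600

    def test_absent_state_gives_zero_curve(self):
        curve = cumulative_state_curve(LabelSequence("a" * 100, 1.0), "o")
        assert np.all(curve == 0)


class TestCV:
    def test_constant_sample_has_zero_cv(self):
        assert coefficient_of_variance([2.0, 2.0, 2.0]) == 0.0

    def test_two_point_sample_by_formula(self):
        # sd = sqrt(2), mean = 2
        assert coefficient_of_variance([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    @given(st.floats(0.001, 1000.0))
    def test_cv_is_scale_invariant(self, c):
        x = np.array([1.0, 2.0, 4.0])
        assert coefficient_of_variance(c * x) == pytest.approx(
            coefficient_of_variance(x)
        )

    def test_zero_mean_is_an_error(self):
        with pytest.raises(ValueError):
            coefficient_of_variance([-1.0, 1.0])

    def test_splitting_awake_substates_lowers_their_cv(self, rng):
        """Pooled awake band power varies more than within any substate."""
        a1 = rng.normal(10.0, 1.0, 200)  # delta power of a1 epochs
        a3 = rng.normal(3.0, 0.3, 200)  # of a3 epochs
        pooled = np.concatenate([a1, a3])
        assert coefficient_of_variance(a1) < coefficient_of_variance(pooled)
        assert coefficient_of_variance(a3) < coefficient_of_variance(pooled)


class TestCorrelogram:
    def test_complementary_states_correlate_minus_one(self, rng):
        x = rng.uniform(0.2, 0.5, 20)
        table = pd.DataFrame({"a": x, "m": 0.8 - x})
        res = state_correlogram(table)
        assert res.r.loc["a", "m"] == pytest.approx(-1.0)
        assert res.significant.loc["a", "m"]

    def test_independent_columns_are_not_flagged(self, rng):
        table = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        res = state_correlogram(table)
        off = ~np.eye(4, dtype=bool)
        assert np.abs(res.r.to_numpy()[off]).max() < 0.5
        assert not res.significant.to_numpy()[off].any()

    def test_genotype_covariate_drives_strong_negative_correlation(self, rng):
        genotype = np.repeat([0, 1, 2], 10).astype(float)
        nrem1 = 0.4 - 0.08 * genotype + 0.02 * rng.standard_normal(30)
        res = state_correlogram(pd.DataFrame({"genotype": genotype, "m": nrem1}))
        assert res.r.loc["genotype", "m"] < -0.7
        assert res.significant.loc["genotype", "m"]

    def test_constant_column_is_masked_undefined(self, rng):
        table = pd.DataFrame({"a": rng.standard_normal(10), "k": np.ones(10)})
        res = state_correlogram(table)
        assert np.isnan(res.r.loc["a", "k"])
        assert not res.significant.loc["a", "k"]

    def test_fewer_than_three_subjects_is_an_error(self):
        with pytest.raises(ValueError):
            state_correlogram(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestDifferenceWave:
    def test_identical_groups_give_empty_mask(self, rng):
        a = rng.standard_normal((10, 65))
        assert not difference_wave_test(a, a.copy()).any()

    def test_huge_offset_rejects_everywhere(self, rng):
        a = rng.standard_normal((10, 65))
        b = a + 10.0
        assert difference_wave_test(a, b).all()

    def test_single_subject_group_is_an_error(self, rng):
        with pytest.raises(ValueError):
            difference_wave_test(rng.standard_normal((1, 65)), rng.standard_normal((10, 65)))
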