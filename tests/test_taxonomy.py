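import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flankcrowd.exceptions import (
    DegenerateRangeError,
    InvalidLatencyError,
    InvalidResponseError,
    MissingColumnError,
)
from flankcrowd.taxonomy import (
    NO_RESPONSE,
    classify_error,
    classify_trials,
    composite_score,
    crowding_indices,
    error_summary,
    inverse_transform,
    standardize_scores,
    trim_latencies,
    validate_trials,
)

from conftest import make_trial, trials_frame


class TestClassifyError:
    @pytest.mark.parametrize(
        "target,flankers,response,expected",
        [
            ("N", ("Z", "H"), "Z", "B"),  # flanker named
            ("M", ("Y", "T"), "V", "C"),  # letter in neither target nor flankers
            ("T", ("3", "6"), "C", "C"),  # digit flankers, integration error
            ("N", ("Z", "H"), "N", "correct"),
            ("N", ("Z", "H"), NO_RESPONSE, "A"),
            ("N", ("Z", "H"), "H", "B"),
        ],
    )
    def test_worked_examples(self, target, flankers, response, expected):
        assert classify_error(target, flankers, response) == expected

    def test_invariant_to_flanker_order(self):
        for resp in ("Z", "H", "V", NO_RESPONSE, "N"):
            assert classify_error("N", ("Z", "H"), resp) == classify_error(
                "N", ("H", "Z"), resp
            )

    def test_unknown_response_symbol_rejected(self):
        with pytest.raises(InvalidResponseError):
            classify_error("N", ("Z", "H"), "Q")  # not in the permitted alphabet

    def test_classes_partition_trials(self, rng):
        rows = []
        pool = ["N", "Z", "H", "V", NO_RESPONSE]
        for _ in range(200):
            rows.append(make_trial(response=pool[rng.integers(len(pool))]))
        t = classify_trials(trials_frame(rows))
        counts = t["error_class"].value_counts()
        assert counts.sum() == len(t)
        assert set(counts.index) <= {"correct", "A", "B", "C"}

    def test_missing_column_raises(self):
        with pytest.raises(MissingColumnError):
            validate_trials(pd.DataFrame({"participant_id": []}))


class TestErrorSummary:
    def test_one_error_of_each_type(self):
        rows = [
            make_trial(response="N"),
            make_trial(response=NO_RESPONSE),
            make_trial(response="Z"),
            make_trial(response="V"),
        ]
        s = error_summary(classify_trials(trials_frame(rows)))
        assert (s.prop_a, s.prop_b, s.prop_c) == (1 / 3, 1 / 3, 1 / 3)
        assert s.error_rate == 0.75

    def test_all_correct_leaves_proportions_undefined(self):
        s = error_summary(classify_trials(trials_frame([make_trial()] * 5)))
        assert s.error_rate == 0.0
        assert s.prop_a is None and s.prop_b is None and s.prop_c is None

    def test_planted_counts(self, rng):
        rows = (
            [make_trial(response=NO_RESPONSE) for _ in range(6)]
            + [make_trial(response="Z") for _ in range(8)]
            + [make_trial(response="V") for _ in range(6)]
            + [make_trial() for _ in range(80)]
        )
        s = error_summary(classify_trials(trials_frame(rows)))
        assert s.n_valid == 100 and s.n_errors == 20
        assert (s.prop_a, s.prop_b, s.prop_c) == (0.30, 0.40, 0.30)
        assert s.error_rate == pytest.approx(0.20)


class TestTrimLatencies:
    def test_two_sd_rule_removes_only_the_outlier(self, latency_fixture):
        retained, ledger = trim_latencies(latency_fixture)
        # mean ~909, sd ~1357: only 5000 ms exceeds mean + 2 sd
        assert ledger["n_removed_stage1"] == 0
        assert ledger["n_removed_stage2"] == 1
        assert 5000.0 not in retained["latency_ms"].to_numpy()
        assert len(retained) == 10

    def test_equal_latencies_remove_nothing(self):
        t = trials_frame([make_trial(latency=700.0) for _ in range(8)])
        _, ledger = trim_latencies(t)
        assert ledger["n_removed_stage2"] == 0

    def test_stage1_removes_errors_prompts_distractions(self):
        rows = [
            make_trial(response="Z", latency=500.0),  # error
            make_trial(prompted=True, latency=500.0),
            make_trial(distracted=True, latency=500.0),
            make_trial(latency=500.0),
            make_trial(latency=520.0),
        ]
        retained, ledger = trim_latencies(trials_frame(rows))
        assert ledger["n_removed_stage1"] == 3
        assert len(retained) == 2

    def test_single_latency_skips_stage2(self):
        rows = [make_trial(participant="P09", latency=444.0)]
        retained, ledger = trim_latencies(trials_frame(rows))
        assert ledger["stage2_skipped_participants"] == ["P09"]
        assert len(retained) == 1

    def test_conservation_identity_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            rows = []
            for i in range(n):
                rows.append(
                    make_trial(
                        participant=f"P{rng.integers(3)}",
                        response=["N", "Z", NO_RESPONSE][rng.integers(3)],
                        prompted=bool(rng.random() < 0.2),
                        distracted=bool(rng.random() < 0.1),
                        latency=float(rng.lognormal(6.5, 0.8)),
                    )
                )
            _, ledger = trim_latencies(trials_frame(rows))
            assert (
                ledger["n_removed_stage1"]
                + ledger["n_removed_stage2"]
                + ledger["n_retained"]
                == ledger["n_total"]
                == n
            )


class TestInverseTransform:
    def test_values(self):
        assert inverse_transform(800.0) == pytest.approx(1.25)
        assert inverse_transform(1000.0) == pytest.approx(1.0)

    @given(st.floats(1.0, 60000.0), st.floats(1.0, 60000.0))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_decreasing(self, a, b):
        if a < b:
            assert inverse_transform(a) > inverse_transform(b)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidLatencyError):
            inverse_transform(0.0)
        with pytest.raises(InvalidLatencyError):
            inverse_transform(np.array([500.0, -2.0]))


class TestStandardizeScores:
    def test_anchors_and_midpoint(self):
        out = standardize_scores([2.0, 6.0, 10.0])
        assert out[0] == 0.0 and out[2] == 100.0 and out[1] == 50.0

    def test_affine_invariance(self, rng):
        x = rng.random(15)
        assert np.allclose(standardize_scores(3.5 * x + 2.0), standardize_scores(x))

    def test_degenerate_range_raises(self):
        with pytest.raises(DegenerateRangeError):
            standardize_scores([4.0, 4.0, 4.0])
        with pytest.raises(DegenerateRangeError):
            standardize_scores([4.0])

    def test_composite_is_mean_of_standardized_members(self):
        df = pd.DataFrame({"t1": [0.0, 5.0, 10.0], "t2": [10.0, 10.0, 30.0]})
        comp = composite_score(df)
        assert comp.tolist() == [0.0, 25.0, 100.0]


class TestCrowdingIndices:
    def _trials(self, task, n_spaced_correct, n_condensed_correct, n=20, pid="P01",
                polarity="none"):
        rows = []
        for spacing, ncorr in (("spaced", n_spaced_correct), ("condensed", n_condensed_correct)):
            for i in range(n):
                rows.append(
                    make_trial(
                        participant=pid,
                        task=task,
                        spacing=spacing,
                        polarity=polarity,
                        response="N" if i < ncorr else "V",
                    )
                )
        return rows

    def test_spacing_index_is_raw_correct_difference(self):
        t = trials_frame(self._trials(3, 20, 14))
        idx = crowding_indices(t)
        assert idx.loc[0, "spacing_shape"] == 6

    def test_identical_accuracy_gives_zero_indices(self):
        rows = self._trials(3, 12, 12) + self._trials(4, 12, 12)
        idx = crowding_indices(trials_frame(rows))
        assert idx.loc[0, "spacing_shape"] == 0
        assert idx.loc[0, "spacing_shapes_numbers"] == 0

    def test_missing_task_reported_missing_not_zero(self):
        idx = crowding_indices(trials_frame(self._trials(3, 15, 10)))
        assert np.isnan(idx.loc[0, "polarity"])
        assert np.isnan(idx.loc[0, "spacing_number"])

    def test_polarity_condensed_uses_condensed_trials_only(self):
        # task 5 (same): condensed 10, spaced 20 correct; task 6 (reverse):
        # condensed 16, spaced 20 -> polarity_condensed = 16 - 10 = 6
        rows = self._trials(5, 20, 10, polarity="same") + self._trials(
            6, 20, 16, polarity="reverse"
        )
        idx = crowding_indices(trials_frame(rows))
        assert idx.loc[0, "polarity_condensed"] == 6
        assert idx.loc[0, "polarity"] == (36 - 30)

    def test_prompted_trials_do_not_count(self):
        rows = self._trials(3, 15, 15)
        rows.append(make_trial(task=3, spacing="spaced", response="N", prompted=True))
        idx = crowding_indices(trials_frame(rows))
        assert idx.loc[0, "spacing_shape"] == 0
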