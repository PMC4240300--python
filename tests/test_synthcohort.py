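import json

import numpy as np
import pandas as pd
import pytest

from flankcrowd.synthcohort import (
    CohortConfig,
    MechanismParams,
    default_group_params,
    planted_truth,
    simulate_cohort,
    simulate_error_trials,
)
from flankcrowd.taxonomy import classify_trials, error_summary, trim_latencies


class TestMechanismParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            MechanismParams(w_avg=-0.1)
        with pytest.raises(ValueError):
            MechanismParams(w_avg=0.6, w_subst=0.5, w_mask=0.1)
        with pytest.raises(ValueError):
            MechanismParams(rho=1.5)

    def test_strength_zero_at_or_beyond_critical_spacing(self):
        p = MechanismParams(critical_spacing_deg=1.2)
        assert p.crowding_strength(1.2) == 0.0
        assert p.crowding_strength(2.0) == 0.0
        assert p.crowding_strength(0.0) == 1.0
        assert p.crowding_strength(0.1) > p.crowding_strength(1.0)

    def test_reverse_polarity_attenuates_by_rho(self):
        p = MechanismParams(rho=0.5)
        g = 0.1
        assert p.crowding_strength(g, "reverse") == pytest.approx(
            0.5 * p.crowding_strength(g, "same")
        )
        assert MechanismParams(rho=0.0).crowding_strength(g, "reverse") == 0.0


class TestCohortStructure:
    def test_same_seed_gives_identical_tables(self, glyphset):
        cfg = CohortConfig(seed=7, n_pca=2, n_tad=1, n_control=1)
        t1 = simulate_cohort(cfg, glyphset)
        t2 = simulate_cohort(cfg, glyphset)
        pd.testing.assert_frame_equal(t1, t2)

    def test_default_group_sizes(self, cohort_default):
        sizes = cohort_default.groupby("group")["participant_id"].nunique()
        assert sizes["PCA"] == 26 and sizes["tAD"] == 17 and sizes["control"] == 14

    def test_task_structure_per_participant(self, cohort_default):
        one = cohort_default[cohort_default["participant_id"] == "PCA01"]
        assert one[one["task"] == 1].shape[0] == 20
        for task in (2, 3, 4, 5, 6):
            tt = one[one["task"] == task]
            assert len(tt) == 24
            assert tt["spacing_condition"].value_counts().to_dict() == {
                "condensed": 12,
                "spaced": 12,
            }
        assert (one[one["task"] == 6]["polarity_condition"] == "reverse").all()

    def test_controls_make_no_flanked_errors(self, cohort_default):
        ctl = classify_trials(cohort_default[cohort_default["group"] == "control"])
        flanked = ctl[ctl["task"] != 1]
        assert flanked["correct"].all()

    def test_pca_condensed_worse_than_spaced(self, cohort_default):
        pca = classify_trials(cohort_default[cohort_default["group"] == "PCA"])
        flanked = pca[pca["task"] != 1]
        acc = flanked.groupby("spacing_condition")["correct"].mean()
        assert acc["condensed"] < acc["spaced"]

    def test_no_crowding_when_gap_beyond_critical_spacing(self, glyphset):
        params = MechanismParams(w_avg=0.3, w_subst=0.3, w_mask=0.3,
                                 critical_spacing_deg=0.05, lapse_rate=0.0)
        cfg = CohortConfig(seed=3, n_pca=3, n_tad=1, n_control=1,
                           group_params={**default_group_params(), "PCA": params})
        t = classify_trials(simulate_cohort(cfg, glyphset))
        pca_flanked = t[(t["group"] == "PCA") & (t["task"] != 1)]
        # both gaps (0.1, 1.0 deg) exceed the 0.05 deg interference zone
        assert pca_flanked["correct"].all()

    def test_flankers_differ_from_target_and_each_other(self, cohort_default):
        fl = cohort_default[cohort_default["task"] != 1]
        assert (fl["flanker_left"] != fl["target"]).all()
        assert (fl["flanker_left"] != fl["flanker_right"]).all()

    def test_same_flanker_pair_under_both_spacings(self, cohort_default):
        one = cohort_default[
            (cohort_default["participant_id"] == "PCA02") & (cohort_default["task"] == 2)
        ]
        pairs = one.groupby("target")[["flanker_left", "flanker_right"]].nunique()
        assert (pairs <= 1).all().all()


class TestMechanismComposition:
    def test_error_type_composition_tracks_weights_on_letter_flankers(self, glyphset):
        """On letter-flanker tasks with weights 0.3 (mask), 0.36 (subst),
        0.34 (avg), Type A/B/C proportions approach the weights at large n."""
        params = MechanismParams(
            w_mask=0.30, w_subst=0.36, w_avg=0.34, critical_spacing_deg=1e9,
            beta_avg=4.0,
        )
        cfg = CohortConfig(
            seed=11, n_pca=20, n_tad=1, n_control=1,
            items_per_task=100, participant_sd=0.0, distract_prob=0.0,
            group_params={**default_group_params(), "PCA": params},
        )
        t = classify_trials(simulate_cohort(cfg, glyphset))
        letters = t[(t["group"] == "PCA") & (t["task"].isin([2, 5, 6])) &
                    (t["polarity_condition"] != "reverse")]
        assert len(letters) >= 4000
        s = error_summary(letters)
        assert s.prop_a == pytest.approx(0.30, abs=0.05)
        assert s.prop_b == pytest.approx(0.36, abs=0.05)
        assert s.prop_c == pytest.approx(0.34, abs=0.05)

    def test_trimming_recovers_planted_outlier_fraction(self, glyphset):
        cfg = CohortConfig(seed=5, n_pca=1, n_tad=1, n_control=14,
                           outlier_prob=0.05, distract_prob=0.0)
        t = simulate_cohort(cfg, glyphset)
        ctl = t[t["group"] == "control"]
        _, ledger = trim_latencies(classify_trials(ctl))
        removed_frac = ledger["n_removed_stage2"] / ledger["n_total"]
        # binomial error around the planted 5% contamination
        se = np.sqrt(0.05 * 0.95 / ledger["n_total"])
        assert abs(removed_frac - 0.05) < 4 * se + 0.01


class TestPlantedTruth:
    def test_pure_averaging_labelled(self):
        params = MechanismParams(w_avg=0.3, w_subst=0.0, w_mask=0.0)
        cfg = CohortConfig(seed=1, group_params={**default_group_params(), "PCA": params})
        truth = planted_truth(cfg)
        assert truth["groups"]["PCA"]["mechanism"] == "averaging"
        assert truth["groups"]["control"]["mechanism"] == "none"

    def test_weights_echoed_and_json_round_trip(self):
        cfg = CohortConfig(seed=2)
        truth = planted_truth(cfg)
        assert truth["groups"]["PCA"]["weights"] == {
            "w_avg": 0.105, "w_subst": 0.105, "w_mask": 0.09,
        }
        assert json.loads(json.dumps(truth)) == truth

    def test_seed_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            CohortConfig(seed="not-an-int")


class TestErrorTrialGenerator:
    def test_all_rows_are_bc_errors(self, glyphset):
        for mech in ("averaging", "substitution", "null"):
            t = classify_trials(simulate_error_trials(4, 6, mech, seed=2, glyphs=glyphset))
            assert t["error_class"].isin(["B", "C"]).all()

    def test_averaging_draws_avoid_array_letters(self, glyphset):
        t = simulate_error_trials(10, 20, "averaging", seed=4, glyphs=glyphset)
        assert (t["response"] != t["flanker_left"]).all()
        assert (t["response"] != t["flanker_right"]).all()

    def test_substitution_mostly_names_flankers(self, glyphset):
        t = classify_trials(simulate_error_trials(10, 20, "substitution", seed=4, glyphs=glyphset))
        assert (t["error_class"] == "B").mean() == pytest.approx(0.9, abs=0.08)

    def test_pure_averaging_limit_is_argmax_of_profile(self, glyphset):
        t = simulate_error_trials(3, 10, "averaging", seed=8, beta_avg=200.0, glyphs=glyphset)
        for row in t.itertuples(index=False):
            profile = glyphset.composite_profile(row.target, row.flanker_left, row.flanker_right)
            pool = {c: v for c, v in profile.items()
                    if c != row.target and c not in (row.flanker_left, row.flanker_right)}
            assert row.response == max(pool, key=pool.get)
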