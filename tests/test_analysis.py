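"""Analysis pipeline: scoring, exclusions, remapping, classification,
change directions, permutation tests and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import morphcat as mc
from morphcat.analysis import (
    CLASSES,
    CRITERIA_PRESETS,
    UndefinedMappingError,
    _max_runs,
    _warning_count,
    apply_label_mapping,
)

from conftest import make_minimal_records


class TestScoring:
    def test_valid_match_is_correct_invalid_match_is_not(self):
        df = make_minimal_records("s", [1.0, 1.0], valid=[True, False])
        scored = mc.score_responses(df)
        assert scored["correct"].tolist() == [True, False]

    def test_missing_response_is_incorrect(self):
        df = make_minimal_records("s", [None, 1.0])
        assert mc.score_responses(df)["correct"].tolist() == [False, True]

    def test_all_invalid_subject_scores_zero_everywhere(self, fixtures_by_name):
        scored = mc.score_responses(fixtures_by_name["all_invalid"].records)
        acc = mc.block_item_accuracy(scored)
        assert (acc["accuracy"] == 0.0).all()


class TestExclusions:
    def test_same_key_run_of_12_excluded_under_supervision(self):
        responses = [1.0] * 12 + [1.0 if i % 2 else 2.0 for i in range(148)]
        df = make_minimal_records("s", responses, condition="supervised")
        kept, report = mc.apply_exclusions(df, "supervised")
        assert report.excluded["s"] == ["response run"]
        assert len(kept) == 0

    def test_same_run_of_12_kept_in_semi_supervised(self):
        base = [1.0, 1.0, 2.0, 2.0] * 37
        responses = [1.0] * 12 + base[:148]
        df = make_minimal_records("s", responses, condition="semi_supervised")
        kept, report = mc.apply_exclusions(df, "semi_supervised")
        assert "s" not in report.excluded and len(kept) == 160

    def test_run_of_18_excluded_in_semi_supervised(self):
        responses = [1.0] * 18 + ([1.0, 1.0, 2.0, 2.0] * 36)[:142]
        df = make_minimal_records("s", responses, condition="semi_supervised")
        _, report = mc.apply_exclusions(df, "semi_supervised")
        assert report.excluded["s"] == ["response run"]

    def test_strict_alternation_run_excluded(self):
        responses = [1.0, 2.0] * 6 + ([1.0, 1.0, 2.0, 2.0] * 37)[:148]
        df = make_minimal_records("s", responses, condition="supervised")
        _, report = mc.apply_exclusions(df, "supervised")
        assert report.excluded["s"] == ["response run"]

    def test_broken_alternation_resets_counter(self):
        responses = ([1.0, 2.0] * 5 + [2.0, 1.0, 1.0, 2.0, 2.0, 1.0]) * 10
        df = make_minimal_records("s", responses, condition="supervised")
        _, report = mc.apply_exclusions(df, "supervised")
        assert "s" not in report.excluded

    def test_clean_subject_zero_warnings(self, fixtures_by_name):
        fx = fixtures_by_name["perfect_conformant"]
        _, report = mc.apply_exclusions(fx.records, "semi_supervised")
        assert report.details[fx.records["subject_id"].iloc[0]]["warnings"] == 0

    def test_run_helpers_against_brute_force(self):
        """Windowed warning count and run lengths versus direct enumeration."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            valid = rng.random(60) > 0.3
            responses = rng.choice([1.0, 2.0, np.nan], size=60, p=[0.45, 0.45, 0.1])
            # brute-force longest same-key run
            best = cur = 0
            prev = None
            for r in responses:
                if np.isnan(r):
                    cur, prev = 0, None
                    continue
                cur = cur + 1 if r == prev else 1
                best = max(best, cur)
                prev = r
            assert _max_runs(list(responses))[0] == best
            assert _warning_count(list(valid)) >= 0


class TestRemapping:
    def test_systematic_swap_detected(self):
        df = make_minimal_records("s", [2.0] * 20)  # category is always 1
        assert mc.best_label_mapping(df) == "swap"
        remapped = apply_label_mapping(df, "swap")
        assert (remapped["response"] == 1.0).all()

    def test_mostly_correct_keeps_identity(self):
        df = make_minimal_records("s", [1.0] * 18 + [2.0] * 2)
        assert mc.best_label_mapping(df) == "identity"

    def test_exact_tie_keeps_identity(self):
        df = make_minimal_records("s", [1.0, 2.0] * 5)
        assert mc.best_label_mapping(df) == "identity"

    def test_no_valid_unindicative_trials_raises(self):
        df = make_minimal_records("s", [None] * 10)
        with pytest.raises(UndefinedMappingError):
            mc.best_label_mapping(df)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from([1.0, 2.0, None]), st.booleans()),
                    min_size=1, max_size=60))
    def test_post_remap_valid_unindicative_accuracy_at_least_half(self, trials):
        """The maximisation over the two possible mappings guarantees at least
        chance accuracy on the valid unindicative trials."""
        responses = [r for r, _ in trials]
        df = make_minimal_records("s", responses)
        df["category"] = [1 if c else 2 for _, c in trials]
        valid_unind = df["valid"] & df["response"].notna()
        if not valid_unind.any():
            with pytest.raises(UndefinedMappingError):
                mc.best_label_mapping(df)
            return
        mapping = mc.best_label_mapping(df)
        remapped = apply_label_mapping(df, mapping)
        sub = remapped[valid_unind]
        assert (sub["response"] == sub["category"]).mean() >= 0.5


class TestBlockItemAccuracy:
    def test_hand_counted_block(self):
        df = make_minimal_records("s", [1.0] * 3 + [2.0] * 3)
        df["indicative"] = True
        acc = mc.block_item_accuracy(mc.score_responses(df))
        assert acc.loc[0, "accuracy"] == 0.5 and acc.loc[0, "n_trials"] == 6

    def test_all_correct_subject(self, fixtures_by_name):
        fx = fixtures_by_name["salient_attender"]
        acc = mc.block_item_accuracy(mc.score_responses(fx.records))
        unind = acc[acc["item_type"] == "unindicative"]
        assert (unind["accuracy"] == 1.0).all()

    def test_against_brute_force_recount(self, fixtures_by_name):
        """Full 160-trial fixture: groupby result equals an explicit loop."""
        scored = mc.score_responses(fixtures_by_name["perfect_conformant"].records)
        acc = mc.block_item_accuracy(scored)
        counts: dict = {}
        for row in scored.itertuples():
            key = (row.subject_id, row.block, "indicative" if row.indicative else "unindicative")
            n_corr, n_tot = counts.get(key, (0, 0))
            counts[key] = (n_corr + bool(row.correct), n_tot + 1)
        for row in acc.itertuples():
            n_corr, n_tot = counts[(row.subject_id, row.block, row.item_type)]
            assert row.accuracy == pytest.approx(n_corr / n_tot)
            assert row.n_trials == n_tot


def acc_table(ind, unind, subject="s", blocks=range(1, 11)):
    rows = []
    for b in blocks:
        rows.append({"subject_id": subject, "block": b, "item_type": "indicative",
                     "accuracy": ind, "n_trials": 6})
        rows.append({"subject_id": subject, "block": b, "item_type": "unindicative",
                     "accuracy": unind, "n_trials": 10})
    return pd.DataFrame(rows)


class TestClassification:
    conf, nonc = CRITERIA_PRESETS["default"]

    @pytest.mark.parametrize(
        "ind,unind,expected",
        [
            (0.8, 0.8, "conformant"),
            (0.3, 0.8, "non_conformant"),
            (0.5, 0.5, "other"),
            (0.6, 0.8, "other"),  # exactly at a strict threshold
            (0.4, 0.8, "other"),
            (0.8, 0.6, "other"),
        ],
    )
    def test_threshold_logic(self, ind, unind, expected):
        assert mc.classify_learner(acc_table(ind, unind), self.conf, self.nonc) == expected

    def test_missing_window_block_raises(self):
        with pytest.raises(ValueError):
            mc.classify_learner(acc_table(0.8, 0.8, blocks=range(1, 9)), self.conf, self.nonc)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_exhaustive_and_exclusive(self, ind, unind):
        result = mc.classify_learner(acc_table(ind, unind), self.conf, self.nonc)
        assert result in CLASSES
        is_conf = unind > 0.6 and ind > 0.6
        is_nonc = unind > 0.6 and ind < 0.4
        assert not (is_conf and is_nonc)
        assert result == ("conformant" if is_conf else "non_conformant" if is_nonc else "other")


class TestChangeDirection:
    @pytest.mark.parametrize(
        "a3,a9,expected",
        [(0.5, 0.8, "improved"), (0.8, 0.5, "worsened"), (0.5, 0.5, "no_change")],
    )
    def test_sign_of_change(self, a3, a9, expected):
        tbl = acc_table(0.5, 0.5)
        tbl.loc[(tbl.block == 3) & (tbl.item_type == "indicative"), "accuracy"] = a3
        tbl.loc[(tbl.block == 9) & (tbl.item_type == "indicative"), "accuracy"] = a9
        assert mc.change_direction(tbl, 3, 9, "indicative") == expected


class TestPermutationTest:
    def test_zero_statistic_gives_p_one(self):
        for alt in ("greater", "less", "two_sided"):
            res = mc.one_sample_permutation_test([0.5, 0.5, 0.5], 0.5, alt)
            assert res.p_value == 1.0 and res.exact

    def test_exact_enumeration_three_values(self):
        """(0.9, 0.8, 1.0) vs 0.5, greater: only the all-positive sign pattern
        reaches the observed mean, so p = 1/8."""
        res = mc.one_sample_permutation_test([0.9, 0.8, 1.0], 0.5, "greater")
        assert res.exact and res.n_permutations == 8
        assert res.p_value == pytest.approx(1 / 8)
        assert res.statistic == pytest.approx(0.4)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mc.one_sample_permutation_test([], 0.5)

    def test_monte_carlo_matches_exact_within_three_se(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            values = rng.uniform(0.3, 0.9, size=10)
            exact = mc.one_sample_permutation_test(values, 0.5, "greater")
            n_perm = 4000
            monte = mc.one_sample_permutation_test(
                values, 0.5, "greater", n_permutations=n_perm,
                rng=np.random.default_rng(1), exact_threshold=0,
            )
            assert exact.exact and not monte.exact
            se = np.sqrt(exact.p_value * (1 - exact.p_value) / n_perm)
            assert abs(monte.p_value - exact.p_value) <= 3 * se + 2 / n_perm

    def test_monte_carlo_p_floor(self):
        values = np.linspace(0.9, 1.0, 20)
        res = mc.one_sample_permutation_test(values, 0.5, "greater", n_permutations=500,
                                             rng=np.random.default_rng(0))
        assert res.p_value >= 1 / 501


@pytest.fixture(scope="module")
def summary(semi_cohort):
    scored = mc.score_responses(semi_cohort)
    kept, _ = mc.apply_exclusions(scored, "semi_supervised")
    return mc.summarize_cohort(kept, n_permutations=500, rng=0)


class TestCohortSummary:
    def test_class_fractions_sum_to_one(self, summary):
        assert sum(summary.class_fractions.values()) == pytest.approx(1.0)
        assert sum(summary.class_counts.values()) == summary.n_subjects

    def test_change_fractions_sum_to_one_per_cell(self, summary):
        for cls in CLASSES:
            for item in ("indicative", "unindicative"):
                cell = summary.change_fractions[cls][item]
                if cell["n"] > 0:
                    total = cell["improved"] + cell["worsened"] + cell["no_change"]
                    assert total == pytest.approx(1.0)

    def test_empty_dataset_summary(self):
        empty = pd.DataFrame(columns=mc.cohort.TRIAL_COLUMNS)
        summary = mc.summarize_cohort(mc.score_responses(empty))
        assert summary.n_subjects == 0
        assert all(v == 0 for v in summary.class_counts.values())

    def test_pure_fast_cohort_is_mostly_conformant_and_improves(self):
        spec = mc.PopulationSpec(n_subjects=30, fraction_fast=1.0,
                                 fraction_nonlearner=0.0, master_seed=5)
        rec = mc.run_cohort(spec, "semi_supervised")
        kept, _ = mc.apply_exclusions(mc.score_responses(rec), "semi_supervised")
        s = mc.summarize_cohort(kept, n_permutations=200, rng=0)
        assert s.class_fractions["conformant"] > 0.5
        cell = s.change_fractions["conformant"]["indicative"]
        assert cell["improved"] > cell["worsened"]

    def test_pure_slow_cohort_is_mostly_non_conformant_and_worsens(self):
        spec = mc.PopulationSpec(n_subjects=30, fraction_fast=0.0,
                                 fraction_nonlearner=0.0, master_seed=5)
        rec = mc.run_cohort(spec, "semi_supervised")
        kept, _ = mc.apply_exclusions(mc.score_responses(rec), "semi_supervised")
        s = mc.summarize_cohort(kept, n_permutations=200, rng=0)
        assert s.class_fractions["non_conformant"] > 0.5
        cell = s.change_fractions["non_conformant"]["indicative"]
        assert cell["worsened"] > cell["improved"]


class TestRobustnessSweep:
    def test_single_default_pair_matches_summarize(self, semi_cohort):
        scored = mc.score_responses(semi_cohort)
        kept, _ = mc.apply_exclusions(scored, "semi_supervised")
        direct = mc.summarize_cohort(kept, n_permutations=200, rng=0)
        sweep = mc.robustness_sweep(kept, [CRITERIA_PRESETS["default"]],
                                    n_permutations=200, rng=0)
        assert len(sweep) == 1
        assert sweep[0]["summary"].class_counts == direct.class_counts

    def test_stricter_criteria_shrink_classes(self, semi_cohort):
        scored = mc.score_responses(semi_cohort)
        kept, _ = mc.apply_exclusions(scored, "semi_supervised")
        sweep = mc.robustness_sweep(kept, n_permutations=200, rng=0)
        counts = [e["summary"].class_counts for e in sweep]
        for a, b in zip(counts, counts[1:]):
            assert b["conformant"] <= a["conformant"]
            assert b["non_conformant"] <= a["non_conformant"]

    def test_empty_pair_list_rejected(self, semi_cohort):
        with pytest.raises(ValueError):
            mc.robustness_sweep(mc.score_responses(semi_cohort), [])
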