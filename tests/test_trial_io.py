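"""Trial-log reading, per-fly aggregation, and the completion filter."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flychoice.trial_io import (
    ConfigError,
    DataError,
    FlyRecord,
    TrialRecord,
    aggregate_flies,
    filter_complete,
    read_fly_table,
    read_trials,
    write_fly_table,
    write_trials,
)


def _write(tmp_path, text, name="trials.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "fly_id\tgroup\tlane\ttrial\tlit_side\tscore\n"


class TestReadTrials:
    def test_direct_mapping_of_choice_words(self, tmp_path):
        p = _write(tmp_path, HEADER + "A\tControl\tL1\t1\tleft\ttoward\n")
        recs = read_trials(p, encoding_map={"toward": 1, "away": -1})
        assert recs == [TrialRecord(fly_id="A", group_label="Control",
                                    trial_index=1, score=1, lit_side="left",
                                    lane_id="L1")]

    def test_unmapped_choice_value_names_value_and_row(self, tmp_path):
        p = _write(tmp_path, HEADER + "A\tControl\tL1\t1\tleft\ttoward\n"
                                      "A\tControl\tL1\t2\tleft\tT\n")
        with pytest.raises(DataError, match=r"'T'.*row 2"):
            read_trials(p, encoding_map={"toward": 1, "away": -1})

    def test_duplicate_fly_trial_pair_rejected(self, tmp_path):
        p = _write(tmp_path, HEADER + "A\tControl\tL1\t1\tleft\t1\n"
                                      "A\tControl\tL1\t2\tleft\t1\n"
                                      "A\tControl\tL1\t2\tright\t-1\n")
        with pytest.raises(DataError, match=r"duplicate.*'A', 2"):
            read_trials(p)

    def test_missing_mapped_column_is_config_error(self, tmp_path):
        p = _write(tmp_path, "fly\tgrp\tscore\nA\tControl\t1\n")
        with pytest.raises(ConfigError):
            read_trials(p)

    def test_score_from_lit_and_chosen_side_pair(self, tmp_path):
        text = ("fly_id\tgroup\ttrial\tlit_side\tchosen_side\n"
                "A\tControl\t1\tleft\tleft\n"
                "A\tControl\t2\tright\tleft\n")
        p = _write(tmp_path, text)
        cmap = {"fly_id": "fly_id", "group_label": "group",
                "trial_index": "trial", "lit_side": "lit_side",
                "chosen_side": "chosen_side"}
        recs = read_trials(p, column_map=cmap)
        assert [r.score for r in recs] == [1, -1]

    def test_comma_dialect_autodetected(self, tmp_path):
        p = _write(tmp_path, "fly_id,group,lane,trial,lit_side,score\n"
                             "A,Control,L1,1,left,-1\n", name="trials.csv")
        assert read_trials(p)[0].score == -1


class TestAggregation:
    @pytest.mark.parametrize(
        "n_trials,n_toward,lcp,index",
        [(40, 30, Fraction(3, 4), Fraction(1, 2)),
         (40, 0, Fraction(0), Fraction(-1)),
         (10, 5, Fraction(1, 2), Fraction(0))],
    )
    def test_lcp_and_index_forced_by_definitions(self, n_trials, n_toward, lcp, index):
        trials = [
            TrialRecord(fly_id="f", group_label="g", trial_index=i + 1,
                        score=1 if i < n_toward else -1)
            for i in range(n_trials)
        ]
        (fly,) = aggregate_flies(trials)
        assert fly.lcp_exact == lcp
        assert fly.phototaxis_index_exact == index

    def test_empty_input_gives_empty_output(self):
        assert aggregate_flies([]) == []

    @given(st.integers(min_value=1, max_value=40).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n))))
    @settings(max_examples=50, deadline=None)
    def test_index_is_two_lcp_minus_one_exactly(self, nt):
        n, k = nt
        fly = FlyRecord(fly_id="f", group_label="g", n_trials=n, n_toward=k)
        assert fly.phototaxis_index_exact == 2 * fly.lcp_exact - 1
        assert 0 <= fly.lcp <= 1
        assert -1 <= fly.phototaxis_index <= 1


class TestCompletionFilter:
    def test_partition_on_trial_counts(self):
        flies = [FlyRecord(f"f{i}", "g", n, n // 2)
                 for i, n in enumerate([40, 40, 39, 40, 12])]
        cohort = filter_complete(flies, 40)
        assert len(cohort.flies) == 3
        assert len(cohort.excluded) == 2
        assert cohort.provenance["excluded_per_group"] == {"g": 2}

    def test_all_complete_leaves_excluded_empty(self):
        flies = [FlyRecord(f"f{i}", "g", 40, 20) for i in range(4)]
        assert filter_complete(flies, 40).excluded == []

    def test_overrun_is_data_error_not_truncation(self):
        with pytest.raises(DataError, match="more than the scheduled"):
            filter_complete([FlyRecord("f", "g", 41, 20)], 40)

    def test_retained_plus_excluded_covers_all_groups(self):
        flies = [FlyRecord(f"a{i}", "A", 40 if i % 2 else 30, 10) for i in range(6)]
        flies += [FlyRecord(f"b{i}", "B", 40, 10) for i in range(3)]
        cohort = filter_complete(flies, 40)
        assert len(cohort.flies) + len(cohort.excluded) == 9
        assert cohort.group_labels == ["A", "B"]


def test_fly_table_round_trip(tmp_path, toy_cohort):
    path = tmp_path / "flies.tsv"
    write_fly_table(toy_cohort, path)
    back = read_fly_table(path)
    assert [(f.lcp, f.phototaxis_index) for f in back] == \
        [(f.lcp, f.phototaxis_index) for f in toy_cohort.flies]


def test_trial_table_round_trip(tmp_path):
    trials = [TrialRecord(fly_id="A", group_label="g", trial_index=i + 1,
                          score=1 if i % 3 else -1, lit_side="left", lane_id="L1")
              for i in range(5)]
    path = tmp_path / "t.tsv"
    write_trials(trials, path)
    assert read_trials(path) == trials
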