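"""Unit tests for stimulus tables, designs, trial I/O, aggregation, screening."""

import numpy as np
import pandas as pd
import pytest

import viscoweber as vw
from viscoweber.data import ValidationError


# ---------------------------------------------------------------------------
# stimulus table
# ---------------------------------------------------------------------------


class TestStimulusTable:
    def test_builtin_known_values(self):
        trans = {s.sample_id: s.viscosity for s in vw.builtin_stimuli("transparent")}
        opaque = {s.sample_id: s.viscosity for s in vw.builtin_stimuli("opaque")}
        assert trans[4] == 547
        assert opaque[4] == 544
        assert trans[18] == 15530
        assert opaque[18] == 16850
        assert len(trans) == len(opaque) == 21

    def test_csv_round_trip(self, tmp_path):
        samples = vw.builtin_stimuli("transparent") + vw.builtin_stimuli("opaque")
        path = tmp_path / "stimuli.csv"
        vw.write_stimulus_table(samples, path)
        loaded = vw.load_stimulus_table(path)
        assert loaded == samples

    def test_rejects_nonpositive_viscosity(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,appearance,viscosity_cp\n1,transparent,-1\n")
        with pytest.raises(ValidationError, match="line 2"):
            vw.load_stimulus_table(path)

    def test_rejects_duplicate_key(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "sample_id,appearance,viscosity_cp\n"
            "1,transparent,153\n1,transparent,154\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            vw.load_stimulus_table(path)

    def test_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("sample_id,viscosity_cp\n1,153\n")
        with pytest.raises(ValidationError, match="missing columns"):
            vw.load_stimulus_table(path)

    def test_sample_validation(self):
        with pytest.raises(ValidationError):
            vw.StimulusSample(1, "transparent", 0.0)
        with pytest.raises(ValidationError):
            vw.StimulusSample(1, "shiny", 100.0)


# ---------------------------------------------------------------------------
# group designs
# ---------------------------------------------------------------------------


class TestGroupDesigns:
    def test_transparent_group_a(self, transparent_groups):
        a = next(g for g in transparent_groups if g.label == "A")
        assert a.reference.viscosity == 547
        assert [t.viscosity for t in a.tests] == [153, 179, 272, 620, 756, 1040]

    def test_opaque_group_e(self, opaque_stimuli):
        groups = vw.build_group_designs(opaque_stimuli)
        e = next(g for g in groups if g.label == "E")
        assert e.reference.viscosity == 16850
        assert [t.viscosity for t in e.tests] == [
            7420, 10630, 14140, 20440, 25650, 33810,
        ]

    def test_mixed_groups_cross_tables(self, mixed_groups):
        a = next(g for g in mixed_groups if g.label == "A")
        assert a.reference.appearance == "opaque"
        assert a.reference.viscosity == 544
        assert all(t.appearance == "transparent" for t in a.tests)

    def test_bracketing_invariant(self):
        ref = vw.StimulusSample(10, "transparent", 1000.0)
        below_only = tuple(
            vw.StimulusSample(i, "transparent", v)
            for i, v in enumerate([100.0, 200.0, 300.0], start=1)
        )
        with pytest.raises(ValidationError, match="bracket"):
            vw.GroupDesign("X", ref, below_only)

    def test_unknown_sample_id(self, transparent_stimuli):
        with pytest.raises(ValidationError, match="unknown"):
            vw.build_group_designs(transparent_stimuli, {"A": (99, (1, 2, 3, 5, 6, 7))})

    def test_duplicate_tests_rejected(self):
        ref = vw.StimulusSample(2, "transparent", 1000.0)
        tests = tuple(
            vw.StimulusSample(i, "transparent", v)
            for i, v in enumerate([500.0, 500.0, 2000.0], start=3)
        )
        with pytest.raises(ValidationError, match="duplicate"):
            vw.GroupDesign("X", ref, tests)


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------


class TestEnumeratePairs:
    def test_same_appearance_dedup_gives_32(self, transparent_groups):
        design = vw.enumerate_unique_pairs(
            transparent_groups, True, "within_appearance", "task1a"
        )
        assert design.n_pairs == 32

    def test_home_group_pair_counts(self, task1a_design):
        from collections import Counter

        counts = Counter(p.home_group for p in task1a_design.pairs)
        assert counts == {"A": 7, "B": 6, "C": 6, "D": 6, "E": 7}

    def test_boundary_pair_shared_between_groups(self, task1a_design):
        shared = [p for p in task1a_design.pairs if len(p.group_labels) == 2]
        keys = {
            tuple(sorted((p.reference.viscosity, p.test.viscosity))) for p in shared
        }
        assert keys == {(547, 1040), (1040, 1560), (1560, 3520)}

    def test_mixed_appearance_keeps_35(self, mixed_groups):
        design = vw.enumerate_unique_pairs(mixed_groups, True, "none", "task1c")
        assert design.n_pairs == 35

    def test_single_group_without_equal_pair(self, group_c):
        design = vw.enumerate_unique_pairs([group_c], False, "within_appearance")
        assert design.n_pairs == 6

    def test_opaque_dedup_also_32(self, opaque_stimuli):
        groups = vw.build_group_designs(opaque_stimuli)
        design = vw.enumerate_unique_pairs(groups, True, "within_appearance", "task1b")
        assert design.n_pairs == 32


# ---------------------------------------------------------------------------
# trial I/O
# ---------------------------------------------------------------------------


class TestTrialIO:
    def test_write_read_round_trip(self, small_trials, tmp_path):
        path = tmp_path / "trials.csv"
        vw.write_trials(small_trials, path)
        loaded = vw.read_trials(path)
        assert loaded == small_trials

    def test_one_participant_has_32_rows(self, small_trials):
        per = [t for t in small_trials if t.participant_id == "S001"]
        assert len(per) == 32

    def test_duplicate_trial_rejected(self, small_trials, tmp_path):
        path = tmp_path / "dup.csv"
        vw.write_trials(list(small_trials) + [small_trials[0]], path)
        with pytest.raises(ValidationError, match="duplicate trial"):
            vw.read_trials(path)

    def test_schema_mismatch(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,task_id\nS001,task1a\n")
        with pytest.raises(ValidationError, match="missing columns"):
            vw.read_trials(path)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def _trial(pid, ref_v, test_v, side, resp, task="t", group="A"):
    return vw.TrialRecord(pid, task, group, ref_v, test_v, "transparent",
                          "transparent", side, resp)


class TestScreening:
    def test_always_test_flagged(self):
        trials = [_trial("P1", 547, 100.0 + i, "left", True) for i in range(8)]
        report = vw.screen_participants(trials)
        assert "always_test" in report.flags[("P1", "t")]

    def test_always_side_flagged(self):
        # alternating response but reference side arranged so the chosen key
        # is always "left"
        trials = []
        for i in range(8):
            resp = i % 2 == 0
            side = "right" if resp else "left"  # chosen = left either way
            trials.append(_trial("P1", 547, 100.0 + i, side, resp))
        report = vw.screen_participants(trials)
        assert "always_left" in report.flags[("P1", "t")]

    def test_mixed_not_flagged(self):
        trials = [
            _trial("P1", 547, 100.0, "left", True),
            _trial("P1", 547, 200.0, "left", False),
        ]
        report = vw.screen_participants(trials)
        assert report.flags[("P1", "t")] == ()

    def test_simulated_cohort_unflagged(self, small_trials):
        # an ideal observer (w ~ 1) flips responses essentially surely over
        # 32 pairs spanning the reference; no degenerate flags expected
        report = vw.screen_participants(small_trials)
        assert report.flagged() == []
        assert report.n_participants == 12

    def test_empty_error(self):
        with pytest.raises(ValidationError):
            vw.screen_participants([])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


class TestAggregate:
    def test_counting(self, group_c):
        trials = []
        for i in range(10):
            for t in group_c.tests:
                trials.append(
                    vw.TrialRecord(
                        f"P{i}", "t", "C", group_c.reference.viscosity,
                        t.viscosity, "transparent", "transparent", "left",
                        t.viscosity > group_c.reference.viscosity,
                    )
                )
        table = vw.aggregate(trials, group_c)
        rows = {r.test_viscosity: r for r in table.rows}
        assert rows[1040.0].k_thicker == 0
        assert rows[1040.0].n_total == 10
        assert rows[3520.0].k_thicker == 10

    def test_empty_error(self, group_c):
        with pytest.raises(ValidationError):
            vw.aggregate([], group_c)

    def test_permutation_invariance(self, small_trials, group_c):
        rng = np.random.default_rng(0)
        shuffled = list(small_trials)
        rng.shuffle(shuffled)
        t1 = vw.aggregate(small_trials, group_c)
        t2 = vw.aggregate(shuffled, group_c)
        assert [(r.test_viscosity, r.k_thicker, r.n_total) for r in t1.rows] == [
            (r.test_viscosity, r.k_thicker, r.n_total) for r in t2.rows
        ]

    def test_conservation_single_group(self, group_c):
        """Sum of k equals the number of 'test thicker' trials when no
        cross-group re-use is possible."""
        design = vw.enumerate_unique_pairs([group_c], True, "within_appearance", "t")
        config = vw.SimulationConfig(
            design, 25, 5, vw.ObserverSpec(w_by_group={"C": 0.6})
        )
        trials = vw.simulate_experiment(config)
        table = vw.aggregate(trials, group_c)
        assert sum(r.k_thicker for r in table.rows) == sum(
            t.response_test_thicker for t in trials
        )

    def test_overlap_pair_reused_with_flip(self, transparent_groups, task1a_design):
        """The shared boundary pair contributes to both adjacent groups with
        the response orientation flipped."""
        group_a = transparent_groups[0]
        group_b = transparent_groups[1]
        config = vw.SimulationConfig(
            task1a_design, 30, 7,
            vw.ObserverSpec(w_by_group={g.label: 0.8 for g in transparent_groups}),
        )
        trials = vw.simulate_experiment(config)
        tab_a = vw.aggregate(trials, group_a)  # row eta=1040 (test side)
        tab_b = vw.aggregate(trials, group_b)  # row eta=547 (flipped side)
        row_a = next(r for r in tab_a.rows if r.test_viscosity == 1040.0)
        row_b = next(r for r in tab_b.rows if r.test_viscosity == 547.0)
        assert row_a.n_total == row_b.n_total == 30
        assert row_a.k_thicker + row_b.k_thicker == 30

    def test_simulation_frequencies_match_model(self, group_c):
        """Aggregated frequencies converge on the generative probabilities."""
        design = vw.enumerate_unique_pairs([group_c], True, "within_appearance", "t")
        n = 800
        w_true = 0.7
        config = vw.SimulationConfig(
            design, n, 13, vw.ObserverSpec(w_by_group={"C": w_true})
        )
        table = vw.aggregate(vw.simulate_experiment(config), group_c)
        for row in table.rows:
            prob = vw.predict(
                row.test_viscosity,
                vw.PsychometricParams(w_true, group_c.reference.viscosity),
            )
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(row.k_thicker / n - prob) < 3 * se + 1e-12


# ---------------------------------------------------------------------------
# per-subject percentages
# ---------------------------------------------------------------------------


class TestPerSubjectPercentages:
    def test_arithmetic(self):
        trials = [
            _trial("P1", 547.0, 100.0 + i, "left", i < 3) for i in range(7)
        ]
        out = vw.per_subject_percentages(trials)
        assert len(out) == 1
        assert out.loc[0, "percent_test_thicker"] == pytest.approx(42.857142857)
        assert out.loc[0, "n_trials"] == 7

    def test_all_thicker_is_100(self):
        trials = [_trial("P1", 547.0, 100.0 + i, "left", True) for i in range(5)]
        out = vw.per_subject_percentages(trials)
        assert out.loc[0, "percent_test_thicker"] == 100.0

    def test_unbiased_symmetric_cohort_near_50(self):
        """On an exactly log-symmetric design the expected percentage is 50."""
        ref = vw.StimulusSample(0, "transparent", 1000.0)
        tests = tuple(
            vw.StimulusSample(i + 1, "transparent", 1000.0 * float(np.exp(d)))
            for i, d in enumerate([-0.9, -0.5, -0.2, 0.2, 0.5, 0.9])
        )
        group = vw.GroupDesign("S", ref, tests)
        design = vw.enumerate_unique_pairs([group], True, "within_appearance", "t")
        n_subjects, n_pairs = 400, 7
        config = vw.SimulationConfig(
            design, n_subjects, 21, vw.ObserverSpec(w_by_group={"S": 0.8})
        )
        out = vw.per_subject_percentages(vw.simulate_experiment(config))
        grand_mean = out["percent_test_thicker"].mean()
        se = 100.0 * np.sqrt(0.25 / (n_subjects * n_pairs))
        assert abs(grand_mean - 50.0) < 3 * se

    def test_empty_error(self):
        with pytest.raises(ValidationError):
            vw.per_subject_percentages([])
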