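"""Scoring keys, slot classification, summaries, agreement."""

import itertools

import numpy as np
import pytest

import rtvalid as rv
from rtvalid.inference import inference_table
from rtvalid.pseudo import COMPONENTS, ManipulationPattern
from rtvalid.scoring import OUTCOMES, ScoringKey, score_slots


def canonical_truth():
    return inference_table({i + 1: p for i, p in enumerate(rv.enumerate_patterns())})


class TestClassify:
    def test_printed_definitions(self):
        assert rv.classify_slot("B", "B") == "correct"
        assert rv.classify_slot("B", "0") == "miss"
        assert rv.classify_slot("0", "A") == "false_alarm"
        assert rv.classify_slot("A", "B") == "flip"

    def test_exhaustive_partition(self):
        """All 9 truth x inference pairs fall into exactly one outcome, with
        the expected multiplicities (3 correct, 2 miss, 2 FA, 2 flip)."""
        from collections import Counter

        c = Counter(
            rv.classify_slot(t, i) for t, i in itertools.product("A0B", repeat=2)
        )
        assert c == {"correct": 3, "miss": 2, "false_alarm": 2, "flip": 2}

    def test_rejects_bad_labels(self):
        with pytest.raises(ValueError):
            rv.classify_slot("B", "X")


class TestKeys:
    def test_slot_bookkeeping(self):
        truth = canonical_truth()
        assert truth.size == 56  # 14 data sets x 4 components
        assert rv.build_truth(truth, "planned_no_ndt").size == 42

    def test_planned_key_identity(self):
        truth = canonical_truth()
        assert rv.build_truth(truth, "planned").equals(truth)
        assert rv.build_truth(truth, ScoringKey("planned")).loc[3].tolist() == ["0", "B", "0", "0"]

    def test_alt1_couples_ease_to_caution_and_excludes_opposed(self):
        truth = canonical_truth()
        t1 = rv.build_truth(truth, "alt1_caution_ease")
        assert t1.loc[3].tolist() == ["B", "B", "0", "0"]
        assert sorted(set(truth.index) - set(t1.index)) == [8, 11, 12]

    def test_alt2_couples_ndt_to_caution(self):
        truth = canonical_truth()
        t2 = rv.build_truth(truth, "alt2_caution_ndt")
        assert t2.loc[3].tolist() == ["0", "B", "0", "B"]
        assert len(t2) == 14

    def test_keys_agree_where_caution_null(self):
        truth = canonical_truth()
        t1 = rv.build_truth(truth, "alt1_caution_ease")
        t2 = rv.build_truth(truth, "alt2_caution_ndt")
        for ds in truth.index[truth["caution"] == "0"]:
            assert truth.loc[ds].equals(t2.loc[ds])
            if ds in t1.index:
                assert truth.loc[ds].equals(t1.loc[ds])

    def test_generic_alt1_exclusion_rule(self):
        """User-supplied patterns: exclusion falls out of opposed directions,
        not hard-coded ids."""
        pats = {1: ManipulationPattern(ease="A", caution="B"), 2: ManipulationPattern(caution="B")}
        t = rv.build_truth(inference_table(pats), "alt1_caution_ease")
        assert list(t.index) == [2]

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            rv.build_truth(canonical_truth(), "post_hoc")


class TestSummarize:
    def test_printed_outcome_counts_reproduce_margins(self):
        """4 misses + 5 false alarms over 56 slots -> 0.84 / 0.07 / 0.09."""
        truth = canonical_truth()
        inf = truth.copy()
        # miss 4 manipulated slots, false-alarm 5 null slots
        missed = flipped = 0
        for ds in truth.index:
            for comp in COMPONENTS:
                if missed < 4 and truth.loc[ds, comp] != "0":
                    inf.loc[ds, comp] = "0"
                    missed += 1
                elif flipped < 5 and truth.loc[ds, comp] == "0":
                    inf.loc[ds, comp] = "A"
                    flipped += 1
        s = rv.summarize_scores(inf, truth)
        assert s.n_slots == 56
        assert s.counts == {"correct": 47, "miss": 4, "false_alarm": 5, "flip": 0}
        assert s.display() == {"correct": 0.84, "miss": 0.07, "false_alarm": 0.09, "flip": 0.0}

    def test_all_correct(self):
        truth = canonical_truth()
        s = rv.summarize_scores(truth.copy(), truth)
        assert s.proportions == {"correct": 1.0, "miss": 0.0, "false_alarm": 0.0, "flip": 0.0}

    def test_counts_always_sum_to_slots(self):
        truth = canonical_truth()
        rng = np.random.default_rng(0)
        inf = truth.copy()
        for ds in truth.index:
            for comp in COMPONENTS:
                inf.loc[ds, comp] = rng.choice(["A", "0", "B"])
        for key in ("planned", "alt1_caution_ease", "alt2_caution_ndt", "planned_no_ndt"):
            t = rv.build_truth(truth, key)
            s = rv.summarize_scores(inf, t)
            assert sum(s.counts.values()) == s.n_slots == t.size
            assert abs(sum(s.proportions.values()) - 1.0) < 1e-12

    def test_missing_dataset_raises(self):
        truth = canonical_truth()
        with pytest.raises(ValueError):
            rv.summarize_scores(truth.drop(index=5), truth)


class TestRescoringMonotonicity:
    def test_coupling_methods_gain_under_matching_alt_key(self):
        """A method that always infers ease along with caution scores
        strictly higher under alt1 than planned; one that couples ndt with
        caution gains under alt2 (the LBA / diffusion contrast)."""
        truth = canonical_truth()
        ease_coupler = truth.copy()
        ndt_coupler = truth.copy()
        manip = truth["caution"] != "0"
        ease_coupler.loc[manip, "ease"] = truth.loc[manip, "caution"]
        ndt_coupler.loc[manip, "ndt"] = truth.loc[manip, "caution"]

        def correct(inf, key):
            t = rv.build_truth(truth, key)
            return rv.summarize_scores(inf, t).proportions["correct"]

        assert correct(ease_coupler, "alt1_caution_ease") > correct(ease_coupler, "planned")
        assert correct(ndt_coupler, "alt2_caution_ndt") > correct(ndt_coupler, "planned")

    def test_score_slots_outcomes_enumerated(self):
        truth = canonical_truth()
        slots = score_slots(truth.copy(), truth)
        assert set(slots["outcome"]) == {"correct"}
        assert set(OUTCOMES) == {"correct", "miss", "false_alarm", "flip"}


class TestAgreement:
    def test_self_agreement_is_one(self):
        t = canonical_truth()
        m = rv.agreement_matrix({"a": t, "b": t.copy()})
        assert m.loc["a", "a"] == 1.0 and m.loc["a", "b"] == 1.0

    def test_single_slot_difference(self):
        t = canonical_truth()
        u = t.copy()
        u.loc[3, "ndt"] = "A"
        m = rv.agreement_matrix({"x": t, "y": u})
        assert m.loc["x", "y"] == pytest.approx(55 / 56)
        assert m.equals(m.T)

    def test_row_order_invariance(self):
        t = canonical_truth()
        u = t.copy()
        u.loc[2, "ease"] = "0"
        shuffled = u.sample(frac=1.0, random_state=2)
        m1 = rv.agreement_matrix({"x": t, "y": u})
        m2 = rv.agreement_matrix({"x": t, "y": shuffled})
        assert np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_needs_two_methods(self):
        with pytest.raises(ValueError):
            rv.agreement_matrix({"only": canonical_truth()})
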