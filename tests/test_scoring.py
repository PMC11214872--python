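"""Scoring: token classification, pooled 1/N uniqueness, oracle equivalence."""

import numpy as np
import pytest

from semfluency import (
    Cohort,
    Group,
    Transcript,
    build_word_count_index,
    classify_tokens,
    score_cohort,
    uniqueness_of_participant,
    normalize_token,
)

from conftest import random_micro_cohort


def brute_force_scores(cohort, lexicon):
    """Independent recount over all (participant, word) pairs.

    Re-derives every parameter from first principles: normalizes each token,
    counts category members/duplicates/intrusions by direct set logic, and
    recomputes every N by scanning all participants for each word.
    """
    per = {}
    for t in cohort:
        normed = [normalize_token(tok, lexicon) for tok in t.tokens]
        correct_set = {w for w, ok in normed if ok}
        n_correct_tokens = sum(1 for w, ok in normed if ok)
        incorrect = sum(1 for _, ok in normed if not ok)
        per[t.participant_id] = {
            "group": t.group,
            "correct": correct_set,
            "fluency": len(correct_set),
            "repetitions": n_correct_tokens - len(correct_set),
            "incorrect": incorrect,
        }
    out = {}
    for pid, rec in per.items():
        if not rec["correct"]:
            uniq = None
        else:
            total = 0.0
            for w in rec["correct"]:
                n = sum(1 for other in per.values() if w in other["correct"])
                total += 1.0 / n
            uniq = total / len(rec["correct"])
        out[pid] = (rec["fluency"], rec["repetitions"], rec["incorrect"], uniq)
    return out


@pytest.mark.parametrize(
    "tokens, expected_correct, expected_rep, expected_inc",
    [
        (["cat", "dog", "cat", "lotus"], ["cat", "dog"], 1, 1),
        ([], [], 0, 0),
        (["puppy", "dog"], ["dog"], 1, 0),
        (["lotus", "lotus"], [], 0, 2),  # out-of-category duplicates stay incorrect
        (["Dog ", "dog", "KITTY"], ["dog", "cat"], 1, 0),
    ],
)
def test_classify_tokens(toy_lexicon, tokens, expected_correct, expected_rep,
                         expected_inc):
    t = Transcript("P", Group.HC, tokens)
    correct, reps, inc = classify_tokens(t, toy_lexicon)
    assert correct == expected_correct
    assert (reps, inc) == (expected_rep, expected_inc)
    assert len(correct) + reps + inc == len(tokens)  # conservation


def test_build_word_count_index():
    idx = build_word_count_index(
        [("A", {"cat", "dog"}), ("B", {"cat", "horse"}), ("C", {"cat"})])
    assert idx.counts == {"cat": 3, "dog": 1, "horse": 1}
    assert idx.total_participants == 3

    single = build_word_count_index([("A", {"cat"})])
    assert single.counts == {"cat": 1} and single.total_participants == 1

    twin = build_word_count_index([("A", {"cat"}), ("B", {"cat"})])
    assert twin.counts == {"cat": 2} and twin.total_participants == 2

    # empty sets still raise the denominator M
    idx2 = build_word_count_index([("A", {"cat"}), ("B", set())])
    assert idx2.total_participants == 2

    with pytest.raises(ValueError, match="duplicate"):
        build_word_count_index([("A", {"cat"}), ("A", {"dog"})])


def test_uniqueness_of_participant():
    idx = build_word_count_index(
        [("A", {"cat", "dog"}), ("B", {"cat", "horse"}), ("C", {"cat"})])
    assert uniqueness_of_participant({"cat", "dog"}, idx) == pytest.approx(2 / 3)
    assert uniqueness_of_participant({"cat"}, idx) == pytest.approx(1 / 3)
    assert uniqueness_of_participant(set(), idx) is None
    with pytest.raises(ValueError, match="missing from index"):
        uniqueness_of_participant({"zebra"}, idx)


def test_score_cohort_toy(toy_cohort, toy_lexicon):
    records = {r.participant_id: r for r in score_cohort(toy_cohort, toy_lexicon)}
    assert [records[p].fluency for p in "ABC"] == [2, 2, 1]
    assert records["A"].uniqueness == pytest.approx(2 / 3)
    assert records["B"].uniqueness == pytest.approx(2 / 3)
    assert records["C"].uniqueness == pytest.approx(1 / 3)


def test_score_cohort_degenerate_cases(toy_lexicon):
    # identical word lists: everyone's uniqueness is exactly 1/M
    clones = Cohort([Transcript(f"P{i}", Group.HC, ["cat", "dog"])
                     for i in range(5)])
    for r in score_cohort(clones, toy_lexicon):
        assert r.uniqueness == pytest.approx(1 / 5)

    # single participant: every N = 1, uniqueness 1.0 regardless of words
    solo = Cohort([Transcript("P0", Group.PD, ["cat", "horse", "pig"])])
    (rec,) = score_cohort(solo, toy_lexicon)
    assert rec.uniqueness == 1.0


def test_pooling_invariance(toy_lexicon):
    """Uniqueness depends only on the pooled index, never on group labels."""
    rng = np.random.default_rng(7)
    cohort = random_micro_cohort(rng)
    base = score_cohort(cohort, toy_lexicon)
    shuffled_groups = list(Group)
    permuted = Cohort([
        Transcript(t.participant_id,
                   shuffled_groups[(i * 2 + 1) % 3],
                   list(t.tokens), t.age, t.education)
        for i, t in enumerate(cohort)
    ])
    for r_base, r_perm in zip(base, score_cohort(permuted, toy_lexicon)):
        assert r_base.fluency == r_perm.fluency
        assert r_base.repetitions == r_perm.repetitions
        assert r_base.incorrect == r_perm.incorrect
        assert r_base.uniqueness == r_perm.uniqueness


def test_monotonicity_under_duplication(toy_lexicon):
    """Adding a participant who repeats A's words weakly lowers A's uniqueness."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        cohort = random_micro_cohort(rng)
        target = cohort.transcripts[0]
        base = {r.participant_id: r for r in score_cohort(cohort, toy_lexicon)}
        clone = Transcript("CLONE", Group.HC, list(target.tokens))
        bigger = Cohort(cohort.transcripts + [clone])
        after = {r.participant_id: r for r in score_cohort(bigger, toy_lexicon)}
        if base[target.participant_id].uniqueness is not None:
            assert (after[target.participant_id].uniqueness
                    <= base[target.participant_id].uniqueness + 1e-12)


def test_scoring_matches_brute_force_oracle(toy_lexicon):
    """score_cohort equals an independent recount on random micro-cohorts."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        cohort = random_micro_cohort(rng)
        expected = brute_force_scores(cohort, toy_lexicon)
        m = len(cohort)
        for rec in score_cohort(cohort, toy_lexicon):
            exp_f, exp_r, exp_i, exp_u = expected[rec.participant_id]
            assert rec.fluency == exp_f
            assert rec.repetitions == exp_r
            assert rec.incorrect == exp_i
            if exp_u is None:
                assert rec.uniqueness is None
            else:
                assert rec.uniqueness == pytest.approx(exp_u, abs=1e-12)
                assert 1 / m - 1e-12 <= rec.uniqueness <= 1 + 1e-12
            # conservation against the raw token count
            t = next(t for t in cohort if t.participant_id == rec.participant_id)
            assert rec.fluency + rec.repetitions + rec.incorrect == len(t.tokens)
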