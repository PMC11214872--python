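"""Scoring of category-fluency transcripts.

Four parameters per participant:

* **fluency** — number of distinct correct (in-category) words produced;
* **repetitions** — in-category productions whose canonical form was already
  produced by the same participant;
* **incorrect** — productions outside the category (intrusions, e.g. "lotus"
  in an animal task); out-of-category duplicates count as incorrect each time,
  never as repetitions;
* **uniqueness** — the mean over the participant's distinct correct words of
  1/N, where N is the number of participants *in the entire pooled sample*
  (all groups) whose correct-word set contains that word.  High values mean
  rarer word choices.  Undefined (None) when fluency is zero.

N counts distinct participants, not tokens: repeating "cat" five times still
contributes 1 to N(cat).  Each participant is included in their own N, so
N >= 1 and uniqueness lies in [1/M, 1] for a pooled sample of M participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .lexicon_io import CategoryLexicon, Cohort, Group, Transcript, normalize_token

__all__ = [
    "ScoreRecord",
    "WordCountIndex",
    "classify_tokens",
    "build_word_count_index",
    "uniqueness_of_participant",
    "score_cohort",
]


@dataclass
class ScoreRecord:
    """The four per-participant parameters."""

    participant_id: str
    group: Group
    fluency: int
    repetitions: int
    incorrect: int
    uniqueness: float | None

    def __post_init__(self) -> None:
        if min(self.fluency, self.repetitions, self.incorrect) < 0:
            raise ValueError("counts must be non-negative")
        if (self.uniqueness is None) != (self.fluency == 0):
            raise ValueError(
                "uniqueness must be None exactly when fluency == 0"
            )


@dataclass
class WordCountIndex:
    """Pooled word -> number-of-participants map (the N in 1/N)."""

    counts: dict[str, int]
    total_participants: int

    def __post_init__(self) -> None:
        for word, n in self.counts.items():
            if not 1 <= n <= self.total_participants:
                raise ValueError(
                    f"N({word!r}) = {n} outside [1, {self.total_participants}]"
                )


def classify_tokens(
    t: Transcript, lexicon: CategoryLexicon
) -> tuple[list[str], int, int]:
    """Scan tokens in production order into (correct words, repetitions, incorrect).

    The correct-word list holds canonical forms in order of first production;
    a repeated in-category canonical increments the repetition count.  The
    conservation identity ``len(correct) + repetitions + incorrect ==
    len(t.tokens)`` holds by construction.
    """
    correct: list[str] = []
    seen: set[str] = set()
    repetitions = 0
    incorrect = 0
    for raw in t.tokens:
        canon, in_category = normalize_token(raw, lexicon)
        if not in_category:
            incorrect += 1
        elif canon in seen:
            repetitions += 1
        else:
            seen.add(canon)
            correct.append(canon)
    return correct, repetitions, incorrect


def build_word_count_index(
    cohort_correct_sets: Iterable[tuple[str, Iterable[str]]]
) -> WordCountIndex:
    """Count, for every word, the participants whose correct-word set holds it.

    Pools over *all* supplied participants (all groups), including those with
    empty sets — they still raise the denominator M.
    """
    counts: dict[str, int] = {}
    seen_ids: set[str] = set()
    m = 0
    for pid, words in cohort_correct_sets:
        if pid in seen_ids:
            raise ValueError(f"duplicate participant id {pid!r}")
        seen_ids.add(pid)
        m += 1
        for word in set(words):
            counts[word] = counts.get(word, 0) + 1
    return WordCountIndex(counts, m)


def uniqueness_of_participant(
    correct: Iterable[str], index: WordCountIndex
) -> float | None:
    """Mean of 1/N over the participant's distinct correct words.

    Returns None (undefined, not zero) for an empty word set.  Every word must
    be present in the index — the participant has to have been pooled when the
    index was built.
    """
    words = set(correct)
    if not words:
        return None
    total = 0.0
    for word in words:
        if word not in index.counts:
            raise ValueError(
                f"word {word!r} missing from index: index was not built "
                "from this cohort"
            )
        total += 1.0 / index.counts[word]
    return total / len(words)


def score_cohort(
    cohort: Cohort | Sequence[Transcript], lexicon: CategoryLexicon
) -> list[ScoreRecord]:
    """Classify every transcript, pool one word-count index, emit ScoreRecords.

    The index is built over ALL groups jointly, so uniqueness never depends on
    group labels.  Deterministic given inputs.
    """
    transcripts = list(cohort)
    classified = [
        (t, *classify_tokens(t, lexicon)) for t in transcripts
    ]
    index = build_word_count_index(
        (t.participant_id, correct) for t, correct, _, _ in classified
    )
    records = []
    for t, correct, reps, incorrect in classified:
        records.append(
            ScoreRecord(
                participant_id=t.participant_id,
                group=t.group,
                fluency=len(correct),
                repetitions=reps,
                incorrect=incorrect,
                uniqueness=uniqueness_of_participant(correct, index),
            )
        )
    return records
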