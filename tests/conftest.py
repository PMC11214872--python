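import numpy as np
import pytest

from semfluency import (
    CategoryLexicon,
    Cohort,
    GenerativeParams,
    Group,
    Transcript,
    default_animal_lexicon,
)


@pytest.fixture(scope="session")
def animal_lexicon():
    return default_animal_lexicon()


@pytest.fixture()
def toy_lexicon():
    return CategoryLexicon(
        canonical=["cat", "dog", "horse", "cow", "fish", "bird", "mouse", "pig"],
        synonym_map={"puppy": "dog", "kitty": "cat"},
        category_name="animals",
    )


@pytest.fixture()
def toy_cohort():
    """Three participants whose hand-computed scores anchor the scoring tests."""
    return Cohort([
        Transcript("A", Group.PSP_RS, ["cat", "dog"], age=60, education=10),
        Transcript("B", Group.PD, ["cat", "horse"], age=62, education=12),
        Transcript("C", Group.HC, ["cat"], age=58, education=11),
    ])


def random_micro_cohort(rng: np.random.Generator, max_participants: int = 10,
                        vocab: tuple[str, ...] = ("cat", "dog", "horse", "cow",
                                                  "fish", "bird", "mouse", "pig"),
                        intruders: tuple[str, ...] = ("lotus", "rose")) -> Cohort:
    """A small random cohort over a tiny vocabulary, duplicates and intrusions in."""
    n = int(rng.integers(1, max_participants + 1))
    groups = list(Group)
    transcripts = []
    for i in range(n):
        n_tokens = int(rng.integers(0, 13))
        pool = vocab + intruders
        tokens = [str(pool[j]) for j in rng.integers(0, len(pool), n_tokens)]
        transcripts.append(
            Transcript(f"P{i}", groups[int(rng.integers(0, 3))], tokens,
                       age=int(rng.integers(45, 81)),
                       education=int(rng.integers(5, 21)))
        )
    return Cohort(transcripts)
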