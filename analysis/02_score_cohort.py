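#!/usr/bin/env python
"""Score the simulated cohort into the four per-participant parameters.

Reads results/cohort.csv, scores every transcript against the packaged
animal lexicon (fluency, repetitions, incorrect words, and pooled 1/N
uniqueness) and writes results/scores.csv.
"""

from pathlib import Path

from semfluency import default_animal_lexicon, read_cohort, score_cohort, write_scores

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    records = score_cohort(cohort, default_animal_lexicon())
    out = RESULTS / "scores.csv"
    write_scores(records, out)
    n_undef = sum(1 for r in records if r.uniqueness is None)
    print(f"scored {len(records)} participants -> {out}")
    if n_undef:
        print(f"note: {n_undef} participant(s) produced no correct word; "
              "their uniqueness is undefined")


if __name__ == "__main__":
    main()
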