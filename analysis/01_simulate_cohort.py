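#!/usr/bin/env python
"""Generate the default synthetic study cohort (27 PSP-RS / 35 PD / 40 HC).

Writes the cohort CSV plus a provenance YAML of the generator parameters to
results/.  Downstream scripts (02-05) consume this cohort.
"""

from pathlib import Path

import yaml

from semfluency import GenerativeParams, generate_cohort, write_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = GenerativeParams(seed=SEED)
    cohort = generate_cohort(params)
    out = RESULTS / "cohort.csv"
    write_cohort(cohort, out)
    (RESULTS / "cohort.params.yaml").write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=True))
    by_group = {}
    for t in cohort:
        by_group[t.group.value] = by_group.get(t.group.value, 0) + 1
    print(f"simulated {len(cohort)} participants {by_group} -> {out}")


if __name__ == "__main__":
    main()
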