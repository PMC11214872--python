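#!/usr/bin/env python
"""Stage 2: fluency x uniqueness partial correlations within each group.

Age and education controlled, Bonferroni family of three (corrected alpha
.017).  The expected structure under the generator's defaults: positive in
HC and PD, negative in PSP-RS (the fluency-uniqueness trade-off).
"""

from pathlib import Path

from semfluency import AnalysisConfig, read_cohort, run_analysis

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    bundle = run_analysis(cohort, AnalysisConfig())
    for pc in bundle.fluency_uniqueness:
        flag = "significant" if pc.significant else "n.s."
        print(f"{pc.x} ~ {pc.y} | {'+'.join(pc.covariates)}: "
              f"r = {pc.r:+.2f}, p = {pc.p:.4g}, n = {pc.n} [{flag}]")


if __name__ == "__main__":
    main()
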