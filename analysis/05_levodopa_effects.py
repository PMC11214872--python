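#!/usr/bin/env python
"""Stage 3: levodopa dose effects within the PSP-RS group.

Partial correlations of the actual levodopa dose (mg/day) with fluency and
uniqueness, controlling the levodopa-equivalent dose of all other drugs, age
and education (Bonferroni family of two, corrected alpha .025).  Under the
generator's defaults the dose raises fluency and lowers uniqueness.
"""

from pathlib import Path

from semfluency import AnalysisConfig, read_cohort, run_analysis

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    bundle = run_analysis(cohort, AnalysisConfig())
    psp = bundle.scores[bundle.scores["group"] == "PSP_RS"]
    print(f"PSP-RS levodopa dose: mean {psp['levodopa_dose'].mean():.1f} "
          f"(SD {psp['levodopa_dose'].std():.1f}) mg/day; "
          f"other-drug LED mean {psp['other_led'].mean():.1f} mg/day")
    for pc in bundle.levodopa_effects:
        flag = "significant" if pc.significant else "n.s."
        print(f"dose ~ {pc.y} | {'+'.join(pc.covariates)}: "
              f"r = {pc.r:+.2f}, p = {pc.p:.4g}, n = {pc.n} [{flag}]")


if __name__ == "__main__":
    main()
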