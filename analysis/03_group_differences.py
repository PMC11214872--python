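#!/usr/bin/env python
"""Stage 1: group differences in the four parameters.

One ANCOVA per outcome (group factor, age + education covariates, Bonferroni
family of four, corrected alpha .013), post hoc pooled-variance t-tests for
significant outcomes.  Writes the tidy test table and the full text report to
results/ and prints the stage-1 section.
"""

from pathlib import Path

from semfluency import AnalysisConfig, make_report, read_cohort, run_analysis

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    bundle = run_analysis(cohort, AnalysisConfig())
    bundle.write(RESULTS / "bundle")
    for res in bundle.group_tests:
        flag = "significant" if res.significant else "n.s."
        print(f"{res.outcome}: F{res.df} = {res.statistic:.2f}, "
              f"p = {res.p:.4g}, eta_p^2 = {res.partial_eta_sq:.2f} [{flag}]")
    print(f"\nfull report -> {RESULTS / 'bundle' / 'report.txt'}")
    print(make_report(bundle))


if __name__ == "__main__":
    main()
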