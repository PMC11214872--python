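#!/usr/bin/env python
"""Monte-Carlo validation of the whole pipeline.

Two experiments over independent seeds:

* sign recovery (50 seeds): fraction of seeds in which the pipeline recovers
  each qualitative feature of the expected result structure;
* null calibration (100 seeds): rejection rate of the uniqueness ANCOVA under
  the generator's no-effect configuration — should sit at or below the
  corrected alpha.

Writes results/sign_recovery.csv and prints both summaries.
"""

import csv
from pathlib import Path

from semfluency.experiments import null_calibration, sign_recovery

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rates = sign_recovery(n_seeds=50, seed0=0)
    with open(RESULTS / "sign_recovery.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["check", "recovery_rate", "n_seeds"])
        for name, rate in rates.items():
            writer.writerow([name, rate, 50])
            print(f"{name}: {rate:.0%}")
    rate = null_calibration(n_seeds=100, seed0=0)
    print(f"\nnull calibration: uniqueness ANCOVA rejected in {rate:.0%} "
          "of 100 no-effect seeds (corrected alpha .013)")


if __name__ == "__main__":
    main()
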