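"""Levodopa-equivalent daily dose (LEDD) computation.

LEDD converts every anti-parkinsonian drug dose to a common levodopa-
equivalent scale: LED(drug) = dose_mg * factor(drug).  COMT inhibitors such
as entacapone act as *augmenters* — instead of contributing through their own
dose they add a fixed fraction of the concurrent levodopa LED.

The breakdown separates the levodopa component from everything else because
the dose analyses correlate the *actual* levodopa dose (raw mg/day, factor 1)
with performance while controlling the LED of all other drugs.  Augmenter
contributions are assigned to the other-drug component.

Conversion factors live in a version-stamped YAML config, not in code; the
packaged default carries the standard Tomlinson et al. (2010) factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["LEDDTable", "LEDDBreakdown", "compute_ledd", "default_ledd_table"]

LEVODOPA = "levodopa"


@dataclass
class LEDDTable:
    """Drug -> multiplicative factor map plus augmenter fractions."""

    factors: dict[str, float]
    augmenters: dict[str, float] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for drug, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"factor for {drug!r} must be > 0")
        for drug, frac in self.augmenters.items():
            if frac < 0:
                raise ValueError(f"augmenter fraction for {drug!r} must be >= 0")

    def knows(self, drug: str) -> bool:
        return drug in self.factors or drug in self.augmenters


@dataclass
class LEDDBreakdown:
    levodopa_led: float
    other_led: float

    @property
    def total_led(self) -> float:
        return self.levodopa_led + self.other_led


def default_ledd_table() -> LEDDTable:
    ref = resources.files("semfluency.data") / "ledd_factors.yaml"
    with resources.as_file(ref) as path:
        return load_ledd_table(path)


def load_ledd_table(path: str | Path) -> LEDDTable:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return LEDDTable(
        factors={str(k).lower(): float(v) for k, v in cfg["factors"].items()},
        augmenters={str(k).lower(): float(v)
                    for k, v in cfg.get("augmenters", {}).items()},
        version=str(cfg.get("version", "unversioned")),
    )


def compute_ledd(
    meds: Mapping[str, float], table: LEDDTable | None = None
) -> LEDDBreakdown:
    """Split a medication map into levodopa LED, other-drug LED and total.

    Augmenters (e.g. entacapone) add their configured fraction of the
    levodopa LED to the *other*-drug component, so the levodopa component
    stays equal to the actual levodopa dose when its factor is 1.
    """
    if table is None:
        table = default_ledd_table()
    unknown = [d for d in meds if not table.knows(d.lower())]
    if unknown:
        raise KeyError(
            f"drugs missing from LEDD table {table.version!r}: {sorted(unknown)}"
        )
    for drug, dose in meds.items():
        if dose < 0:
            raise ValueError(f"negative dose for {drug!r}")

    meds_lc = {d.lower(): dose for d, dose in meds.items()}
    levodopa_led = meds_lc.get(LEVODOPA, 0.0) * table.factors.get(LEVODOPA, 1.0)
    other = 0.0
    for drug, dose in meds_lc.items():
        if drug == LEVODOPA:
            continue
        if drug in table.augmenters:
            if dose > 0:
                other += table.augmenters[drug] * levodopa_led
        else:
            other += dose * table.factors[drug]
    return LEDDBreakdown(levodopa_led=levodopa_led, other_led=other)
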