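"""End-to-end analysis: scoring -> group statistics -> dose correlations.

Three inference stages, each with its own Bonferroni family:

1. group differences in the four parameters (fluency, repetitions, incorrect,
   uniqueness): one ANCOVA per outcome with age and education as covariates
   (family m=4, corrected alpha .013), followed — for significant outcomes —
   by pairwise pooled-variance t-tests;
2. the fluency-uniqueness relationship within each group: partial
   correlations controlling age and education (family m=3, alpha .017);
3. the levodopa effect within PSP-RS: partial correlations of the actual
   levodopa dose (mg/day) with fluency and uniqueness, controlling the
   levodopa-equivalent dose of all other drugs, age and education
   (family m=2, alpha .025).

Participants whose fluency is zero have undefined uniqueness and are dropped
from uniqueness-based analyses only; every drop is logged on the bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .ledd import LEDDTable, compute_ledd, default_ledd_table
from .lexicon_io import CategoryLexicon, Cohort, Group, default_animal_lexicon
from .scoring import ScoreRecord, score_cohort
from .stats import (
    PartialCorrResult,
    StatResult,
    ancova_group_effect,
    bonferroni_alpha,
    partial_correlation,
    posthoc_t,
)

__all__ = ["AnalysisConfig", "AnalysisBundle", "run_analysis", "make_report",
           "scores_frame"]

FOUR_PARAMETERS = ["fluency", "repetitions", "incorrect", "uniqueness"]
GROUP_ORDER = [Group.PSP_RS, Group.PD, Group.HC]


@dataclass
class AnalysisConfig:
    """Families, covariates and screening knobs for one analysis run."""

    family_alpha: float = 0.05
    four_param_family_m: int = 4
    correlation_family_m: int = 3
    levodopa_family_m: int = 2
    demographics_family_m: int = 13
    group_covariates: tuple[str, ...] = ("age", "education")
    levodopa_covariates: tuple[str, ...] = ("other_led", "age", "education")
    normality_alpha: float = 0.05
    force_posthoc: bool = False
    lexicon: CategoryLexicon | None = None
    ledd_table: LEDDTable | None = None


@dataclass
class AnalysisBundle:
    """Everything one run produced, plus the decision log."""

    scores: pd.DataFrame
    group_tests: list[StatResult] = field(default_factory=list)
    posthoc_tests: list[StatResult] = field(default_factory=list)
    fluency_uniqueness: list[PartialCorrResult] = field(default_factory=list)
    levodopa_effects: list[PartialCorrResult] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def tidy(self) -> pd.DataFrame:
        """One row per test: the machine-readable results table."""
        rows = []
        for res in self.group_tests + self.posthoc_tests:
            df1, df2 = (res.df if isinstance(res.df, tuple) else (res.df, None))
            rows.append({
                "stage": "group_differences" if res.test == "ancova_F"
                else "posthoc",
                "outcome": res.outcome, "test": res.test,
                "statistic": res.statistic, "df1": df1, "df2": df2,
                "p": res.p, "effect_size": res.partial_eta_sq,
                "alpha_corrected": res.alpha_corrected,
                "significant": res.significant,
            })
        for stage, results in (("fluency_uniqueness", self.fluency_uniqueness),
                               ("levodopa", self.levodopa_effects)):
            for pc in results:
                rows.append({
                    "stage": stage,
                    "outcome": f"{pc.x}~{pc.y}|{'+'.join(pc.covariates)}",
                    "test": "partial_r", "statistic": pc.r,
                    "df1": pc.n - 2 - len(pc.covariates), "df2": None,
                    "p": pc.p, "effect_size": pc.r,
                    "alpha_corrected": pc.alpha_corrected,
                    "significant": pc.significant,
                })
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(outdir / "scores.csv", index=False)
        self.tidy().to_csv(outdir / "tests.csv", index=False)
        (outdir / "report.txt").write_text(make_report(self))
        (outdir / "analysis.log").write_text("\n".join(self.log) + "\n")


def scores_frame(cohort: Cohort, records: list[ScoreRecord],
                 ledd_table: LEDDTable | None = None) -> pd.DataFrame:
    """Merge score records with covariates and medication-derived columns."""
    if ledd_table is None:
        ledd_table = default_ledd_table()
    by_id = {t.participant_id: t for t in cohort}
    rows = []
    for r in records:
        t = by_id[r.participant_id]
        breakdown = compute_ledd(t.meds, ledd_table)
        rows.append({
            "participant_id": r.participant_id,
            "group": r.group.value,
            "fluency": r.fluency,
            "repetitions": r.repetitions,
            "incorrect": r.incorrect,
            "uniqueness": np.nan if r.uniqueness is None else r.uniqueness,
            "age": t.age,
            "education": t.education,
            "levodopa_dose": t.meds.get("levodopa", 0.0),
            "other_led": breakdown.other_led,
            "total_led": breakdown.total_led,
        })
    return pd.DataFrame(rows)


def run_analysis(cohort: Cohort, config: AnalysisConfig | None = None
                 ) -> AnalysisBundle:
    """Score the cohort and run all three inference stages."""
    config = config or AnalysisConfig()
    lexicon = config.lexicon or default_animal_lexicon()
    records = score_cohort(cohort, lexicon)
    frame = scores_frame(cohort, records, config.ledd_table)
    bundle = AnalysisBundle(scores=frame)
    log = bundle.log
    log.append(f"scored {len(frame)} participants "
               f"({frame.groupby('group').size().to_dict()})")
    n_undef = int(frame["uniqueness"].isna().sum())
    if n_undef:
        log.append(f"{n_undef} participant(s) with fluency 0: uniqueness "
                   "undefined, excluded from uniqueness analyses")

    groups_present = [g for g in GROUP_ORDER if g.value in set(frame["group"])]

    # ----- stage 1: four-parameter ANCOVAs + post hoc t-tests
    if len(groups_present) >= 2:
        alpha1 = bonferroni_alpha(config.family_alpha,
                                  config.four_param_family_m)
        covs = frame[list(config.group_covariates)].to_numpy(dtype=float)
        for outcome in FOUR_PARAMETERS:
            res = ancova_group_effect(
                frame[outcome].to_numpy(dtype=float),
                frame["group"].to_numpy(),
                covariates=covs,
                outcome=outcome,
                alpha_corrected=alpha1,
                covariate_names=config.group_covariates,
            )
            if res.n_dropped:
                log.append(f"stage1/{outcome}: dropped {res.n_dropped} "
                           "row(s) with missing values")
            bundle.group_tests.append(res)
            if res.significant or config.force_posthoc:
                for ga, gb in combinations(groups_present, 2):
                    sub = frame[np.isfinite(frame[outcome].astype(float))]
                    res_t = posthoc_t(
                        sub.loc[sub["group"] == ga.value, outcome],
                        sub.loc[sub["group"] == gb.value, outcome],
                        outcome=f"{outcome}:{ga.value}-{gb.value}",
                        alpha_corrected=alpha1,
                    )
                    bundle.posthoc_tests.append(res_t)
    else:
        log.append("stage1 skipped: fewer than 2 groups present")

    # ----- stage 2: fluency x uniqueness partial correlations per group
    m2 = min(config.correlation_family_m, max(len(groups_present), 1))
    if m2 != config.correlation_family_m:
        log.append(f"stage2: correlation family adjusted to m={m2} "
                   f"({len(groups_present)} groups present)")
    alpha2 = bonferroni_alpha(config.family_alpha, m2)
    for g in groups_present:
        sub = frame[(frame["group"] == g.value)
                    & np.isfinite(frame["uniqueness"].astype(float))]
        if len(sub) <= len(config.group_covariates) + 2:
            log.append(f"stage2/{g.value}: too few usable rows ({len(sub)})")
            continue
        pc = partial_correlation(
            sub["fluency"], sub["uniqueness"],
            covariates=sub[list(config.group_covariates)].to_numpy(dtype=float),
            x_name=f"fluency[{g.value}]", y_name="uniqueness",
            covariate_names=config.group_covariates,
            alpha_corrected=alpha2,
        )
        bundle.fluency_uniqueness.append(pc)

    # ----- stage 3: levodopa dose effects within PSP-RS
    psp = frame[(frame["group"] == Group.PSP_RS.value)]
    if len(psp) == 0:
        log.append("stage3 skipped: no PSP-RS participants")
        return bundle
    alpha3 = bonferroni_alpha(config.family_alpha, config.levodopa_family_m)
    for outcome in ("fluency", "uniqueness"):
        sub = psp[np.isfinite(psp[outcome].astype(float))]
        if len(sub) <= len(config.levodopa_covariates) + 2:
            log.append(f"stage3/{outcome}: too few usable rows ({len(sub)})")
            continue
        pc = partial_correlation(
            sub["levodopa_dose"], sub[outcome],
            covariates=sub[list(config.levodopa_covariates)].to_numpy(dtype=float),
            x_name="levodopa_dose", y_name=outcome,
            covariate_names=config.levodopa_covariates,
            alpha_corrected=alpha3,
        )
        bundle.levodopa_effects.append(pc)
    return bundle


# ---------------------------------------------------------------------------
# Report rendering: pure formatting of the bundle, no computation.


def _round_half_up(x: float, places: int) -> Decimal:
    q = Decimal(10) ** -places
    return Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)


def fmt_stat(x: float) -> str:
    return str(_round_half_up(x, 2))


def fmt_p(p: float) -> str:
    if p < 0.001:
        return "p < .001"
    return "p = " + str(_round_half_up(p, 3))[1:]  # strip leading 0


def fmt_alpha(alpha: float) -> str:
    return str(_round_half_up(alpha, 3))[1:]


def _fmt_f(res: StatResult) -> str:
    df1, df2 = res.df
    return (f"F[{int(df1)}, {int(df2)}] = {fmt_stat(res.statistic)}, "
            f"{fmt_p(res.p)}, ηp² = "
            f"{_round_half_up(res.partial_eta_sq, 2)}")


def _fmt_t(res: StatResult) -> str:
    return (f"t[{int(res.df)}] = {fmt_stat(res.statistic)}, {fmt_p(res.p)}")


def _fmt_r(pc: PartialCorrResult) -> str:
    return f"r = {fmt_stat(pc.r)}, {fmt_p(pc.p)}"


def make_report(bundle: AnalysisBundle) -> str:
    """Human-readable text report; every number is a rounding of the bundle."""
    lines: list[str] = []
    add = lines.append
    add("Semantic fluency analysis report")
    add("=" * 40)

    add("")
    add("Group means (SD)")
    summary = bundle.scores.groupby("group")[FOUR_PARAMETERS].agg(["mean", "std"])
    for g in [g.value for g in GROUP_ORDER if g.value in summary.index]:
        parts = [
            f"{p} {fmt_stat(summary.loc[g, (p, 'mean')])} "
            f"({fmt_stat(summary.loc[g, (p, 'std')])})"
            for p in FOUR_PARAMETERS
        ]
        add(f"  {g}: " + ", ".join(parts))

    add("")
    add("Stage 1 - group differences (ANCOVA, covariates age + education)")
    if not bundle.group_tests:
        add("  skipped: fewer than 2 groups present")
    for res in bundle.group_tests:
        star = " *" if res.significant else ""
        add(f"  {res.outcome}: {_fmt_f(res)}"
            f" (corrected alpha {fmt_alpha(res.alpha_corrected)}){star}")
    if bundle.posthoc_tests:
        add("  post hoc pooled-variance t-tests:")
        for res in bundle.posthoc_tests:
            add(f"    {res.outcome}: {_fmt_t(res)}")

    add("")
    add("Stage 2 - fluency x uniqueness partial correlations "
        "(age + education controlled)")
    if not bundle.fluency_uniqueness:
        add("  skipped: no usable groups")
    for pc in bundle.fluency_uniqueness:
        star = " *" if pc.significant else ""
        add(f"  {pc.x}: {_fmt_r(pc)} (n = {pc.n}, corrected alpha "
            f"{fmt_alpha(pc.alpha_corrected)}){star}")

    add("")
    add("Stage 3 - levodopa dose effects in PSP-RS "
        "(other-drug LED + age + education controlled)")
    if not bundle.levodopa_effects:
        add("  skipped: no PSP-RS participants")
    for pc in bundle.levodopa_effects:
        star = " *" if pc.significant else ""
        add(f"  dose ~ {pc.y}: {_fmt_r(pc)} (n = {pc.n}, corrected alpha "
            f"{fmt_alpha(pc.alpha_corrected)}){star}")

    add("")
    add("Log")
    for entry in bundle.log:
        add(f"  - {entry}")
    return "\n".join(lines) + "\n"
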