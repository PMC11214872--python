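"""Multi-seed simulation experiments over the full pipeline.

Two study-level checks run here:

* **sign recovery** — with the generator's documented defaults, does the
  whole pipeline (generate -> score -> stats) reproduce the qualitative
  result structure: lower mean fluency and uniqueness in PSP-RS than in PD
  and HC, a positive fluency-uniqueness partial correlation in HC and PD but
  a negative one in PSP-RS, and a positive dose->fluency / negative
  dose->uniqueness partial correlation within PSP-RS?  Reported as the
  fraction of independent seeds recovering each sign.
* **null calibration** — under the generator's true no-effect configuration
  (:meth:`GenerativeParams.null`), how often does the uniqueness ANCOVA
  reject at its Bonferroni-corrected alpha?  A calibrated pipeline stays at
  or below the nominal corrected level.
"""

from __future__ import annotations

from dataclasses import replace

from .lexicon_io import CategoryLexicon, Group, default_animal_lexicon
from .pipeline import AnalysisConfig, run_analysis
from .simulate import GenerativeParams, generate_cohort

__all__ = ["sign_recovery", "null_calibration", "SIGN_CHECKS"]

SIGN_CHECKS = [
    "fluency_psp_lt_pd",
    "fluency_psp_lt_hc",
    "uniqueness_psp_lt_pd",
    "uniqueness_psp_lt_hc",
    "fluency_uniqueness_r_pos_hc",
    "fluency_uniqueness_r_pos_pd",
    "fluency_uniqueness_r_neg_psp",
    "dose_fluency_r_pos_psp",
    "dose_uniqueness_r_neg_psp",
]


def _one_seed_signs(params: GenerativeParams,
                    lexicon: CategoryLexicon) -> dict[str, bool]:
    bundle = run_analysis(generate_cohort(params, lexicon), AnalysisConfig())
    means = bundle.scores.groupby("group")[["fluency", "uniqueness"]].mean()
    corr = {pc.x.split("[")[1].rstrip("]"): pc.r
            for pc in bundle.fluency_uniqueness}
    dose = {pc.y: pc.r for pc in bundle.levodopa_effects}
    psp, pd_, hc = Group.PSP_RS.value, Group.PD.value, Group.HC.value
    return {
        "fluency_psp_lt_pd": means.loc[psp, "fluency"] < means.loc[pd_, "fluency"],
        "fluency_psp_lt_hc": means.loc[psp, "fluency"] < means.loc[hc, "fluency"],
        "uniqueness_psp_lt_pd":
            means.loc[psp, "uniqueness"] < means.loc[pd_, "uniqueness"],
        "uniqueness_psp_lt_hc":
            means.loc[psp, "uniqueness"] < means.loc[hc, "uniqueness"],
        "fluency_uniqueness_r_pos_hc": corr[hc] > 0,
        "fluency_uniqueness_r_pos_pd": corr[pd_] > 0,
        "fluency_uniqueness_r_neg_psp": corr[psp] < 0,
        "dose_fluency_r_pos_psp": dose["fluency"] > 0,
        "dose_uniqueness_r_neg_psp": dose["uniqueness"] < 0,
    }


def sign_recovery(n_seeds: int = 50, seed0: int = 0,
                  params: GenerativeParams | None = None) -> dict[str, float]:
    """Fraction of seeds recovering each qualitative sign (keys SIGN_CHECKS)."""
    base = params or GenerativeParams()
    lexicon = default_animal_lexicon()
    hits = {name: 0 for name in SIGN_CHECKS}
    for i in range(n_seeds):
        signs = _one_seed_signs(replace(base, seed=seed0 + i), lexicon)
        for name, ok in signs.items():
            hits[name] += bool(ok)
    return {name: hits[name] / n_seeds for name in SIGN_CHECKS}


def null_calibration(n_seeds: int = 100, seed0: int = 0,
                     params: GenerativeParams | None = None) -> float:
    """Rejection rate of the uniqueness ANCOVA under the true null generator."""
    base = (params or GenerativeParams()).null()
    lexicon = default_animal_lexicon()
    rejections = 0
    for i in range(n_seeds):
        cohort = generate_cohort(replace(base, seed=seed0 + i), lexicon)
        bundle = run_analysis(cohort, AnalysisConfig())
        res = next(r for r in bundle.group_tests if r.outcome == "uniqueness")
        rejections += bool(res.significant)
    return rejections / n_seeds
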