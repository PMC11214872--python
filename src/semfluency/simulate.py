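"""Synthetic fluency-cohort generator.

Emulates the statistical structure a timed category-fluency study assumes,
so every downstream stage (scoring, ANCOVA, partial correlations) can be
exercised and calibrated without access to clinical data.

Generative mechanism (per participant i in group g):

* a retrieval **budget** ``k_i = round(mu_g + beta_f * dose_i + eps)`` with
  ``eps ~ N(0, sigma)`` — how many distinct words the participant retrieves
  in the minute;
* a **typicality** exponent
  ``theta_i = theta_g + c_g * (k_i - mu_g)/sigma + beta_u * dose_i`` that
  sharpens or flattens the word-frequency distribution the participant
  samples from: word of frequency rank r has weight ``r ** (-s * theta_i)``
  (Zipf-like, heavy-tailed).  Sharper sampling (larger theta) yields commoner
  words, hence lower pooled uniqueness;
* ``k_i`` distinct words drawn sequentially without replacement with those
  weights, from the first V entries of the category lexicon (file order =
  frequency rank);
* repetitions and out-of-category intrusions injected at small per-token,
  per-group rates;
* age and education from per-group normal distributions;
* for the PSP-RS group, a levodopa dose (mg/day) plus occasional MAO-B
  inhibitors, so the other-drug LED covariate varies.

The **coupling** ``c_g`` links an individual's budget deviation to their
typicality.  Negative coupling (HC, PD defaults) makes high-fluency
individuals sample *flatter* — rarer words, higher uniqueness — producing a
positive fluency-uniqueness correlation; positive coupling (PSP-RS default)
produces the opposite trade-off.  The dose coefficients raise fluency
(``beta_f > 0``) while sharpening typicality (``beta_u > 0``), i.e. lowering
uniqueness.  This mechanism is illustrative — one of several that yield the
same correlation structure — not a claim about retrieval in the brain.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np

from .lexicon_io import CategoryLexicon, Cohort, Group, Transcript, default_animal_lexicon

__all__ = ["GenerativeParams", "generate_participant", "generate_cohort"]

# Out-of-category productions for the intrusion channel.
INTRUSION_WORDS = ["lotus", "rose", "chair", "apple", "cloud", "river"]

_THETA_MIN, _THETA_MAX = 0.05, 5.0


def _gmap(psp: float, pd: float, hc: float) -> dict[Group, float]:
    return {Group.PSP_RS: psp, Group.PD: pd, Group.HC: hc}


@dataclass
class GenerativeParams:
    """All knobs of the synthetic cohort model.

    Defaults are design-time fixtures chosen so that group fluency means land
    in the plausible 10-25 words/minute range with the study's group sizes
    (27/35/40), the fluency-uniqueness coupling is positive in HC/PD and
    negative in PSP-RS, and the levodopa dose raises fluency while lowering
    uniqueness in PSP-RS.
    """

    seed: int = 0
    vocab_size: int = 200
    zipf_exponent: float = 1.1
    group_sizes: dict[Group, int] = field(
        default_factory=lambda: {Group.PSP_RS: 27, Group.PD: 35, Group.HC: 40})
    budget_mean: dict[Group, float] = field(
        default_factory=lambda: _gmap(9.0, 17.0, 20.0))
    budget_sd: float = 4.0
    typicality_base: dict[Group, float] = field(
        default_factory=lambda: _gmap(1.0, 0.9, 0.9))
    coupling: dict[Group, float] = field(
        default_factory=lambda: _gmap(+0.35, -0.15, -0.15))
    # levodopa (PSP-RS only): dose distribution and effect coefficients
    levodopa_mean: float = 330.0
    levodopa_sd: float = 150.0
    levodopa_treated_p: float = 24 / 27
    beta_fluency: float = 0.012       # words per mg/day
    beta_typicality: float = 0.0015   # theta units per mg/day
    # occasional MAO-B inhibitors so other-drug LED varies within PSP-RS
    rasagiline_p: float = 4 / 27
    rasagiline_dose: float = 1.0
    selegiline_p: float = 3 / 27
    selegiline_dose: float = 5.0
    rep_rate: dict[Group, float] = field(
        default_factory=lambda: _gmap(0.05, 0.02, 0.02))
    intrusion_rate: dict[Group, float] = field(
        default_factory=lambda: _gmap(0.015, 0.0, 0.0))
    age_mean: dict[Group, float] = field(
        default_factory=lambda: _gmap(63.5, 62.3, 59.9))
    age_sd: dict[Group, float] = field(
        default_factory=lambda: _gmap(6.7, 8.9, 6.4))
    education_mean: dict[Group, float] = field(
        default_factory=lambda: _gmap(10.7, 12.1, 11.5))
    education_sd: dict[Group, float] = field(
        default_factory=lambda: _gmap(3.5, 3.2, 1.8))

    def __post_init__(self) -> None:
        self.group_sizes = {Group(g): int(n) for g, n in self.group_sizes.items()}
        for name in ("budget_mean", "typicality_base", "coupling", "rep_rate",
                     "intrusion_rate", "age_mean", "age_sd",
                     "education_mean", "education_sd"):
            setattr(self, name,
                    {Group(g): float(v) for g, v in getattr(self, name).items()})
        if self.vocab_size < 1 or self.zipf_exponent <= 0:
            raise ValueError("vocab_size >= 1 and zipf_exponent > 0 required")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for {g} must be >= 1")
        for rates in (self.rep_rate, self.intrusion_rate):
            for g, r in rates.items():
                if not 0 <= r < 1:
                    raise ValueError(f"rate {r} for {g} outside [0, 1)")
        if self.budget_sd < 0 or self.levodopa_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.levodopa_treated_p <= 1:
            raise ValueError("levodopa_treated_p must be in [0, 1]")

    def null(self) -> "GenerativeParams":
        """A true no-group-effect configuration for type-I calibration.

        Zeroes the fluency-typicality coupling and both dose coefficients and
        equalizes budgets and typicality across groups, so all participants
        sample under identical conditions and any detected group difference
        is a false positive.
        """
        mid_budget = float(np.mean(list(self.budget_mean.values())))
        mid_theta = float(np.mean(list(self.typicality_base.values())))
        return replace(
            self,
            coupling=_gmap(0.0, 0.0, 0.0),
            beta_fluency=0.0,
            beta_typicality=0.0,
            budget_mean=_gmap(mid_budget, mid_budget, mid_budget),
            typicality_base=_gmap(mid_theta, mid_theta, mid_theta),
            rep_rate=_gmap(0.02, 0.02, 0.02),
            intrusion_rate=_gmap(0.0, 0.0, 0.0),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, dict):
                d[key] = {(k.value if isinstance(k, Group) else k): v
                          for k, v in val.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _weighted_sample_without_replacement(
    k: int, weights: np.ndarray, rng: np.random.Generator
) -> list[int]:
    """Sequential weighted draws (successive-sampling / Wallenius style)."""
    available = np.ones(len(weights), dtype=bool)
    picked: list[int] = []
    for _ in range(k):
        w = np.where(available, weights, 0.0)
        total = w.sum()
        if total <= 0:
            break
        idx = int(rng.choice(len(w), p=w / total))
        available[idx] = False
        picked.append(idx)
    return picked


def generate_participant(
    g: Group,
    params: GenerativeParams,
    rng: np.random.Generator,
    participant_id: str,
    vocab: list[str],
) -> Transcript:
    """Draw one participant's transcript under the generative mechanism."""
    g = Group(g)
    mu = params.budget_mean[g]
    sigma = max(params.budget_sd, 1e-12)

    dose = 0.0
    meds: dict[str, float] = {}
    if g is Group.PSP_RS:
        if rng.random() < params.levodopa_treated_p:
            dose = float(np.clip(
                rng.normal(params.levodopa_mean, params.levodopa_sd), 50.0, 900.0))
            dose = round(dose / 50.0) * 50.0
            meds["levodopa"] = dose
        if rng.random() < params.rasagiline_p:
            meds["rasagiline"] = params.rasagiline_dose
        if rng.random() < params.selegiline_p:
            meds["selegiline"] = params.selegiline_dose

    k = int(round(mu + params.beta_fluency * dose + rng.normal(0.0, sigma)))
    k = int(np.clip(k, 0, min(params.vocab_size, len(vocab))))

    theta = (params.typicality_base[g]
             + params.coupling[g] * (k - mu) / sigma
             + params.beta_typicality * dose)
    theta = float(np.clip(theta, _THETA_MIN, _THETA_MAX))

    ranks = np.arange(1, min(params.vocab_size, len(vocab)) + 1, dtype=float)
    weights = ranks ** (-params.zipf_exponent * theta)
    picked = _weighted_sample_without_replacement(k, weights, rng)
    base_words = [vocab[i] for i in picked]

    tokens: list[str] = []
    rep_rate = params.rep_rate[g]
    intr_rate = params.intrusion_rate[g]
    for word in base_words:
        if tokens and rng.random() < rep_rate:
            tokens.append(str(rng.choice([t for t in tokens
                                          if t in set(base_words)])))
        if rng.random() < intr_rate:
            tokens.append(str(rng.choice(INTRUSION_WORDS)))
        tokens.append(word)

    age = int(np.clip(round(rng.normal(params.age_mean[g], params.age_sd[g])),
                      45, 80))
    education = int(np.clip(
        round(rng.normal(params.education_mean[g], params.education_sd[g])),
        5, 22))
    return Transcript(
        participant_id=participant_id,
        group=g,
        tokens=tokens,
        age=age,
        education=education,
        meds=meds,
    )


def generate_cohort(
    params: GenerativeParams, lexicon: CategoryLexicon | None = None
) -> Cohort:
    """One Transcript per participant per group; deterministic given params.

    The sampling vocabulary is the first ``vocab_size`` canonical entries of
    the lexicon (defaults to the packaged animal lexicon, whose file order is
    the frequency rank).
    """
    if lexicon is None:
        lexicon = default_animal_lexicon()
    if len(lexicon.canonical) < params.vocab_size:
        raise ValueError(
            f"lexicon has {len(lexicon.canonical)} canonical words "
            f"< vocab_size {params.vocab_size}"
        )
    vocab = list(lexicon.canonical[: params.vocab_size])
    rng = np.random.default_rng(params.seed)
    transcripts = []
    prefix = {Group.PSP_RS: "PSP", Group.PD: "PD", Group.HC: "HC"}
    for g in (Group.PSP_RS, Group.PD, Group.HC):
        n = params.group_sizes.get(g, 0)
        for i in range(1, n + 1):
            transcripts.append(
                generate_participant(
                    g, params, rng, f"{prefix[g]}{i:03d}", vocab)
            )
    return Cohort(
        transcripts,
        provenance={
            "generator": "semfluency.simulate",
            "seed": str(params.seed),
            "params_sha256": params.digest(),
        },
    )
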