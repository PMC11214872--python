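# Methods

## Scoring model

Each participant's transcript is an ordered list of raw productions from a
one-minute category-fluency task (animals).  Tokens are normalized
(lowercase, trimmed, internal whitespace collapsed) and mapped through a
synonym table onto a canonical vocabulary; the lexicon is an input, shipped
as a 200-word default, because category membership is language- and
culture-dependent.  Scanning in production order yields four parameters:

* **fluency** — the number of *distinct* canonical in-category words;
* **repetitions** — in-category productions whose canonical form was already
  produced by the same participant (so a synonym of an earlier word, e.g.
  "puppy" after "dog", is a repetition);
* **incorrect** — out-of-category productions, counted every time they occur
  (an out-of-category duplicate is another incorrect word, never a
  repetition);
* **uniqueness** — the mean over the participant's distinct correct words of
  1/N, where N is the number of participants in the *entire pooled sample*
  (all groups jointly) whose correct-word set contains that word.

Conservation (`fluency + repetitions + incorrect = token count`) holds by
construction.  N counts distinct participants, not tokens, and each
participant is included in their own N, so N ≥ 1 and uniqueness lies in
[1/M, 1] for a pooled sample of M participants.  A participant with zero
correct words has *undefined* uniqueness (a mean over an empty set); they are
excluded from uniqueness-based analyses only, and the exclusion is logged.
Because the index pools all groups, uniqueness is invariant under permutation
of group labels — a property the test suite checks directly.

## Inference plan

**Group comparisons.**  Each of the four parameters is tested with a linear
model `outcome ~ intercept + group (2 dummies) + age + education`; the group
effect is the F of the full-vs-reduced residual-sum-of-squares comparison
(Type-III style, unambiguous with a single factor), df1 = 2 and
df2 = n − 3 − k for k covariates (97 for n = 102, k = 2).  The effect size is
partial eta squared, SS_group/(SS_group + SS_error) = F·df1/(F·df1 + df2).
Covariate columns with zero variance are dropped (logged on the result), so
the model degrades gracefully to plain one-way ANOVA; genuinely collinear
designs raise a singularity error naming the columns.  The four tests share a
Bonferroni family (corrected alpha 0.05/4 = .013 as displayed).  Significant
omnibus tests are followed by pairwise pooled-variance (Student) t-tests with
df = n_a + n_b − 2; pooled rather than Welch because with a single factor and
matched covariate sets the classical post hoc convention applies, and the
pooled dfs are what the group sizes imply (60 and 65 for 27 vs 35 and 27 vs
40).

**Partial correlations.**  x and y are each residualized on
[intercept, covariates] by least squares and r is the Pearson correlation of
the residuals; p comes from t = r·sqrt((n − 2 − k)/(1 − r²)) on n − 2 − k
degrees of freedom, two-tailed.  With k = 0 this is exactly Pearson's r.  The
fluency–uniqueness correlations control age and education within each group
(family of three, alpha .017); the dose analysis within PSP-RS correlates the
actual levodopa dose (raw mg/day) with fluency and uniqueness controlling the
levodopa-equivalent dose of all *other* drugs, age and education (family of
two, alpha .025).  A variable lying in the covariate column space leaves a
zero residual vector and raises an explicit error rather than returning a
spurious r.

**Demographics screening.**  Numeric features are tested with one-way ANOVA
when every group passes a per-group Shapiro–Wilk screen at 0.05 (the screen
alpha is configurable; any fixed rule is a convention, and this one is a
common default), Kruskal–Wallis otherwise; sex tables get a chi-square test
of independence.  All demographics tests share a family of 13 (alpha .004 as
displayed).

**Missing data** are removed listwise per analysis and the dropped count is
recorded on each result.  Machine output keeps full precision; the text
report rounds statistics to 2 decimals and p-values/alphas to 3, half-up.

## Levodopa-equivalent dose

LED(drug) = dose × factor, with the standard Tomlinson et al. (2010)
conversion factors stored in a version-stamped YAML config (levodopa 1,
pramipexole 100, piribedil 1, selegiline 10, rasagiline 100, amantadine 1,
dopamine agonists as listed).  COMT inhibitors are *augmenters*: entacapone
adds 0.33 × the concurrent levodopa LED.  The breakdown keeps the levodopa
component separate from everything else; augmenter contributions are assigned
to the other-drug component, so "actual levodopa dose" used in the dose
analysis stays the raw mg/day figure.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the retrieval process in the brain.  For participant i in group g:

1. retrieval budget `k_i = round(mu_g + beta_f·dose_i + eps)`,
   `eps ~ N(0, sigma)`, clipped to [0, V];
2. typicality exponent
   `theta_i = theta_g + c_g·(k_i − mu_g)/sigma + beta_u·dose_i`, clipped to
   [0.05, 5];
3. `k_i` distinct words drawn sequentially without replacement with weight
   `rank^(−s·theta_i)` over the first V = 200 lexicon entries (file order =
   frequency rank; s = 1.1 gives a heavy-tailed, Zipf-like vocabulary);
4. repetitions and intrusions injected at per-token, per-group rates;
5. age and education drawn from per-group normals; PSP-RS participants
   receive a levodopa dose (≈89% treated, mean 330, SD 150 mg/day, rounded
   to 50 mg) and occasionally rasagiline (1 mg) or selegiline (5 mg) so the
   other-drug LED covariate varies.

The coupling `c_g` is the load-bearing mechanism: negative in HC and PD
(−0.15), so higher-budget individuals sample *flatter* and reach rarer
words — a positive fluency–uniqueness correlation; positive in PSP-RS
(+0.35), producing the opposite trade-off.  The dose coefficients
(`beta_f` = 0.012 words per mg, `beta_u` = 0.0015 theta per mg) raise fluency
while sharpening typicality, i.e. lowering uniqueness.  Group budget means
(9/17/20 before the dose contribution) and typicality bases (1.0/0.9/0.9)
were fixed once, at design time, so that group fluency means land in the
plausible 10–25 words/minute range with group sizes 27/35/40; they are
fixtures of the simulator, not estimates of any dataset.  This
typicality-coupling mechanism is one of several that could produce the same
correlation signs; it is documented as illustrative.

**No-effect configuration.**  `GenerativeParams.null()` zeroes the coupling
and both dose coefficients *and equalizes budget means and typicality across
groups*.  Equal budgets matter: even with identical sampling exponents, a
participant who produces more words reaches rarer words and mechanically
scores higher uniqueness, so unequal budgets alone create a real group
gradient.  The null configuration removes every channel, making the measured
rejection rate of the uniqueness ANCOVA a genuine type-I calibration of the
whole pipeline (measured ≤ a few percent over 100 seeds at corrected
alpha .013).

**What the generator does not emulate:** semantic clustering and switching
dynamics, within-minute time structure, culture-specific vocabularies,
measurement error in transcription, and any correlation between age/education
and performance (covariates are pure noise here).  Passing sign-recovery
tests therefore show that the *pipeline* recovers the structure the generator
encodes, not that the structure holds in any clinical population.

## Validation problem sizes

Scoring is checked against an independent brute-force recount on 1000 random
micro-cohorts (≤ 10 participants, 8-word vocabulary plus intruders); ANCOVA
and partial correlations against explicit normal-equation oracles on 100
random ≤ 30-row fixtures (1e-8) and against `pingouin.partial_corr` on a
subset; sign recovery uses 50 independent seeds of the full 102-participant
pipeline and null calibration 100 seeds — sizes chosen to make the Monte
Carlo stable (binomial SE ≤ ~6 points) while keeping the whole suite fast.

## Known limitations

* The synonym table defines word identity; no fuzzy matching, so unseen
  spelling variants count as intrusions.
* The sequential weighted draw is one convention for sampling without
  replacement; the acceptance surface does not depend on its exact
  distributional form.
* Post hoc t-tests are uncorrected for covariates by design (classical
  convention); adjusted contrasts would need a different df accounting.
* The demographics normality screen is a convention, configurable but
  necessarily arbitrary at small n.
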