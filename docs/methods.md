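# Methods

## Scoring model

Each modified Magee equation is an affine function of routine pathology
variables: Nottingham score (3–9), modified ER and PR H-scores (0–300),
a HER-2 term, tumor size (cm), and Ki-67 (%). The coefficients ship in
`src/romma/data/magee_equations.yaml`, transcribed from the public
Magee-equation calculator (URL and transcription date in the file header);
they are configuration, not code, so alternative coefficient sets can be
loaded without touching the engine. ER and PR H-scores are accepted as
already-computed integers — the derivation from staining intensity/percent
classes is upstream of this package.

HER-2 resolution is deterministic: FISH overrides IHC whenever present
(amplified → positive, not amplified → negative); without FISH, IHC 0/1+ is
negative, 3+ positive, and 2+ remains *equivocal*. An unresolved equivocal
makes every equation with a HER-2 term non-computable and the case is
flagged rather than silently classified. The equivocal entries in the
coefficient config are retained for completeness and auditability even
though the engine never scores an unresolved case with them.

An equation is computable iff all its required predictors are present; the
amMs is the arithmetic mean over computable equations (1, 2, or 3 of them —
`n_equations_used` is always reported). A case with missing Ki-67 is scored
by eq2 alone; missing tumor size leaves eq3. Scores are carried unrounded
internally; display rounds to one decimal, and every threshold comparison
uses the unrounded value to avoid boundary artifacts from display rounding.

## Decision rules

Categories are assigned in order: lowest risk (amMs ≤ 9), low risk
(amMs ≤ 12 *or* histologic criteria: NS < 6, ER ≥ 150 **and** PR ≥ 150,
Ki-67 < 10%), high risk (amMs > 30), else intermediate. Only intermediate
cases are recommended for send-out testing. Two readings of the published
histologic rule were possible ("ER and PR H-score ≥ 150" could mean either
one suffices); this package requires **both** H-scores to clear 150, the
literal reading, and exposes the thresholds for sensitivity analysis. The
histologic rule precedes the high-risk comparison, so a (practically
unreachable) case meeting it with amMs > 30 would be called low risk; with
Ki-67 < 10% and both H-scores ≥ 150 the equations cannot produce such a
score under the default coefficients. A missing Ki-67 makes the histologic
rule indeterminate (treated as not met, flagged in the call's rationale).

Band boundaries are exactly as configured and tested: amMs = 12 → low,
amMs = 30 → intermediate, amMs = 18 → predicted below the ODXRS-26
boundary (the ≤ 18 form of the rule is used, inclusive).

## Statistics

* **2×2 diagnostic accuracy** — sensitivity, specificity, PPV, NPV as count
  ratios; odds ratio as the cross-product, reported as ∞ (never adjusted)
  when an off-diagonal cell is zero. The association p-value is a two-sided
  Fisher exact test: exact, reproducible, and free of continuity-correction
  ambiguity; for the large published table it reproduces p < 0.0001. The
  odds-ratio 95% CI uses the Woolf log method — a package addition, since
  the published tables print none.
* **Band agreement** — cumulative amMs groups (< 9, ≤ 10, ≤ 11, ≤ 12, ≤ 14,
  ≤ 15, < 18, the histologic-criteria row, > 30) crossed with ODX bands
  (low < 18, intermediate 18–30, high > 30); the percent-concordant column
  is ODX-low for every group except > 30, where it is ODX-high.
* **Discordance** — both scores are banded on the ODX criteria; the label is
  the band distance (concordant / one-step / two-step).
* **Outcomes** — analyses are patient-level (a patient with multiple tumors
  takes the highest-risk call). Covariate odds ratios reuse the 2×2
  machinery; unknown and suspicious LVI/LN statuses are excluded from
  denominators, never imputed. The group-mean test is Welch's unequal-
  variance t-test, the robust default for the very unbalanced recurrence
  groups (~18 vs ~280). The chi-squared independence test defaults to the
  uncorrected statistic.
* **Cost model** — institutional savings are exact integer-cent arithmetic
  (avoided tests × list price, default $4,620). The national extrapolation
  is round(126,740 × 0.85) = 107,729 candidate cases; the avoidable
  fraction (default 20.8% + 2.8% = 23.6%) is kept *unrounded* in the dollar
  product and only the final figure is rounded — that is the only order of
  operations that reproduces the published $117,459,083 (rounding the case
  count first gives 25,424 × $4,620 = $117,458,880).

## Synthetic cohorts

The generator emulates the cohort structure the analyses assume, not any
real patient population. Each case first draws a target stratum — low risk
20.8% (of which 15% qualify only histologically), high risk 2.8%, the rest
intermediate, matching the published triage fractions — and pathology
inputs are then rejection-sampled from stratum-appropriate distributions
until the amMs computed **with the real equations on the equations actually
computable for that case** lands in the stratum. Stratum frequencies are
therefore multinomial around their targets by construction. Ki-67 and
tumor size are missing at the observed availability rates (5.9% and 0.3%);
missingness is drawn before stratum acceptance so it cannot shift the
frequencies, and the two are never missing together (which would leave no
computable equation). Every generated equivocal IHC receives a FISH result,
as in routine reflex practice.

The ODXRS follows a linear-Gaussian link, `clip(round(slope·amMs +
intercept + N(0, sd)), 0, 100)` with defaults slope 1.1, intercept 0,
sd 4 — two interpretable knobs calibrated once so that ≥ 95% of amMs ≤ 18
cases fall below ODXRS 26, mirroring the published 98% without overfitting
to it. Recurrence is Bernoulli with a logistic model whose signs encode the
reported associations (higher Ki-67 +, lower PR −, node positivity +,
LVI +) and whose intercept puts the overall recurrence rate in the
single-digit percent range. Node/LVI/chemotherapy rates tilt upward with
stratum severity; follow-up is uniform on 5–11 years.

What the generator does **not** model: inter-observer IHC variability,
pre-analytic tissue effects, site effects, non-linear or heteroscedastic
amMs–ODXRS structure, informative missingness, and time-to-event outcome
structure. Passing tests on synthetic cohorts therefore demonstrate the
*pipeline's* correctness and calibration-recovery behavior, not clinical
performance on real data.

## Numerical and design choices

* Integer rounding of the generated ODXRS means a "zero-noise" cohort is
  rank-correlated with the amMs only up to ties; slope recovery is exact to
  well under 1%.
* Problem sizes in the test and acceptance runs (2,000–5,000 synthetic
  cases, 10,000 fuzzed classifier calls, exhaustive 2×2 enumeration up to
  cell count 6) were chosen as the smallest sizes at which the binomial /
  Monte-Carlo error bands in the assertions are comfortably narrow.
* The Fisher oracle in the tests enumerates the hypergeometric support
  directly and is independent of the scipy routine it checks.
* `round()` (banker's rounding) is used for the cost model's case counts;
  at the published parameter values no half-way cases arise.

## Known limitations

* The package does not re-fit equation coefficients, compute IHC4/IHC4+C
  scores, or model survival (no Kaplan-Meier/Cox); follow-up is summarized
  descriptively.
* The published low-risk outcome denominators (45- and 116-patient filtered
  groups) depend on a patient-flow filter chain described only in prose;
  the filters shipped here (`--require-hormonal`, `--exclude-chemo`)
  implement that chain as explicit predicates, and the published endpoint
  counts are carried as reference constants rather than re-derived from
  per-patient data, which were not released.
* One published outcome odds ratio (LN involvement, printed as 2.0) is not
  reproducible from its own printed counts (5/18 vs 47/270 gives ≈ 1.8);
  this package always computes from counts and will disagree with that
  printed value by design.
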