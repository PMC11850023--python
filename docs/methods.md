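# Methods

## The inference problem

A learner must decide which of two jars a set of balls was drawn from. Each
jar has a known colour composition (by default a 5:1 mixture, e.g. mostly
red vs. mostly yellow). The learner receives two kinds of evidence: a
unanimous majority of informants who each endorse one jar, and one piece of
dissenting information — either a dissenting informant or a ball the
learner observed directly. The crucial manipulation is whether the
majority's members each drew a private ball (**independent** evidence) or
all inspected a single common ball (**shared** evidence). A normative
learner should discount the shared majority: its n endorsements carry
roughly one ball's worth of evidence.

## The ideal observer

The observer scores each hypothesis h (jar) by Bayes' rule,

    p(h | e, t_1..t_n)  ∝  p(t_1..t_n | h) · p(e | h) · p(h),

with a uniform prior unless configured otherwise. The learner's own draws
enter through the jar composition directly, `p(e|h) = count(e)/total`.

Informant endorsements are modelled through the informant's unseen draw d:

* **maximize** — the informant deterministically endorses the jar with the
  highest `p(d|h)p(h)`, splitting uniformly over exact ties;
* **probability_match** — the informant endorses each jar with probability
  equal to its single-datum posterior, `p(t=h|d) ∝ p(d|h)p(h)`.

A single testimony's likelihood marginalizes the draw:
`p(t|h) = Σ_d p(d|h) p(t|d)`. Independent sets multiply these. For a shared
set the marginalization runs over the one common draw d′, and two readings
are implemented as first-class options:

* `literal_product` — every informant reacts to the shared ball:
  `Σ_d′ p(d′|h) Π_i p(t_i|d′)`. Under probability matching, later
  endorsements still carry *some* information (they are independent noisy
  readings of the same ball).
* `copy_after_first` — informants after the first deterministically voice
  agreement with the first endorsement, as scripted shared-evidence stimuli
  have them do: `Σ_d′ p(d′|h) p(t_1|d′)` for a unanimous set, likelihood
  zero for a non-unanimous one. A shared unanimous majority then carries exactly
  one testimony's worth of evidence, independent of its size.

For maximizing informants with no tie colours the two variants coincide.

A posterior is mapped to a predicted choice proportion by a response rule:
`posterior_match` (identity; a population of probability-matching
responders) is the default, because the reference predictions are graded,
non-extreme bars; `posterior_maximize` (threshold at 1/2) is available.

All probabilities are computed in plain floating point — the largest
products involve four factors of simple rationals, so there is no need for
log-space — and the test suite cross-checks every likelihood against exact
`fractions.Fraction` enumeration over all colour assignments (tolerance
1e-12).

## Experimental designs

`builtin_conditions(k)` returns the four cells of design k:

* **Design 1** (balls): jars 5:1 plus one distractor ball unique to each
  jar (one white in the mostly-red jar, one green in the mostly-yellow);
  the distractors were visible and therefore enter the likelihoods, though
  they are never sampled. Dissenting-informant cells use 2-person
  majorities plus 1 dissenter; own-ball cells use 3-person majorities plus
  one opposite-colour ball shown to the learner (total informant count was
  equated rather than majority size).
* **Design 2** (toys): plain two-colour 5:1 jars, 3-person majorities in
  every cell.
* **Design 3** (visible samples, no testimony): the draws themselves are
  shown — three majority-colour cups plus one dissenting cup (independent)
  or one cup of each colour (shared). With no testimony the informant
  strategy never enters, so maximizing and probability-matching predictions
  coincide exactly.

Counterbalancing of which jar is "the majority jar" cannot affect the
predictions (label-swap symmetry, property-tested), so prediction tables
are computed for one orientation.

## The independence-effect statistic

`independence_effect` reduces a four-cell prediction table to

    100 × mean over dissent conditions of (p_majority[independent] − p_majority[shared]),

an unweighted mean of the two dissent conditions; a per-condition breakdown
is always available because alternative weightings are conceivable.

The reference figure for this statistic under the probability-matching
observer is 26%. Our exact enumeration gives, for the probability-matching
observer with the identity response rule:

| design reading | literal_product | copy_after_first |
|---|---|---|
| design 1 as run (2/3-person majorities, distractors) | 21.86 | 36.96 |
| equal 3-person majorities, plain 5:1 jars | 25.48 | 40.38 |
| equal 3-person majorities, distractor jars | 27.25 | 44.42 |

Only the equal-majority, plain-jar, literal-product configuration is
consistent with the printed 26 (to within rounding); that configuration is
also the one the canonical three-informant task narrative describes and the
one design 2 implements. `scripts/acceptance.py` therefore reports that
value as the headline statistic and prints all readings side by side. The
copy-after-first variant matches the verbal predictions for the *shared +
dissenting informant* cell (exactly at chance) but not the printed average;
the literal variant leaves that cell slightly above chance (0.63–0.65).

A related exactness caveat: the maximizing observer's at-chance prediction
for shared majorities holds exactly in the dissenter cells (posterior
exactly 1/2, distractors included — the concurring and dissenting draws
cancel), but in the shared + own-ball cell with distractor jars the
cancellation is broken by the distractors' asymmetric support (posterior
6/11 ≈ 0.545); with plain two-colour jars it is exactly 1/2. Both facts
are asserted in tests.

## Synthetic cohorts

`simulate_cohort` emulates the between-subjects designs: `n_per_cell`
participants per cell, binary choice of the majority-consistent jar, ages
uniform integers over 45–71 months (the widest range across the designs),
majority jar alternating deterministically within a cell (split differs by
at most one), one seeded generator per cohort so identical configurations
are bit-identical. Strategies:

* `bayesian` — choices are Bernoulli draws around the ideal observer's
  cell probability (any strategy/variant/rule);
* `conform` — always the majority;
* `own_data` — follows the own sample with probability `theta` in
  own-observation cells, otherwise chooses the majority with probability
  `phi` (the candidate heuristic families are this package's
  operationalization; no quantitative heuristic model is given in the
  source designs);
* `uniform` — coin flip.

Evidence is scripted exactly as in the experiments (the majority always
endorses the pre-assigned jar; the dissenting sample is always opposite).
A `generative=True` flag instead samples evidence from the assigned jar —
exploration only, never used by tests. Age has no effect by default (at
most marginal effects were observed); an optional logistic `age_slope` per
month is available.

What the generator deliberately does **not** emulate: verbal
justifications, exclusion criteria (inattentiveness, experimenter error),
per-cell sample-size imbalance (design 1 ran 24/24/30/30), or any real
heterogeneity across children. Passing tests therefore show the pipeline's
statistical machinery is calibrated, not that children behave like any of
these strategies.

`estimate_strategy` recovers `theta`/`phi` (or per-cell saturated rates) by
maximum likelihood — for these families the MLEs are cell proportions —
with exact Clopper-Pearson 95% intervals; degenerate all-0/all-1 cells are
flagged via a `boundary` field rather than raised.

## Statistical stage

* `endorsement_table` — per-cell k/n with exact (Clopper-Pearson)
  intervals.
* `fit_logistic` / `ChoiceLogit` — binomial GLM by IRLS (statsmodels),
  convergence tolerance 1e-10, at most 100 iterations. Two-level factors
  enter with sum-to-zero (+1/−1) contrasts; age, when included, is a
  centred linear term in months. Identical covariate rows are aggregated
  into binomial counts before the solver call (identical estimates, much
  faster simulation tests). Deviance is reported on the Bernoulli scale
  (−2 × maximized log-likelihood), so deviance differences between nested
  fits are likelihood-ratio statistics no matter how each fit grouped its
  rows. Complete separation raises a `SeparationError` naming the
  separating factor(s); detection is a finite-MLE check (|B| > 15 or a
  solver-reported separation).
* `lrt` — deviance difference with the chi-square reference; identical
  models give χ² = 0, df = 0, p = 1.
* `chance_test` — intercept-only fit on a condition subset (B = logit(k/n),
  SE = √(1/k + 1/(n−k)); chance responding is B = 0). The per-condition
  tests are run as subset fits; the factorial tests use the coded model.
* `compare_to_model` — per-cell observed-minus-predicted deviations with
  exact two-sided binomial tests against the model probability.
* `contingency_chisq` — Pearson chi-square (no continuity correction) with
  adjusted standardized residuals e_ij = (O−E)/√(E(1−row/N)(1−col/N)),
  for coded-justification tables; the verbal coding manual itself is out of
  scope.
* `cohens_kappa` — (p_o − p_e)/(1 − p_e) with p_e from marginal products;
  undefined (raised) when both coders are constant on one category.

No multiple-testing correction is applied anywhere, matching the reference
analysis. Wald p-values use the normal reference; intervals are Wald on the
log-odds scale, exponentiated.

## Problem sizes and numerical choices

The calibration checks use 2,000 null replicates at 200 per cell for the
LRT type-I error and 500 replicates per theta at 200 per cell for
parameter recovery — large enough that the Monte-Carlo error on a 5% rate
is ±0.5 points, and the whole suite stays inside a half minute on one core.
Tie-breaking in the maximizer is an exact uniform split; posterior
normalization guards against an all-zero joint likelihood by raising
(impossible-evidence combinations, e.g. a non-unanimous shared set under
deterministic copying). Exact-symmetry claims (posterior = 1/2) hold to
float equality because the cancelling products are IEEE-commutative.

## Known limitations

* The shared-evidence treatment behind the printed 26% statistic is
  reconstructed, not documented; we report every reading rather than
  claim certainty about the original computation.
* Only two-level factors are supported in the logistic stage (all designs
  here are 2×2, optionally plus age).
* The heuristic strategy families are illustrative; fitting them to the
  deposited participant data is deliberately out of scope.
* No modelling of informant reliability or deception, sequential cascade
  dynamics, or more than one dissenting source per condition.
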