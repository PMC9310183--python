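# Methods

## Model and assumptions

The receiver is an ideal Bayesian observer over a two-point intention
space, {affiliative, avoidant}. Four categorical cues enter the posterior:
the gesture and facial expression through the likelihood, the context
valence and dominance relation through the prior. Each cue is summarized by
a single weight θ ∈ [0, 1], the unnormalized multiplicative weight of the
avoidant intention; the affiliative intention receives 1 − θ. This is the
minimal construction that turns "0–0.5 leans affiliative, 0.5–1 leans
avoidant" into a proper two-point posterior: with it, each cue contributes
logit θ = log(θ/(1−θ)) to the posterior log-odds, so the model is an
additive logistic model over cue indicators. The implementation computes
the posterior as the normalized product of the four two-point weights;
`posterior_log_odds` provides the additive form as an algebraically
independent cross-check (the two agree to < 1e-12 everywhere both are
defined).

Assumptions worth stating explicitly:

- **Conditional independence.** Gesture and face contribute independently
  given the intention; context and dominance contribute independently to
  the prior. No interaction terms exist in this model family.
- **One-to-one reaction mapping.** The receiver's coded reaction equals
  the inferred intention, so the posterior avoidant probability is
  compared directly against observed avoidant-reaction proportions.
- **Exchangeability.** Records are exchangeable given their cue
  combination; individual identity, dyad history, and signal timing are
  outside the model.

The RSA layer fixes recursion depth at one pragmatic level (PR1 over PS1
over PR0) — deeper towers are not defined here. The literal receiver
normalizes the raw semantics row and applies **no** prior; the prior
enters only at PR1. Semantics rows are association strengths, not
distributions, and need not sum to 1. The pragmatic receiver's prior
defaults to uniform; a contextual prior from the cue-integration model can
be supplied instead through `RSAScenario(prior=...)`, which is how the two
model halves compose.

## Parameters

Reference cue weights (`default_parameters()`), all unitless weights in
[0, 1] with 0.5 neutral:

| parameter | value | reading |
|---|---|---|
| gesture.stretched_arm | 0.53 | weakly avoidant |
| gesture.bent_arm | 0.47 | weakly affiliative |
| facial.neutral | 0.50 | neutral |
| facial.bared_teeth | 0.60 | weakly avoidant |
| facial.funneled_lip | 0.90 | strongly avoidant |
| context.negative | 0.70 | avoidant-leaning prior |
| context.positive | 0.30 | affiliative-leaning prior |
| dominance.dominant_sender | 0.25 | affiliative-leaning prior |
| dominance.subordinate_sender | 0.75 | avoidant-leaning prior |

Sender rationality α is a continuous real ≥ 0; α = 0 is a uniform sender
(with the 0⁰ := 1 convention for zero literal probabilities), α → ∞ a
maximizing one. The object-choice scenarios use a vague point θ_u = 0.53
and α ∈ {1, 5, 10} as the reference configuration.

Registries are open: labels are data, and any registry with ≥ 1 label per
component works, with parameter files validated for exact coverage. The
default registry is 2 gestures × 3 facials × 2 contexts × 2 dominance
levels = 24 combinations. An absent facial expression is coded as the
`neutral` label (weight 0.5), which is exactly equivalent to omitting the
cue from the product.

## Synthetic data

No public coded interaction table exists for this system, so
`apecomm.synthetic` generates stand-ins with the statistical structure the
model assumes: combinations drawn i.i.d. from a frequency table, reactions
drawn Bernoulli with the model's posterior avoidant probability. The
default frequencies place 85% of events in the negative context (uniform
within context), emulating field data in which only negative-context
combinations accumulate enough observations to clear the ≥ 5 filter at
moderate sample sizes while keeping the positive context reachable for
tests. These defaults are declared stand-ins, not estimates of any real
distribution.

What passing tests on such data do show: the pipeline is internally
consistent (generate → summarize → correlate recovers the generating grid;
fitting recovers the generating parameters up to the identifiable
quantities). What they do not show: robustness to the features of real
interaction data that the generator omits — repeated dyads, individual
signatures, coder disagreement, non-stationary base rates, and any
dependence between cue combination and reaction beyond the model's own.

## Evaluation and numerical choices

- **Filter.** Per-combination summaries keep combinations with at least
  `min_n = 5` observations.
- **Bootstrap.** CIs resample the n reactions of a combination with
  replacement (equivalently Binomial(n, k/n)), B = 10,000 by default,
  percentile method with inverted-CDF quantiles — min{x : F̂(x) ≥ q} —
  which for a discrete resampling distribution coincides with the exact
  binomial quantile at large B. Seeds are mandatory; each combination gets
  an independent child stream of the caller's seed.
- **Correlation.** Pearson, unweighted by default; a count-weighted
  variant is available. Zero-variance cases (e.g. a context-only model
  evaluated on single-context data, which predicts a constant) raise an
  explicit `UndefinedCorrelationError` carrying the reason, and model
  comparison reports them per model instead of propagating NaN. Fewer than
  3 matched combinations is an `InsufficientDataError`.
- **Fitting.** Maximum likelihood in unconstrained log-odds coordinates.
  Because the posterior depends only on the *sum* of the four component
  log-odds, a constant can be shifted between any two component groups
  without changing any posterior: a 3-dimensional unidentifiable subspace.
  Fits therefore require anchors fixing at least one level in at least
  three of the four groups (default: neutral face at 0.5, positive context
  at 0.3, dominant sender at 0.25 — the reference values). The 24-cell
  prediction grid is always identifiable and is the primary recovery
  target; individual weights are meaningful only relative to the anchors.
  Optimization is L-BFGS-B with analytic gradients on the aggregated
  binomial likelihood, 5 seeded random restarts plus a neutral start,
  ftol 1e-8. Free parameters whose label never occurs in the data are
  flagged (`sparse_parameters`) and left at 0.5.
- **Degenerate inputs.** Hard cue weights (exactly 0 or 1) are legal in
  `infer_intention` — the posterior is then 0 or 1 — but two hard weights
  pulling in opposite directions make both intention weights zero and
  raise `DegeneratePosteriorError` rather than returning NaN.
  `posterior_log_odds` rejects hard weights outright. Ties in an
  object-choice semantics column resolve to the first utterance.
- **Tolerances.** Posterior normalization is asserted to 1e-9; the
  log-odds/product identity and the RSA enumeration cross-checks to
  1e-12; floating-point equality in tests uses absolute tolerance 1e-9
  unless the check is exact.

## Problem sizes

The test suite and the acceptance script use: 50,000 records for model
comparison, 2,000 records per cell (48,000 total) for parameter recovery,
B = 100,000 bootstrap replicates when checking calibration against exact
binomial quantiles at n ≤ 12, 1,000 random parameter draws for the
log-odds identity, and 200 random scenarios up to 4 × 4 for the RSA
enumeration check. These sizes hold the binomial noise comfortably below
the tolerances being asserted (e.g. at 2,000 per cell the per-cell SE is
≤ 0.011, against a 0.03 recovery tolerance).

## Known limitations

- The intention space is binary; graded or multi-dimensional intentions
  are out of scope.
- No utterance costs, lexical uncertainty, or convention-formation
  dynamics in the RSA layer; recursion depth is fixed at one.
- The reference cue weights are illustrative settings, not estimates; the
  fitting machinery exists precisely so they can be replaced by estimates
  when a coded dataset in the documented CSV schema is available.
- One narrative reading of the subordinate-sender example conflicts with
  the printed direction of ρ_ss = 0.75 under this parameter convention;
  the implementation follows the printed parameter definitions, and no
  test encodes the narrative example.
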