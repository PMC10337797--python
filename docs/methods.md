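# Methods

## The rater-as-channel model

A participant rating a stimulus on a bounded integer scale is modeled as a
discrete memoryless channel. The channel's input alphabet is the rating
scale (1–10 by default); the input symbol for a stimulus is the
participant's own settled judgment of it, operationalized as the mean of
the repeated ratings rounded to the nearest integer. Each individual
rating is an output symbol. The plug-in mutual information of the
per-block (input, output) contingency table estimates the bits transmitted
per rating. Since every stimulus in a block is presented equally often,
the source entropy of a k-stimulus block is log₂(k); sweeping k and
fitting a saturating curve to MI-vs-log₂(k) yields the capacity asymptote.

Assumptions worth stating explicitly:

- **Within-block inputs.** The input category is recomputed from the five
  ratings of that block only, never across blocks. Blocks are treated as
  independent channel uses.
- **Memorylessness.** Ratings are treated as conditionally independent
  given the stimulus; order and memory effects are ignored.
- **Full-scale tables.** Contingency tables always span the declared
  scale, including unused categories. This is mathematically inert for
  plug-in entropy/MI (zero cells contribute nothing) but keeps shapes
  stable, and it matters for bias corrections, so the Miller–Madow
  estimator lets you count categories as occupied (default) or declared.

## Estimators and conventions

- All information quantities are in **bits** (log base 2), with
  0·log 0 ≡ 0 by continuity.
- The headline estimator is the **plug-in** MI. It is upward-biased in
  small samples — a per-participant block contributes only 15–50 pairs to
  a 10×10 table — and the **Miller–Madow** first-order correction
  (subtract (Kₓ−1)(Kᵧ−1)/(2n·ln2), clip at 0) is provided as a
  diagnostic, not as the default, so that the headline numbers remain the
  plain plug-in quantities the curve is defined by.
- **Rounding** of mean ratings is half-to-even (the default of R's
  `round`, the environment the analysis convention comes from), switchable
  to half-up. A mean of five integer ratings can never land on a
  half-integer, so the tie rule only bites in leave-one-out mode, where
  means of four ratings are taken.
- **Leave-one-out mode** replaces the input for rating i by the rounded
  mean of the other repetitions, removing the self-dependence of the
  plug-in construction. On noiseless data it coincides with the plug-in
  construction exactly.
- **Aggregation.** MI is computed per participant per block and averaged
  across participants, with the population SD as the error bar — the
  convention implied by per-participant spread. A pooled mode
  (all participants' pairs in one table per block size) is also exposed;
  the two answer slightly different questions and are not interchangeable.
  Incomplete participants are dropped with a warning, never imputed,
  because MI on partial tables silently changes n.
- **Capacity fit.** I(H) = C·(1 − e^(−H/τ)), unweighted least squares,
  origin included by default (a source with no entropy transmits
  nothing). The functional form is a convention: the data constrain a
  plateau level, not a unique parametric curve, so `CapacityEstimate`
  carries its method label and residuals, and the asymptote should be read
  as fit-form dependent. Multiple starting points guard against local
  minima; an all-zero curve short-circuits to C = 0.
- The seven-point-to-ten-point scale conversion is the endpoint-preserving
  linear map 1 + 9(x−1)/6, used to place reference mean ratings on the
  analysis scale; `pearson_validate` then checks observed per-stimulus
  means against such references.

## The synthetic generator

`ExperimentDesign` defaults encode the study conditions: 50 participants;
four blocks of 3, 4, 6 and 10 stimuli; five repetitions each (15/20/30/50
trials per block, 5,750 ratings in all); a 1–10 scale; per-stimulus true
means uniformly spaced (to one decimal) between anchors 2.7 and 9.8, both
anchors present in every block so the rated range is constant across
blocks. Trial order is a seeded shuffle redrawn until no stimulus appears
twice in a row. The master seed spawns one substream per participant.

`ChannelSpec` models a rater as additive Gaussian noise on the true mean,
rounded to the nearest integer and clamped to the scale. The confusion
matrix is computed exactly from Gaussian interval probabilities with tails
folded into the end categories. An optional per-participant mean offset
(default 0) adds taste heterogeneity.

**Noise calibration.** The default σ = 0.48 was chosen once so that the
full default study, analyzed by the pipeline and fitted, measures a
capacity of ≈ 2.3 bits (mean fitted asymptote 2.30 across independent
seeds) — i.e. the generator emulates raters whose *measured* capacity sits
at the study's headline value. `calibrate_sigma` exposes the complementary
analytic calibration: the σ at which the largest block's channel-level MI
(`theoretical_block_mi`, ideal-observer input = rounded true mean) equals
a target; for 2.3 bits that gives σ ≈ 0.243. The two calibrations differ
because the pipeline's finite-sample estimate sits above the channel-level
value: the plug-in input contains the rating it predicts, n is small, and
the empirical mean input distinguishes stimuli whose true means round
together. That gap is a real property of the estimator — it is exactly
what the leave-one-out mode interrogates — so the package does not pretend
the two numbers coincide.

**Known shape of the curve.** In the 10-stimulus block the true means are
only ≈ 0.79 scale units apart (vs ≈ 1.42 in the 6-stimulus block), and two
pairs of means round to the same integer. For σ ≳ 0.2 this crowding makes
the mean MI of the largest block sit slightly *below* the 6-stimulus
block: the simulated curve rises and then flattens with a small terminal
dip rather than increasing strictly. Monotonicity of MI in source entropy
is not a theorem here — each block size is a different channel — and the
tests assert strict rises only in the low-noise regime (σ = 0.15) where
crowding is negligible.

## What the simulations do and do not show

The generator reproduces the design, scale, anchors and sample sizes of
the study, and a noise level whose measured capacity matches the headline
value. It does **not** model real raters: human rating noise is unlikely
to be homoscedastic Gaussian, taste differences are richer than a mean
shift, and sequential, memory and fatigue effects are absent. Passing
recovery tests therefore demonstrates that the *pipeline* is correct and
well-calibrated on a known channel — not that any particular attribute
transmits 2.3 bits. Conclusions about real raters require real data run
through `ratecap analyze`.

## Numerical choices

- Probability normalization tolerance 1e-9; oracle comparisons 1e-12.
- Exact integer arithmetic for all mean-rounding (no floating-point ties).
- Confusion-matrix rows sum to 1 exactly by construction (CDF differences
  with ±∞ edges).
- Capacity fit: `scipy.optimize.curve_fit`, maxfev 20000, four starting
  points, best residual kept; non-convergence raises with diagnostics.
- Problem sizes in the test suite (participant counts of 3–200, 200 random
  oracle tables, 1,000 bias simulations) were chosen as the smallest sizes
  at which each property is clearly resolved.

## Limitations

- The capacity estimate depends on the chosen saturating form; reporting
  it without its fit diagnostics would overstate its precision.
- Plug-in MI bias is substantial at per-participant block sizes
  (15–50 pairs on a 10×10 table); the Miller–Madow diagnostic bounds the
  first-order effect but does not remove it, and no Bayesian or
  coverage-adjusted estimator is included.
- Blocks sharing a size are aggregated together; designs where same-sized
  blocks have deliberately different stimulus spacings would need a finer
  grouping key.
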