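# Methods

`soprosody` implements the computational chain of a prosody-perception
study on the English causal connective *so*: whether its prosody signals
subjective (CLAIM–ARGUMENT) versus objective (CAUSE–CONSEQUENCE)
causality to listeners.  The chain has four parts: functional PCA of f0
contours with condition-typical restyling, assembly of manipulated
stimulus specifications, a generative simulator of the forced-choice
listening experiment, and a Bayesian hierarchical logistic analysis with
bridge-sampled Bayes factors.  This note records the models, the
defaults, and the design decisions taken where the problem left the
design open.

## Contour model (FPCA)

A set of f0 contours (semitones over milliseconds) is linearly
interpolated onto a shared grid of `grid_size = 101` equally spaced
points on duration-normalized time [0, 1] and decomposed as

    F0(t) ≈ μ(t) + s1·FPC1(t) + s2·FPC2(t) + s3·FPC3(t),

with μ the pointwise mean and FPC1–3 the leading eigenvectors of the
centered sample covariance on the grid (equivalently, right singular
vectors of the centered data matrix).  No roughness penalty is applied;
smoothing, if wanted, is a pre-filter on the input contours.  Scores are
inner products of the centered contour with the components, which under
orthonormality is also the least-squares solution.  Numerical choices:

* **Sign convention.**  Eigenvectors are sign-ambiguous; each component
  is flipped so its grid integral is non-negative, with a near-zero
  integral (|∑| < 1e-12) resolved by making the first nonzero value
  positive.  This makes fits bit-reproducible across runs and platforms,
  but the orientation of a component with a near-zero integral is still
  a convention of the training set, not a physical fact — the direction
  in which a +s2 substitution bends a contour follows that orientation.
* **Degenerate input.**  A zero-variance contour set (all contours equal)
  returns zero scores against a canonical orthonormal basis; genuinely
  rank-deficient but non-degenerate data raise a rank error when more
  components are requested than the data support.
* **Interpolation.**  Linear everywhere (time normalization and
  reconstruction); a reconstruction solves the model curve at t = 0,
  step, 2·step, … including the endpoint only when the duration is
  divisible by the step (285 ms at 5 ms steps → 58 points).
* **Semitone reference.**  `hz_to_semitones` defaults to the per-speaker
  median f0, the common normalization; the reference is configurable
  because the convention is not universal.

## Stimulus restyling

Each stimulus is an untouched "event"-clause contour plus a connective
token (by default two segments, /s/ and /oʊ/).  Building a stimulus:
project the connective contour onto the fitted FPCA model, keep s1,
substitute the condition targets (subjective s2 = +0.335, s3 = −0.065;
objective s2 = −0.515, s3 = +0.025), re-solve the contour every 5 ms at
the condition duration (285 ms subjective, 235 ms objective — a 50-ms
contrast), rescale all segment durations by one common factor (ratios
preserved exactly), and remove the clause–connective silent gap by
shifting the connective onset.  Durations are exact per-token totals, and
real-valued milliseconds internally; rounding (half-up to 0.1 ms) happens
only in the TextGrid export.  The package deliberately stops at
*specifications* — PitchTier and TextGrid text files an external PSOLA
resynthesizer consumes — because waveform synthesis is external tooling,
not part of this computation.

## Synthetic data

The generator produces every input at desk scale; one root seed with
fixed sub-streams (contours = 1, responses = 2, fillers = 3) makes each
generator independently reproducible.

* **Contours** are mean + Σ s_k·component_k + white noise (0.1 st) on a
  5-ms lattice.  Default shapes: a gently falling mean (1 − 2t st), a
  level/tilt first component, a concave mid-span bulge second, an
  end-point tilt third, orthonormalized by Gram–Schmidt before use.
  Within-condition score SDs are (1.0, 0.3, 0.1); the (s2, s3) means are
  the condition targets above, so the pooled s2 condition difference is
  0.85; durations are normal around 285/235 ms (SD 10 ms).
* **Responses** follow the generative twin of the fullest analysis model:
  P(choice = subjective) = inv-logit(β0 + a_p + b_q + (β1 + u_p + w_q)·x)
  with prosody x ∈ {0, 1}, participant/pair random intercepts a, b and
  prosody slopes u, w, all independent normal.  Defaults are the study's
  reported posterior means: β0 = −1.06, β1 = 0.39, sd(u) = 0.51,
  sd(w) = 0.42.  The random-intercept SDs were not reported; they default
  to 0.5, the same order as the slope SDs, and are prominently
  configurable.  Every participant sees every pair in both prosody
  conditions exactly once (30 target trials).  Trials are conditionally
  independent given the random effects — no order or fatigue effects.
* **Filler accuracies** reproduce the printed 55-participant distribution
  band-for-band (38 at 20/20, 2 at 19/20 — the only lattice point
  strictly between 90% and 100% —, 3 in 70–89%, 8 in 50–69%, 4 below
  50%), with within-band counts uniform on the 20-filler lattice.

What the generator does *not* emulate: real speech variability beyond a
three-component low-rank structure, item-level semantic effects,
correlated intercept/slope pairs, or participant inattention beyond the
filler table.  Passing recovery tests therefore shows the estimation
chain is correct under the stated model, not that the model captures
every feature of real listening data.

## Filtering

A participant fails the attention check when their incorrect fraction
over the 20 fillers is **10% or more** (so 2/20 wrong is excluded).  The
complementary phrasing "accuracy below 90% excluded" disagrees at exactly
90%; the strict 10%-or-more rule is used because 18/20 = 90% accuracy is
10% incorrect.  The printed distribution has no participant at exactly
90%, so both phrasings retain 40 of 55 there.

## Bayesian analysis

The model ladder (Bernoulli outcome, logit link) is m0 `~ 1 +
(1|participant) + (1|pair)`, m1 adds the prosody fixed effect, m2 adds a
by-participant prosody slope, m3 adds a by-pair prosody slope.  One
`PriorSpec` scale sd applies to all parameters of interest: normal(0, sd)
on the intercept and prosody coefficient and half-normal(0, sd) on every
random-effect SD.  Tying the SD priors to the screened scale follows the
Bayes-factor table's design, where the varying-slope SD terms are
themselves evaluated under the three priors; intercept/slope pairs are
independent (no correlation parameter).  Candidate scales are
{10, 1.5, 1, 0.5, 0.25} for prior predictive screening and {1.5, 1, 0.5}
for Bayes factors; headline posteriors use the least informative
surviving prior, normal(0, 1.5).

**Sampler.**  Fitting uses the package's No-U-Turn sampler on the
unconstrained space (non-centered parameterization: standard-normal
offsets scaled by SDs; SDs sampled as log σ with the Jacobian).  Warmup
adapts the step size by dual averaging (target acceptance 0.8) and a
diagonal mass matrix over two variance windows.  The full configuration
is 4 chains × 10,000 iterations with 2,000 warmup; `REDUCED_SETTINGS`
(4 × 2,000, 500 warmup) is the desk-scale configuration used by the
recovery studies and the pipeline default, chosen so a full m3 fit takes
about half a minute on one CPU.

**Convergence contract.**  Every fit computes a report: divergent
transitions, split-Rhat (tolerance ±0.01 around 1), bulk ESS against a
target of 90% of the post-warmup draws (tail ESS is recorded alongside).
Violations are never silent: the report is attached to the fit and a
warning (or, on request, an exception) carries it.  At the reduced
settings the hierarchical SD parameters routinely mix below the 90%
bulk-ESS target — the funnel geometry of hierarchical logistic models —
so the contract there is a reported diagnostic, not a gate; the full
configuration is available where the contract must hold.

**Prior predictive.**  Parameters are drawn from the prior and full
datasets simulated on the design.  Two statistics are exposed: the
dataset-level proportion of subjective choices (the default contract) and
the pooled trial-level choice probabilities.  The never-or-always
behaviour of a normal(0, 10) prior is a statement about trial-level
probabilities: about 84% of them fall outside (0.05, 0.95), while the
dataset-level proportion of 40 independently saturated participants
averages back toward the middle (a shared N(0, 10) intercept alone can
push at most ~77% of dataset proportions outside that band).  The
screened scales {1.5, 1, 0.5} keep both statistics broad and centered on
0.5.

**Bayes factors.**  BF10 is the ratio of marginal likelihoods of the
model with and without a term, each estimated by Meng–Wong optimal bridge
sampling with a moment-matched Gaussian proposal on the unconstrained
space (half the posterior draws fix the proposal, half enter the bridge;
all prior normalization constants are included in the target density —
they do not cancel across models of different dimension).  The estimator
is repeated over independent proposal batches; a coefficient of variation
of 10% or more raises an instability error with the repeat values.  The
reduced sampler settings (≈6,000 kept draws for a ~116-dimensional m3
posterior) are the supported minimum for stable bridges; the pipeline's
`bf_cv_tol` loosens the gate only for deliberately tiny smoke runs.
Interpretation bands: BF10 > 10 strong, 3–10 weak, 1–3 very weak
support; < 0.1 favours the model without the term.

**Summaries.**  Per-parameter mean, 50% and 95% central credible
intervals; exponentiated effects report both the mean of the
exponentiated draws (the headline odds-ratio convention, which yields
1.47-style values) and the exponential of the mean (1.48-style), since
the two conventions differ by half the posterior variance.  Models with
by-participant slopes also yield a per-participant slope table
(β1 + u_p, averaged over pairs) flagging participants whose 95% CrI
excludes zero.

## Recovery studies and problem sizes

`soprosody.recovery` refits models to replicate synthetic datasets at the
defaults: m3 recovers the prosody coefficient, intercept, and
mean-of-exponentiated-draws odds ratio; m0 — which contains no prosody
term — is checked against its own generative twin (prosody effect and
slope SDs at zero) so its recovery target is the generating intercept.
The acceptance script uses 12 replicates (8 for the m0 study) of
40 participants × 30 trials at the reduced sampler settings, sizes at
which the whole study runs in about ten minutes on one CPU.  With only
15 pairs in the design, the realized pair-average slope contributes an
irreducible ≈0.11 log-odds of between-replicate spread to the prosody
estimate (confirmed by refitting the same replicates with lme4's
``glmer``, which tracks the package's posterior means replicate for
replicate), so the replicate count is chosen to bring the standard error
of the average comfortably inside the ±0.15 recovery tolerance.

## Known limitations

* The exact component shapes of the source study exist only as figures;
  the FPCA estimator is therefore validated by its mathematical
  properties (SVD equivalence, orthonormality, round-trips) on synthetic
  contours, not against the original curves.
* No pitch tracking and no waveform synthesis: contours in, restyling
  specifications out.
* Bayes factors on the original listener data are not reproducible (the
  responses are not deposited); the Bayes-factor machinery is validated
  by behaviour (unit BF on identical models, Occam behaviour under the
  null, ladder consistency, prior-tightening trends) on synthetic data.
* The bridge estimator assumes the posterior is adequately covered by a
  moment-matched Gaussian on the unconstrained space; with very few
  draws (hundreds) in high dimension it destabilizes and says so.
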