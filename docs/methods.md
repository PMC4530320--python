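# Methods

## Model

The package implements graded Bayesian inference over four causal-graph
hypotheses for a binary effect with two observed candidate causes (target C,
alternative A) and a constant, unobserved background B. All graphs include
B → E; they differ in whether C → E and/or A → E exist. Only generative causes
are modeled: every strength lies in [0, 1], and the default integration rule
is the noisy-OR, under which independent generative causes combine as one
minus the product of their failure probabilities,

    P(e+ | b, c, a) = 1 − (1 − w_B)(1 − w_C·c)(1 − w_A·a).

This is the standard three-parent noisy-OR; with the alternative absent
(a = 0) it reduces exactly to the familiar two-variable form
w_B + w_C·c − w_B·w_C·c. Strengths attached to links a graph does not contain
are fixed at zero during evaluation.

Given a contingency dataset D (per-configuration effect / no-effect counts),
each graph's marginal likelihood integrates the product-binomial likelihood
over the graph's free strengths (a 1-, 2- or 3-dimensional unit cube) against
the prior. Causal support for the target cause is the natural-log ratio

    sup = log [ (P(D|Graph1) + P(D|Graph3)) / (P(D|Graph0) + P(D|Graph2)) ],

a graded confidence in the existence of C → E: strongly positive when a link
is very likely, strongly negative when very unlikely, near zero when the data
cannot decide (as under perfect confounding). Strength estimates are the
posterior mean of w_C in whichever target-link graph (Graph1 or Graph3) has
the higher marginal likelihood; uncertainty about strength is the
differential entropy of that posterior density, which is 0 for the uniform
density (its maximum over densities on [0, 1]) and more negative the more
the posterior concentrates. Natural logarithms are used throughout (support
and entropy in nats); a sign-preserving power transform
sign(s)·|s|^γ is available for mapping support onto bounded judgment scales,
with γ = 1 (identity) by default and a least-squares fitting helper when a
target scale is supplied.

### Assumptions

* Trials are exchangeable Bernoulli draws within a configuration; only the
  aggregate counts matter.
* Causes are generative and, under noisy-OR, act independently; the model has
  no interaction (configural) terms, which is precisely what makes its
  behaviour under interacting data diagnostic.
* Graphs have equal prior probability; strengths are a priori uniform on
  [0, 1] unless the sparse-strong prior is selected.

## Configuration

`ModelConfig` fields (defaults in parentheses):

* `parameterization` (`noisy_or`): `linear` replaces the noisy-OR with
  min(1, Σ w_i x_i); the clip is needed because strengths can sum past one.
* `prior` (`uniform`): `sparse_strong` implements a "necessary and
  sufficient"-style prior as a normalized mixture over which single free
  strength is strong, P(w) ∝ Σ_i exp(−α(1 − w_i) − α Σ_{j≠i} w_j). The exact
  published form of this prior family is not fixed by the sources the package
  follows, so the hyperparameter α (`sparse_strong_alpha`, default 5) is
  exposed; the mixture is normalized numerically on the quadrature nodes so
  that an empty dataset yields marginal likelihood 1 exactly.
* `grid_points_per_dim` (101, minimum 21): quadrature resolution per strength
  dimension, and the resolution of reported posterior grids.
* `strength_mode` (`most_likely_graph`): `graph_average` replaces the
  selected-graph posterior with the posterior-probability-weighted mixture
  across all four graphs, the no-link graphs contributing a point mass at
  strength 0 (carried as `PosteriorGrid.zero_mass`).
* `scale_gamma` (1.0): exponent of the support-scaling transform.

## Numerical choices

* **Marginal likelihoods: Gauss–Legendre quadrature.** Under either
  parameterization the integrand is a piecewise polynomial in each strength,
  of degree bounded by the number of trials in the cells that involve it
  (≤ ~120 per dimension for the packaged design). Gauss–Legendre with the
  default 101 nodes per dimension is exact for polynomials up to degree 201,
  so the packaged-design marginals are exact to floating-point rounding;
  uniform-grid trapezoid or Simpson rules at the same resolution leave
  relative errors up to 10⁻² on cells with zero effect counts. Accumulation
  is in the log domain with log-sum-exp, and meshes larger than ~4×10⁶
  elements are processed in chunks along the background dimension, so finer
  grids cost time, not memory.
* **Posterior densities: uniform grid, trapezoid normalization.** The
  posterior over w_C is reported on a uniform 101-point grid on [0, 1]
  (endpoints included, where densities may legitimately vanish), normalized
  so its trapezoid integral is 1 within 10⁻⁶. The non-target strengths are
  integrated out with the same Gauss–Legendre rule.
* **Entropy: spline-refined quadrature.** −∫ p ln p is evaluated after cubic
  spline refinement of the density to 2001 points, clipping at zero and
  renormalizing against the refined trapezoid weights. Renormalizing against
  the same weights used in the entropy sum guarantees H ≤ 0 with equality
  exactly at the uniform density; direct 101-point quadrature of −p ln p
  would lose ~5×10⁻⁴ absolute accuracy because the integrand has unbounded
  slope where the density vanishes.
* **Ties and degenerate inputs.** If Graph1 and Graph3 have exactly equal
  marginal likelihood (possible for datasets with no alternative-present
  cells, where the two graphs coincide), the simpler Graph1 is used and a
  warning is emitted. An empty dataset returns marginal likelihood 1 for
  every graph, support 0 and the prior as posterior. Observed outcomes that
  are impossible under a parameter vector contribute −∞ log likelihood
  (0·log 0 ≡ 0 for unobserved outcomes); a dataset impossible under *all*
  graphs raises an undefined-support error. Direction comparisons in the
  pipeline use a 10⁻⁹ dead band so sign noise cannot masquerade as a trend.

## The packaged design and human summaries

The design fixture encodes two groups × two phases of 20-trial types: a
confounded pair (compound-only in phase 1, target-alone trials added in
phase 2) and an interacting pair (compound probability in phase 2
inconsistent with the elemental probabilities), 200 trials per group, with
background-only trials never showing the effect. Phase-2 model inputs pool
both phases by default (`cumulative=True`), because the judgments the model
is compared against were elicited about all information seen so far;
per-phase analysis remains available (`cumulative=False`), and the contrast
matters — the interacting-pair support drop across phases is far larger on
per-phase data. The alternative cause of the confounded pair never occurs
alone, so that configuration is simply absent and its strength is integrated
over without direct evidence.

The human-judgment summaries packaged alongside are group-level means and
choice counts only (per-participant data were never released). Uncertainty
means are stored on the 100-minus-confidence scale. Where per-group phase-1
choice splits were not published, only the phase direction of the coded
structure judgment — which the published counts bound unambiguously — is
stored, and the mean fields are null rather than imputed. Inferential
statistics on the human data are out of scope for the same reason. The
comparison report therefore makes ordinal claims (directions of change and
their agreement), not quantitative fits.

## Synthetic data

`simulate_dataset` draws effect counts per configuration from the noisy-OR
with known graph and strengths — Binomial sampling, or an `exact_frequency`
mode (round-half-up of n·p) that reproduces deterministic design-style cells
such as 16-of-20 at p = 0.8. `simulate_cohort` layers a response model on the
fitted quantities: strength ratings are 100·posterior-mean plus Gaussian
noise, confidence is 100·(1 − exp(H)) plus noise (exp(H) being the
uniform-relative concentration of the posterior), and structure choices are
softmax draws over the coded options driven by scaled support. This response
model is repository scaffolding for recovery and pipeline tests: its defaults
are chosen so that the noiseless limit reproduces the model's own predictions
exactly, and it makes no claim about how people actually generate ratings.
Consequently, passing cohort-level tests shows internal consistency of the
pipeline, not validity against real participants: real ratings exhibit
individual differences, scale-use biases and sequential effects the generator
deliberately omits. All randomness flows through explicit
`numpy.random.Generator` seeds; identical seeds give identical data.

Recovery experiments at the default problem size (200 trials per
configuration, 20 replicates per condition) fit in seconds; the test suite
and acceptance script use those sizes throughout.

## Limitations

* No configural/conjunctive graph variants and no preventive
  (noisy-AND-NOT) causes; the model is deliberately elemental-generative.
* The support-scaling exponent used in published figure panels is not
  recoverable from the available sources; γ defaults to the identity and the
  fitting helper is provided instead.
* The sparse-strong prior is one reasonable member of its family, not a
  pinned-down published form.
* Entropy of graph-averaged posteriors is reported for the renormalized
  continuous component; the point mass at zero is excluded because
  differential entropy of a mixed discrete–continuous distribution is not
  defined.
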