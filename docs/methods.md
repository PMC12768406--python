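# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the known limitations of the pipeline.

## Count model for two-choice arenas

Each arena-night contributes two equal-exposure observations, one per side.
The response is the number of egg clusters (each cluster is one oviposition
decision; egg numbers per cluster are wildly overdispersed and reflect
female condition more than choice). The model is a Poisson log-link GLMM:
treatment indicator and number of females as fixed effects (the female
count is centered; it enters as a covariate, not an offset, since both
sides of one night share the same females), and independent normal random
intercepts for arena, repetition, and night-within-repetition. Nights with
zero clusters on both sides carry no choice information and are excluded
before fitting; the count of excluded nights is recorded in the fit notes
and the pipeline report.

Estimation is maximum likelihood under the Laplace approximation: for each
candidate (β, log σ) the random-effect mode is found by damped Newton
iteration to a gradient norm of 1e-8, and the approximate marginal
likelihood (penalized log-likelihood minus half the log-determinant of the
conditional precision) is maximized by L-BFGS-B over the fixed effects and
log-SDs (log σ bounded in [−7, 3]; a boundary solution means σ ≈ 0).
Standard errors come from the numerically differentiated Hessian of the
Laplace log-likelihood; p-values are two-sided Wald. The `converged` flag
reports the optimizer status honestly; there is no silent fallback. With no
grouping factors the identical code path is an ordinary Poisson GLM polished
by full Newton, which the tests verify against statsmodels to 1e-6. At this
problem size (≤ a few hundred random-effect levels) adaptive quadrature
would add nothing; the Laplace fit recovers a true log rate ratio of 1.0
with mean 1.02 and 95% Wald coverage 0.955 over 200 simulated experiments
at the default scale, and its Wald test rejects a true null in 6.4% of 500
replicates at the 5% level.

For Bernoulli responses (the trajectory trend model, below) the same
machinery is used with a logit link. Complete or quasi-separation is
detected (non-convergence or |β| > 12) and triggers a documented fallback:
a weak L2 penalty (1e-3) on the fixed effects, flagged in the result.

## Bayesian per-cluster choice posterior

Each cluster's side is coded 1 (tested side) or 0. The model is deliberately
Gaussian on the 0/1 codes — the stated prior N(0.5, 0.1²) lives on the
outcome scale, so a Gaussian likelihood keeps it interpretable as a prior on
the mean choice probability. An optional normal random intercept is grouped
by the arena's female count; the residual SD and the group SD get
half-normal(0, 1) priors. Sampling is Gibbs: the mean and the group
intercepts have exact normal conditionals; the two SDs are updated by slice
sampling on the log scale (tuning-free, exact stationary distribution).
Default 16,000 retained draws after 1,000 burn-in. With no data the
posterior is the prior (returned as draws, documented rather than an
error). With the random effect disabled and the residual SD fixed, the
sampler matches the conjugate normal–normal closed form within Monte-Carlo
error — this is an acceptance check.

The choice of "female count as a random effect" is one reading of an
ambiguous design (a grouping factor whose levels are the observed female
counts); a random slope in the female count is a plausible alternative and
is deliberately not implemented — the grouping-factor reading keeps the
posterior of μ well-identified at the few distinct counts observed.

## Mirror-shuffle null and the K-S test (gradient arena)

In the 150 cm arena the speaker sits at −75 cm, the feeder at 0, a silent
resistor at +75. Under no acoustic preference the end holding the speaker
is arbitrary, so the null is built by sign-flipping positions about the
center: for each shuffle replicate every analysis unit (egg or cluster)
keeps |x| and draws a fair sign; all replicates are pooled into the H0
reference sample. The test statistic is the two-sample Kolmogorov–Smirnov
D between the observed positions and that pooled reference, computed with
the right-continuous ECDF convention and evaluated only at the observed
sample's jump points from both sides (the supremum over an interval where
one ECDF is constant is attained at its endpoints) — O(n log m) per
replicate, verified against brute-force ECDF enumeration.

**Why the default p-value is a permutation p.** The pooled reference shares
its magnitudes |x| with the observed sample, so the classical asymptotic
two-sample formula does not apply: under the symmetric null the ECDF gap
reduces to a maximum of partial sums of fair signs (a scaled Brownian-motion
supremum, sup|W|/2 at √n scale), stochastically smaller than the
Brownian-bridge supremum the formula assumes. Measured rejection with the
asymptotic formula is ≈0.7% at nominal 5%. The default instead ranks the
observed D among fresh shuffle replicates compared against the same pooled
reference; these are exchangeable with the observed sample under the null,
giving an exact test (measured 5.4% egg-weighted, 4.0% cluster-level, at
nominal 5%). The replicates flip signs per *cluster* and then expand by egg
count: all eggs of one cluster share a position, so a physical
re-randomization of the speaker end moves them together; per-egg-independent
flips would understate the null variance catastrophically (measured ~100%
rejection under the null). The asymptotic construction remains available as
`p_method="asymptotic"` for comparison with analyses that used it.

**Effective sample size under egg weighting.** Egg counts per cluster have
SD ≫ mean, so the egg-weighted ECDF is dominated by a few very large
clusters and the egg-level test has low power (≈19% at ~40 clusters in
simulation) even when the cluster-level test at the same data rejects
reliably (98–99% at ~100 clusters). Power statements in the tests therefore
use the cluster unit — the decision unit throughout the pipeline.

Densities are Gaussian KDEs (egg-weighted or per cluster) on a fixed grid
over [−75, 75], renormalized to integrate to 1 over the arena (truncation
correction); bandwidth is Scott's rule or a kernel SD in cm.

## Trajectory analysis

Samples every 12 s are labeled by side relative to the arena midline; a
sample exactly on the midline inherits the previous label (a leading
midline run is neutral and excluded). Crossings are adjacent label changes.
Occupancy is summarized in 30-minute bins tiling the window from t = 0; a
partial final bin keeps its true sample count.

The time trend is fitted as a logistic mixed model of the **per-sample**
binary occupancy on time (hours, centered), with random intercepts for
trial and moth. An accumulated amount of time is not a binomial outcome, so
the per-sample formulation is the coherent logistic reading of the trend
question; a linear mixed model on per-bin proportions (statsmodels MixedLM)
is provided as the accumulated-time variant and agrees in sign.

Caveat: consecutive 12-s samples are strongly serially dependent, and the
model treats them as conditionally independent. Consequences, measured in
simulation: Wald p-values for the slope are anticonservative (they
describe evidence within this model, not a calibrated error rate), and on
Markov-generated tracks the estimated moth-intercept SD absorbs serial
runs, inflating the subject-specific slope ≈8% above the marginal slope of
the generating chain. Parameter-recovery checks therefore generate from
the fitted model's own assumptions (iid Bernoulli given moth and time),
where the slope is recovered without bias; Markov tracks are checked for
direction and detectability of the trend.

## Synthetic-data generators

The generators mirror the models above, with defaults set to the study's
conditions:

* **Two-choice** (`TwoChoiceSimConfig`): 38 repetitions × 3 nights over 4
  arenas; 10.9 ± 1 females per arena; control rate 0.40 clusters/side-night
  (β₀ = log 0.40) and treatment log rate ratio β₁ = 1.0 — the combined
  playback-vs-silence condition. Random-intercept SDs are not reported for
  the original data; 0.25 per level is a modest realistic default
  (≈10% inflation of marginal means). Counts are Poisson given the nested
  intercepts; zero-laying nights are generated and flagged, never dropped —
  exclusion belongs to the analysis stage.
* **Gradient** (`GradientSimConfig`): cluster positions from a two-component
  normal mixture at the speaker (−75) and feeder (0), truncated to the
  arena by rejection (clipping would create boundary atoms the K-S stage
  would misread). Eggs per cluster are 1 + NegBin with overall mean 68 and
  dispersion 0.26 (SD ≈ 130 ≫ mean; the shift keeps every cluster at ≥ 1
  egg with the exact target mean). The default of 28 females × 3 nights ×
  1.2 clusters/night (~100 clusters) matches the evidence scale implied by
  the reported first-night K-S result (≥60 first-night units).
* **Tracks** (`TrajectorySimConfig`): a two-state Markov chain whose
  stationary log-odds of the playback side rise linearly at `bias_slope`;
  transition probabilities 2·s·π(t) (toward playback) and 2·s·(1−π(t))
  (away) keep the chain stationary at π(t) for frozen t while `s =
  switch_prob0` sets the overall switching rate. Defaults (s = 0.0028,
  slope 1e-4/s) reproduce ≈4.2 crossings per 6 h night and a reliably
  detectable increasing trend at 13 moths. x is uniform within the occupied
  half; no flight dynamics are modelled.
* **Deafening**: Bernoulli responders per moth in each group.

One master seed; each generator draws from a dedicated stream via
`SeedSequence(seed, spawn_key=(stream_id,))` with fixed per-stream ids, so
adding a generator never perturbs the others. Identical seed and config
give bit-identical tables.

What the generators do **not** emulate: within-night spatial correlation of
clusters from one female, the nightly alternation of the physical speaker
side (positions are generated directly in speaker-at-−75 coordinates; the
deposited-format adapter performs that normalization for real tables),
female-to-female preference heterogeneity, and temporal dependence of
laying across nights. Passing tests therefore validate the estimators under
the stated models, not the behavioral conclusions of any particular field
dataset.

## Numerical and interface choices

* Pearson chi-square without Yates continuity correction (the corrected
  statistic would not reproduce the printed validation value); zero margins
  are an error, not a 0.
* The two-experiment laying-probability comparison uses Fisher's exact
  two-sided test; the output labels the method, since "binomial test"
  admits several constructions.
* p-values are reported at full double precision (extreme Wald statistics
  may underflow to 0 below ~1e-308).
* ECDF ties: right-continuous convention everywhere.
* One CSV dialect (comma, dot decimal, UTF-8, header); readers validate
  schema and ranges and cite file, row, and field in errors. Reports embed
  config, seed, and a schema version.

## Limitations

* The Laplace approximation can bias variance components at very small
  cluster counts per level; fixed-effect estimates at the scales used here
  are unbiased within Monte-Carlo error (see the recovery checks).
* The permutation K-S test conditions on the observed |x| magnitudes;
  per-night dependence of real data (all clusters of one night share a
  physical speaker side) is not represented in either the generator or the
  null and would call for night-level sign flips.
* The Gaussian choice model is a literal implementation of an
  outcome-scale prior; it is not a binomial likelihood and its posterior
  can assign mass outside [0, 1] when data are extreme.
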