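# Methods

## The estimation problem

Formal Bayesian comparison of two models M_i, M_j rests on the Bayes factor
BF_ij = p(y|M_i) / p(y|M_j), the ratio of marginal data densities

    p(y|M) = ∫ p(y|θ, h, M) p(h|θ, M) p(θ|M) dθ dh.

With latent variables h (one per observation in the models treated here) the
integral is high-dimensional and direct marginal-likelihood estimation is
unstable or infeasible. When the two models share a latent space, however,
the Bayes factor equals a posterior expectation of a density ratio,

    BF_ij = E[ r_ij(θ, h) | y, M_j ],
    r_ij = p(y|θ,h,M_i) p(h|θ,M_i) p(θ|M_i) / (same terms under M_j),

so an arithmetic mean of r_ij over MCMC draws from the M_j posterior is a
consistent estimator. For nested pairs — an unrestricted model M_U whose
parameter vector θ_U = (θ_A, θ_R) extends the restricted model M_R's shared
block θ_R — the full ratio collapses, depending on which component of the two
models actually differs, to a latent-prior ratio, a parameter-prior ratio, or
a sampling-density ratio (`ratio_kind` in `bftrim.core`). The collapsed forms
assume: prior independence of θ_A and θ_R, a proper θ_A prior, a shared
latent space, and equality of the non-differing components across the two
models. These assumptions are the caller's responsibility: the density
evaluators are opaque to the library and nothing verifies them.

### Pseudo-bias and trimming

The raw ratio mean fails in high dimensions in the same way as the harmonic
mean estimator: the ratio's distribution under the sampling posterior is so
heavy-tailed that the mean is dominated by draws the sampler essentially
never produces. The failure is visible already in a one-parameter conjugate
Gaussian pair: under the M_U posterior, r_RU = exp((T/2)µ² − µΣy) has finite
moments only up to order 1 + 1/T, so the estimator has *infinite variance*
for every T ≥ 1 and its batch-means standard error stops covering the true
error once T exceeds a handful of observations (the package's tests assert
both the small-T validity and the large-T breakdown). The estimates are then
systematically below the target — the downward "pseudo-bias".

The remedy is to trim the space to a subset D with non-trivial probability
under *both* samplers, average I_D·r over the draws, and divide by
Monte-Carlo estimates of D's probability:

    BF_ij,D = (1 / Pr(D|y,M_i)) · (1/k) Σ_q I_D(θ_q, h_q) r_ij(q),

with the U-vs-R direction dividing by Pr(D|y,M_U) and the R-vs-U direction
by Pr(D_R|y,M_R)·Pr(D_A|M_U). Inside D the ratio varies moderately, the
trimmed mean is well-behaved, and the corrections undo the truncation
exactly in expectation.

### The subset D

D = (A × B) ∩ C, built from the two samplers' outputs:

* A — per-parameter range intersection: for each coordinate, [max of the two
  sample minima, min of the two sample maxima]. A coordinate present in only
  one sampler (θ_A, whose draws come from the M_U posterior or the θ_A
  prior stream) takes its single sample's range.
* B — the same construction over all T latent coordinates.
* C — a band on the density ratio: L = max of the two per-sampler ratio
  minima, Q = min of the two maxima.

Membership is closed (boundary points belong to D). By default C uses the
same ratio kind as the estimator; this is configurable. Because the band
couples θ_A with (θ_R, h), D does not factor exactly as D_A × D_R; the
identity behind the R-vs-U correction only needs the probability of D under
the *product measure* (θ_A prior) ⊗ (M_R posterior), which is estimated as
the fraction of paired draws inside D. The reported split keeps the θ_A box
factor exact: Pr(D_A|M_U) is the prior fraction inside the θ_A box and
Pr(D_R|y,M_R) is the joint fraction divided by it, so their product is the
correct joint correction.

With T latent coordinates the box alone excludes a draw whenever any one of
its T coordinates leaves the other sampler's range; for samples of size k
this removes roughly a fraction 1 − exp(−4T/k) of draws even when the two
latent posteriors coincide, so retention diagnostics for both samplers are
recorded on every region and zero retention raises an error rather than
propagating a silent −∞.

### Equivalent pre-truncated form

The indicator-masked estimator (mean over all k draws of I_D·r, divided by
k) and the pre-truncated estimator (mean over draws rejected to D, with the
retention fraction supplied as an explicit Pr(D|y,M_j) correction) are one
algebraic identity; `bf_corrected` is the single kernel for both, and the
caller states which sampling scheme produced the draws. Pre-truncated
sampling is implemented by rejection from the full run — a truncated sampler
is never constructed.

## Numerical conventions

* All accumulation is in natural-log space with log-sum-exp; only reported
  quantities are decimal logarithms (field names say `log10_` explicitly).
  Raw means of exp-ratios overflow already for T in the hundreds.
* NSE: batch means with 20 contiguous batches by default (contiguity
  respects chain autocorrelation); per-batch decimal-log estimates, then
  sd/√(#batches). Correction probabilities contribute via the delta method
  (se(log10 p) = se(p)/(p ln 10)). Subset probabilities get a binomial
  standard error that ignores autocorrelation — a flagged diagnostic, not an
  inferential quantity.
* Degenerate cases raise typed errors instead of returning ±∞: an all-zero
  ratio series, an empty trimming subset, a zero subset probability, a zero
  denominator density (the ratio is undefined there — this is an error, not
  −∞), an empty box intersection or ratio band.
* Draw streams: θ_A prior draws are paired with posterior rows by index;
  mismatched lengths truncate to the shorter with a warning. The two streams
  are assumed mutually independent.

## The Student-t study

The worked model is y_t | µ, v ~ iid t(µ, 1, v) with µ ~ N(0, 1) and
v ~ Exp(0.1) (mean 10, unrestricted support (0, ∞)), in its scale-mixture
form y_t|h_t ~ N(µ, 1/h_t), h_t|v ~ Gamma(v/2, v/2), so the latent dimension
equals the sample size. M_R fixes µ = 0. Study conditions follow the
published design: T ∈ {500, 1000, 2000}, µ_true ∈ {0, 0.25, 0.5}, v_true = 8.

The Gibbs sampler cycles the three full conditionals (normal for µ, gamma
for each h_t, and a nonstandard kernel for v). The v-conditional is sampled
by inverse CDF on an adaptive grid: a coarse log-spaced bracket locates the
mode, the window keeps everything within e^−35 of it (truncated tail mass
< ~1e−14; the kernel decays at rate (κ−T)/2 ≥ λ0 since x − ln x ≥ 1), and
the fine-grid resolution scales so the density's core (within e^−2 of the
mode) always receives ≥ ~150 points — necessary when T is small and the
conditional is very diffuse. Any sampler matching the kernel is conformant;
conformance is established by a Kolmogorov–Smirnov test against the
quadrature-normalised density. Chains run 20,000 retained iterations after
2,000 burn-in by default (the study scale), configurable throughout.

The benchmark integrates the latents analytically (the plain Student-t
likelihood) and estimates each model's marginal likelihood with the
corrected arithmetic-mean estimator (CAME): prior-sample mean of the
likelihood restricted to a region A, divided by A's posterior probability.
A defaults to the full posterior-sample-range box (whose estimated
Pr(A|y) is then 1 by construction; quantile boxes are available and agree
within NSE). Posterior draws of the latent-integrated models come from an
adaptive random-walk Metropolis over (µ, ln v) — the log transform
equalises scales on the positive half-line; the proposal scale targets ~0.3
acceptance during burn-in and is frozen afterwards. 20,000 prior and 20,000
posterior draws per model by default.

Per scenario one dataset is simulated and the benchmark computed once; each
replication then runs fresh Gibbs chains for both models plus a fresh θ_A
prior stream, builds D from the two sampler outputs, and evaluates the
requested estimators with the sampling-density ratio (which for this pair
reduces to exp(−½µ²Σh_t + µΣy_t h_t)). A fresh-dataset-per-replication mode
exists but is not the default: the published per-scenario statistics read as
conditional on one realisation. Summary cells report M, SD and the errors
AE (mean of estimate − benchmark) and RMSE against the benchmark, which
makes RMSE² = AE² + SD²(n−1)/n an exact identity. Replication failures are
recorded with an effective count rather than aborting the study.

### What the generator emulates — and what it does not

The synthetic data are exactly iid Student-t draws: no serial dependence, no
outliers beyond the t tails, no misspecification between the generator and
the fitted model. Passing the study therefore demonstrates the estimators'
Monte-Carlo behaviour under a correctly specified latent-variable model of
realistic dimension (up to 2000 latents), not robustness to model error.
Published table values additionally depend on the authors' unseeded dataset
realisation: at µ_true = 0 the benchmark log10 BF_U,R is, across dataset
draws, approximately −log10[ϕ(0; µ̂, σ̂)/ϕ(0;0,1)] with µ̂/σ̂ ~ N(0,1), giving
an across-dataset spread of roughly 0.3. Desk-scale agreement is therefore
assessed within that Monte-Carlo band plus exact reproduction of the
qualitative structure (sign of the benchmark, corrected estimators on the
benchmark, strong downward pseudo-bias of the uncorrected R-vs-U mean).

## The inverted-gamma MSF ratio

For the hybrid volatility models in which the scalar latent factor follows
ln h_t = φ ln h_{t−1} + ln γ_t with γ_t ~ iid IG(v/2, v/2), the latent-prior
ratio between the φ ≠ 0 model and its φ = 0 reduction (the Student-t case)
has the closed form Σ_t [(vφ/2) ln h_{t−1} + (v/(2h_t))(1 − h_{t−1}^φ)],
which the package exposes as a plug-in density ratio and verifies against
the change-of-variables transition density to 1e−10. The initial factor h_0
is not pinned down by the ratio's t = 1 term; it is drawn from the φ = 0
stationary law IG(v/2, v/2) by default and exposed as a field so users can
condition on a fixed value. The path simulator requires v > 2 so that the
stationary mean v/(v−2) exists, matching the prior truncation used with this
model class. Estimating the full volatility models themselves (SBEKK
recursions, their priors, real financial data) is out of scope.

## Savage–Dickey utility

For nested pairs with a scalar restriction, log10 BF_R,U is also the decimal
log of posterior/prior density at the restriction point. The posterior
density is estimated from a histogram of sampled values with
Freedman–Diaconis bin width (a variance/resolution compromise; the method
source only prescribes "a histogram"). A restriction point outside the
sampled range, or in an empty bin, raises an error: the method is not
reliable in the tail, which is the regime the ratio estimators handle.

## Design choices that were genuinely open

* Burn-in: the study scale is quoted as 20,000 iterations without a burn-in
  statement; the default here retains 20,000 after 2,000 burn-in.
* One dataset per scenario (default) versus fresh data per replication
  (option), as above.
* The band C uses the same ratio kind as the estimator by default; the two
  published constructions (sampling-density and latent-prior bands) are both
  expressible.
* θ_A box bounds come from the single sampler that carries θ_A draws; range
  intersection applies only to coordinates both samplers visit.
* Exponential prior for v on (0, ∞) exactly; no truncation to v > 2 in the
  Student-t study (that truncation belongs to the volatility-model prior).
* `estimate_bf_nested` takes explicit named draw streams (U posterior, R
  posterior, θ_A prior) because the corrected variants need the *other*
  model's sample for their probability corrections.

## Problem sizes used by the bundled runs

The acceptance script runs the full study scale (20,000 retained Gibbs
iterations, 20,000-draw CAME, 20 replications — the published tables used
100); the test suite exercises the same code paths at reduced chain lengths
and replication counts, with the estimator-correctness properties (closed
forms, exact reductions, KS checks) at full strength.

## Known limitations

* The choice of D is the published range-intersection/ratio-band recipe; no
  variance-optimal subset selection is attempted (an open question in the
  source literature).
* Binomial standard errors for subset probabilities ignore chain
  autocorrelation; NSEs for heavy-tailed *uncorrected* estimators are
  unreliable by nature (see pseudo-bias above) — they are reported anyway
  because comparing them against the corrected estimators' calibrated NSEs
  is itself diagnostic.
* The structural assumptions behind the collapsed ratio variants are not
  machine-checkable; misuse produces estimates of the wrong functional
  without warning.
* `posterior_model_probs` assumes the model set is exhaustive.
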