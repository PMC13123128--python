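# Methods

## Model

`centerprofile` fits a Bayesian hierarchical logistic regression for a
binary patient outcome (here: kidney transplant within two years of
starting kidney replacement therapy) observed across J treatment centers:

    logit P(y_i = 1) = eta_i = alpha + x_i' beta + u_{j[i]},
    u_j ~ N(0, sigma_u^2)

with priors alpha ~ N(0, sigma_alpha^2), beta_k ~ N(0, Sigma_beta_kk)
(diagonal Sigma_beta, i.e. independent Gaussian priors per coefficient)
and sigma_u^2 ~ IG(a0, b0) in the *rate* parameterisation
(density ∝ x^-(a+1) e^(-b/x)).  Defaults: sigma_alpha^2 = Sigma_beta_kk =
100 (weakly informative on the log-odds scale), a0 = b0 = 1.  The
logistic likelihood is non-conjugate with the Gaussian priors, so the
full conditionals of alpha, beta and u have no closed form; the
conditional of sigma_u^2 is exactly IG(a0 + J/2, b0 + sum u_j^2 / 2).

Covariates are categorical only and enter by reference-level dummy
coding; design columns are named `covariate.level` and the encoding map
is emitted with every fit so column order is reproducible.

## Sampler

Posterior inference uses Metropolis-Hastings within Gibbs.  Each
iteration updates, in a fixed order: alpha (random-walk MH), each beta_k
in ascending index order (componentwise random-walk MH with the full
conditional evaluated at the current values of the other coordinates),
each u_j (random-walk MH whose acceptance ratio touches only center j's
patients plus the N(0, sigma_u^2) prior), and sigma_u^2 (exact conjugate
Inverse-Gamma draw).  The linear predictor and the per-patient
log(1 + e^eta) terms are updated incrementally; the optimized loop is
cross-checked draw-for-draw against plain reference implementations of
each block update in the test suite.

Proposal scales are tuned toward 20-40% acceptance.  Initial scales are
set per block as 2.4 / sqrt(I), where I is the block's approximate
Fisher information at the pooled event rate (sum of x^2 p(1-p) over the
block's patients plus the prior precision).  A flat common starting
scale would need dozens of doubling windows to reach the right magnitude
for prior-dominated blocks, whereas the curvature-based start lands each
block near its stationary scale immediately.  During burn-in only, each
block's scale is multiplied by 1.1 (or 1/1.1) whenever its acceptance
over the last 100 iterations exceeds 0.40 (or falls below 0.20);
adaptation is frozen at the end of burn-in so the retained draws come
from a fixed-kernel chain with the correct invariant distribution.
Blocks whose conditional is prior-dominated (fewer than ~10 events at a
covariate level) equilibrate near the prior scale where the windowed
acceptance estimate is noisy; their realized acceptance can sit above
the target band without affecting the rest of the chain.

Defaults follow the reference run configuration: 20,000 iterations per
chain, 2,000 burn-in, thinning 1, three chains — 54,000 retained draws.
Chain c draws from an independent RNG substream derived from
(seed, chain_id).  Chain 0 starts at alpha = logit(pooled event rate),
beta = 0, u = 0, sigma_u^2 = 1; later chains jitter alpha and beta by
N(0, 0.5^2) so the Gelman-Rubin diagnostic sees overdispersed starts.
Thinned retention keeps iterations with (it - burn_in + 1) % thin == 0,
so the retained count is exactly floor((n_iter - burn_in)/thin).

The accept-reject step always consumes one uniform variate, even when
the decision is forced, so the RNG stream advances identically on all
paths and runs are bit-reproducible.

Gradients of all four log conditionals are provided in `model.py` and
verified against finite differences; the sampling kernel itself is
plain random-walk MH (a gradient-informed kernel would need an
asymmetric-proposal correction and is not required by any check).

## Center profiling

For each retained draw s, per-patient probabilities p_i^(s) =
sigma(alpha^(s) + x_i' beta^(s) + u_{j[i]}^(s)) give per-draw expected
counts E_j^(s) = sum over center j of p_i^(s), and E_j is their mean
over draws.  The performance measure is the standardized incidence
ratio SIR_j = O_j / E_j and its log, computed with the additive guard
(O_j + eps)/(E_j + eps), eps = 1e-6 applied to numerator and denominator
always, so zero-event centers stay finite (log-SIR around -13 to -15)
while positive-count centers shift only at O(eps).  Credible intervals
are empirical quantiles of the per-draw ratios (O_j + eps)/(E_j^(s) +
eps); log-scale bounds are their logs (quantiles commute with monotone
maps).  sigma_j^2 = Var[log SIR_j] is the sample variance of the
per-draw log ratios: O_j is a fixed observed count, so its variance and
covariance contributions vanish under this estimator.  A delta-method
alternative (Poisson 1/O_j plus Var[log E_j^(s)]) is available via
`var_log_sir(..., method="delta")` for comparison only.

Funnel-plot control limits on the log-SIR scale are mu ± z_{1-alpha/2}
sigma_j with mu = 0 by default.  FDR-adjusted limits follow the
Benjamini-Hochberg step-up: two-sided p_j = 2 Phi(-|log SIR_j|/sigma_j),
sort ascending, k* = max{k : p_(k) <= (k/m) q}, z_FDR =
Phi^{-1}(1 - p_(k*)/2), limits ± z_FDR sigma_j.  When nothing is
rejected, the conventional z_{1-alpha/2} is reported and a `no_signals`
flag is set (the step-up does not define a critical value there).
Zero-event centers participate in the p-value calculation; their
|log SIR|/sigma is enormous, which is flagged in the profile table
rather than silently excluded.  A point exactly on a limit counts as
"within" (conservative flagging).  Classification by credible interval:
"above" if the 2.5% log-SIR bound exceeds 0, "below" if the 97.5% bound
is under 0, else "consistent".

## Shrinkage descriptives

The named metrics are this package's operationalizations (their
formulas are stated nowhere authoritative):

* empirical logit: log((O_j + 0.5)/(N_j - O_j + 0.5)), the
  Haldane-Anscombe correction keeping zero- and full-event centers
  finite;
* shrunken logit: logit(E_j / N_j), the model-implied center rate;
* group mean: unweighted mean of the empirical logits (an N_j-weighted
  variant sits behind `weighted_group_mean=True`);
* distance moved = |empirical - shrunken|; percent moved =
  100 (|empirical - gm| - |shrunken - gm|)/|empirical - gm|, undefined
  (NaN) when a center sits exactly at the group mean, negative when the
  model estimate lands farther from the mean than the raw one;
* volume categories: tertiles of N_j, ties broken by center label order.

## Convergence diagnostics and predictive check

PSRF is the classic unsplit Gelman-Rubin factor
sqrt((((n-1)/n) W + B/n)/W); note the unsplit estimator can dip slightly
below 1 by sampling noise, and is blind to a shared within-chain trend —
a split-chain variant is available via `psrf(..., split=True)`.  ESS is
S/(1 + 2 sum rho_t) with the autocorrelation sum truncated by the
initial-positive-sequence rule on pair sums and the result clipped to
(0, S]; the per-parameter table sums ESS across chains.  All-constant
chains make both undefined and raise.

The posterior predictive check computes, for a subsample of draws, each
draw's fitted probabilities and their ROC AUC against the observed
outcomes (Mann-Whitney with midranks for ties, via scikit-learn), and
reports the 2.5/50/97.5% quantiles over draws plus the AUC of the
draw-averaged probabilities.

## Synthetic cohorts

The generator emulates the structure of the motivating registry extract:
34 centers labelled by letter and Indigenous/non-Indigenous designation,
log-normal center sizes (roughly 20-2,500 patients, ~17,000 total at the
defaults), independent categorical covariates with partly sparse
prevalences (CVD 0.4%, Indigenous 4%), generating coefficients set to
estimates representative of a real registry analysis (intercept -2.38, sigma_u = 0.4),
and two small centers whose random intercept is forced to -6 so they
have essentially zero events — exercising the eps rule and the FDR edge
cases.  The age-group and calendar-period mixes are chosen so the
default two-year transplant prevalence lands in the 0.08-0.16 band
around the registry's ~12% (the latest era is down-weighted because the
outcome needs two full years of follow-up).

What the generator does *not* emulate: covariate correlations (real
case-mix is strongly structured; a latent-copula hook is a possible
extension), center-covariate confounding (real Indigenous-serving
centers differ systematically in case-mix), secular drift within
periods, or informative center sizes.  Passing recovery tests therefore
show that the sampler and profiling pipeline are correct under the
model, not that the model is adequate for any particular registry.

## Problem sizes used in the tests and acceptance run

The replicate recovery study uses 20 cohorts of ~2,000 patients
(3 chains x 6,000 iterations each), a size at which the posterior is
informative for all but the deliberately sparse coefficients while a
full 20-replicate study remains a few minutes of compute.  The
acceptance script's headline fit uses a ~6,000-patient cohort at the
full reference sampler configuration (3 x 20,000, burn-in 2,000), and
five additional ~2,000-patient replicates for coverage.  Sparse
coefficients (CVD, Indigenous status, age 76+) are excluded from the
PSRF/ESS gates exactly as the original analysis singles them out as
non-converged; their posteriors remain wide and prior-influenced.

## Numerical choices and edge cases

* log(1 + e^eta) is computed as logaddexp(0, eta): finite over
  |eta| <= 700.
* The IG rate convention matches the conjugate-update formula; draws
  invert a Gamma(shape, rate) precision draw.
* sigma_u^2 posterior means sit slightly above the generating value at
  J = 34 under the IG(1, 1) prior (its mass at larger variances); the
  recovery check therefore scores sigma_u in posterior-SD units.
* Empty covariate sets (p = 0), single-center data (J = 1) and empty
  cohorts are valid degenerate inputs for the model functions;
  zero-variance draw vectors make PSRF/ESS raise rather than return
  misleading values.
* Missing values in required columns are rejected at load time with row
  numbers — the pipeline has no imputation step.
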