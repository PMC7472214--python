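# Methods

## The task

Two bandits pay 1 monetary unit with probabilities that drift across 220
trials as independent reflected Gaussian random walks (per-step sd 0.05,
reflection bounds [0.1, 0.9], uniform start inside the bounds; all
configurable). Reflection rather than mean reversion keeps the stationary law
symmetric on the bounded interval without extra parameters. One fixed walk
pair can be shared across simulated subjects with counterbalanced bandit
labels (`WalkSchedule.swapped`), or each subject can receive a fresh walk.
Missed trials (no response inside the response window) are supported as data;
the simulator only produces them on request (`miss_rate`).

## The observer model

Each bandit's reward probability is tracked as a beta distribution
Beta(γ_a, ε_a), initialized at γ = ε = 1 (uniform; expected value 0.5 and
variance 1/12 on trial 1). After a choice of bandit *a* with outcome
R ∈ {0, 1}:

- chosen: γ_a ← (1−ω)γ_a + ω + R, ε_a ← (1−ω)ε_a + ω + (1−R)
- unchosen: γ ← (1−λ)γ + λ, ε ← (1−λ)ε + λ

ω (update/relaxation rate) and λ (forgetting rate) lie in (0, 1); both
updates relax toward the uniform prior, so a bandit never chosen again decays
geometrically to Q = 0.5 at rate (1−λ) and all parameters stay in
[1, 1 + 1/rate + 1].

Choice is softmax with temperature β over action propensities. The
previously chosen bandit enters with its updated posterior mean Q; the
previously unchosen bandit receives two extra terms:

    m_unchosen(t+1) = Q_unchosen(t) + υ·V_unchosen(t) + κ·C_rel(t)

with V the posterior variance (exploration bonus when υ > 0) and C_rel =
2·P(θ_chosen > θ_unchosen) − 1 the signed dominance probability of the
chosen bandit's reward rate (relative confidence, weighted by κ). On trial 1
no previous trial exists, so m = Q = 0.5 for both bandits and the choice is
uniform for any parameters.

Timing convention: the printed update equations index the unchosen bandit's
Q and V at trial *t*, i.e. before its relaxation, while the chosen bandit has
already absorbed the trial-*t* outcome. The default `value_timing="literal"`
implements exactly that (C_rel compares the post-update chosen belief with
the pre-relaxation unchosen belief); `"post_update"` evaluates every term
from the fully updated t+1 state. The two differ whenever λ > 0.

Missed trials update nothing, keep the previous propensities, and are
excluded from the likelihood.

### Dominance quadrature

P(θ1 > θ0) for independent betas is ∫ pdf₁(x)·cdf₀(x) dx, computed by
deterministic quadrature, vectorized across trials. Integration windows come
from moment bounds (mean ± 10 sd), verified against the actual tail mass
(beta tails are polynomial; windows discarding more than 1e-13 mass are
replaced by exact 1e-16 quantiles). Windows interior to (0, 1) use 64-node
Gauss–Legendre — the window spans at most 20 sd of the narrower
distribution, which 64 nodes resolve to near machine precision. Windows
touching an endpoint may contain an algebraic singularity x^(γ−1) or
(1−x)^(ε−1); those rows use tanh–sinh nodes (step 0.045), which handle
endpoint singularities spectrally. Orientation is swapped so the integrated
density is the smooth one whenever possible; the rare
sharp-peak-under-wide-window rows fall back to adaptive quadrature
(`scipy.integrate.quad`). Validated accuracy: ≲1e-9 absolute over parameters
in [0.5, 250], exact on polynomial closed forms (1/2, 2/3, 1/6), complement
identity within ~1e-10. A `fast=True` variant (no tail verification, no
fallback; ~1e-5 absolute) serves only inside iterative optimization; every
reported likelihood is recomputed with the accurate path.

## Maximum-likelihood fitting

The likelihood of a session is the product of softmax probabilities of the
observed choices over non-missed trials. Parameters are reported in natural
space (β > 0; ω, λ ∈ (0, 1); υ, κ real) and searched from one canonical
start (β=1, ω=λ=0.5, υ=κ=0) plus seeded uniform draws over transformed-space
boxes (log β ∈ [log 0.1, log 20], logit rates ∈ [logit 0.05, logit 0.95],
υ, κ ∈ [−2, 2]).

The search is box-constrained to those boxes (a quadratic penalty outside,
with the solution clipped back in; solutions within 1e-3 transformed units
of an edge are flagged, not rejected). The boxes double as identification
guards: the likelihood has a ridge along which β trades off against κ
(relative confidence co-varies with the value margin), and unconstrained
estimates diverge along it. Each start runs a Nelder–Mead simplex over the
five transformed parameters with a capped budget (≤200 evaluations, xatol
1e-3). The capped simplex is deliberate: exact maximization redistributes
choice determinism arbitrarily across (β, υ, κ) at task scale, and a
bounded local search from modest starts behaves like implicit
regularization. During the search the dominance quadrature runs in its
reduced-accuracy mode; the objective is then re-evaluated with the accurate
quadrature at each simplex solution *and* at the start itself, so the
returned optimum can never lose to any evaluated start — in particular,
when the generating parameters are supplied as an extra start, the fitted
likelihood is guaranteed to match or beat them. Everything is deterministic
given (session, n_starts, seed).

The Rescorla–Wagner baseline (Q ← Q + α(R − Q) for the chosen bandit,
initial Q = 0.5, softmax choice; k = 2) is cheap and fitted by a plain
simplex on (log β, logit α) with the same restart scheme.

BIC is k·ln(n_obs) + 2·nll with n_obs the number of non-missed trials;
model comparison tables report ΔBIC against the best model. Solutions within
1e-3 (transformed units) of the start-box edges are flagged
(`boundary_flags`), not rejected.

### What recovery can and cannot show

With 220 trials the five observer parameters are only partially identified:
β trades off against κ (relative confidence correlates with the value
margin), and agents whose parameters produce near-chance behavior (low β,
margin-compressing κ) carry no information about any parameter. The
parameter-recovery experiment therefore samples engaged learners —
β ~ logU[2.5, 15], ω ~ U[0.15, 0.65], λ ~ U[0.05, 0.45], υ ~ U[0.25, 0.75],
κ ~ U[0.05, 0.45] — and measures rank correlation between true and recovered
β and ω across 50 agents, plus the likelihood-dominance guarantee above.
Under these conditions the update rate ω recovers in rank terms, and the
fitted likelihood beats the generating parameters for every agent, but the
β coordinate of the estimate remains close to noise: the likelihood spreads
choice determinism across (β, υ, κ) almost arbitrarily at this data size,
under every estimator and task design tried (exact profile maximization,
capped simplex, fixed or per-agent walks, narrower or wider bonus-weight
dispersion). Rank recovery of β at 220 trials should be treated as
unattainable for this model; recovering β requires more trials (see the
scaling property in the test suite) or a hierarchical design, which is out
of scope here.

## Performance measures and the value regressor

Wins = number of rewarded trials (equal to money in task units). An optimal
choice is one whose true reward probability is the (possibly tied) maximum
at that trial. A switch is a non-missed trial whose choice differs from the
previous non-missed choice; the optimal-switch fraction divides optimal
switches by all switches (NaN when no switch occurred). The value regressor
is Q of the chosen option at choice time — the parametric modulator used for
choice-locked value signals in model-based fMRI — with missed trials absent.

## Synthetic cohort

Subject-level covariates follow a linear-Gaussian structural model on
standardized variables: a binary age contrast (old = high) → FA and BP_ND
with independent residuals; FA and BP_ND → q_signal; q_signal → wins.
Default path coefficients: FA→q 0.49, BP_ND→q 0.41, q→wins 0.54 (the
published multivariate estimates); age→FA −0.507, derived analytically from
the published FA group means/sds (0.34/0.03 young, 0.31/0.02 old) so the raw
FA scale honors the group means exactly and the sds in pooled form;
age→BP_ND −0.45 (no published value; chosen so the implied age–q_signal
correlation is near the published univariate −0.32). Residual sds default to
unit-variance completion and generation fails if the paths alone imply
variance ≥ 1. BP_ND and wins receive plausible affine raw scales (BP_ND
2.0 ± 0.25, wins 128.21 ± 10 rounded to integers); affine maps leave all
standardized statistics unchanged. FA–BP_ND dependence arises only through
age, so their age-partialled correlation is zero by construction.

Wins are either linear in q_signal (default; keeps the statistical battery
fast) or mechanistic: q_signal maps through a logistic link to a softmax
temperature β ∈ [0.2, 6] (slope 1 around q = 0) and a full session is
simulated per subject with fixed companion parameters (ω=0.4, λ=0.15,
υ=κ=0.3), which is also how the end-to-end pipeline couples cohort and task.

What the generator does *not* emulate: measurement error in FA/PET/fMRI
estimates, non-Gaussian covariate distributions, age heterogeneity within
groups beyond the binary contrast, and any direct age→wins path. Passing
tests therefore show that the statistical battery recovers the structure it
assumes, not that the structure holds in real data.

## Statistical battery

Pearson correlations with Fisher-z 95% CIs (se = 1/√(n−3−k)); partial
correlations by residualizing both variables on an intercept plus controls,
df = n−2−k. Standardized regression z-scores everything and runs OLS;
coefficient CIs from the t distribution; VIF_j = 1/(1−R²_j) from explicit
auxiliary regressions; the VIF alarm is strict (> 10). Regression BIC uses
the Gaussian likelihood at the ML variance, counting intercept, slopes and
variance, so ΔBIC is comparison-safe across models of the same data.
Residual normality is gated by Shapiro–Wilk at p > 0.05. Group differences
use the pooled-variance t-test (one-tailed direction: first argument
hypothesized lower, matching the old < young performance hypothesis) and
Cohen's d with pooled sd and a normal-approximation CI. Rank-deficient
designs raise a collinearity error naming the dependent columns.

## Pipeline and reproducibility

A single global seed expands into per-stage child seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`. Every artifact carries
`# config_hash/seed/version` provenance lines (CSV) or a `_meta` object
(JSON); floats are written with `repr` so round-trips are exact and repeated
runs are byte-identical. The end-to-end pipeline simulates sessions with the
cohort's logistic q→β link, takes wins from the simulated behavior, fits the
observer per subject, exports performance and value regressors, and runs the
group battery (q_signal ~ age+BP_ND+FA; wins ~ age+BP_ND+FA+q_signal; BIC
comparison of the three q_signal models).

## Problem sizes in the test suite

Chosen as the package's own test design: parameter recovery runs 50 agents ×
220 trials × 10 restarts; model recovery (observer vs. Rescorla–Wagner by
summed BIC) runs 20 replicates with 4 observer restarts; the recovery-
improves-with-data property compares 220 against 1100 trials over 30
replicates with a warm start at the truth plus one random restart and a
100-evaluation simplex budget; Fisher-CI
null coverage uses 2000 simulated datasets of n = 45; cohort path recovery
uses n = 5000. Dominance-quadrature Monte-Carlo checks use 10⁶ samples on a
5×5 parameter grid.

## Known limitations

- Absolute β estimates inflate along the β–κ likelihood ridge at 220 trials;
  only rank-order β comparisons across subjects are meaningful at this size.
- The relative-confidence term enters the *unchosen* propensity with a
  positive sign when the chosen bandit dominates, as printed in the source
  equations; positive κ therefore compresses choice margins. The
  implementation is faithful to the printed form.
- The printed trial-1 variance 0.143 is inconsistent with the variance
  formula at γ = ε = 1 (1/12 ≈ 0.0833); the formula is implemented.
- Optimal-switch uses the all-switches denominator; the alternative
  (all trials) is not implemented.
- The dominance quadrature's `fast` mode is approximate (~1e-5); it never
  backs any reported number.
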