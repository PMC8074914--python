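# Methods

`alloctrace` implements a complete analysis chain for a third-party
resource-allocation experiment with mouse tracking: participants choose, for
three anonymous recipients, between a *Utilitarian* option (larger total
pay-off) and a *non-Utilitarian* option (higher minimum pay-off and lower
Gini coefficient), while the cursor is sampled at 60 Hz.  Because no raw
participant data ship with the package, every stage is driven by a
synthetic-experiment generator whose defaults encode the study's design, and
the statistical guarantees are established by recovery tests against known
generating values.

## Allocation summaries and predictors

An allocation is a triple of non-negative pay-offs (yen).  Its Gini
coefficient is the relative mean absolute difference
G = Σᵢⱼ|πᵢ−πⱼ| / (2·n²·μ) with n = 3, which for three recipients ranges
from 0 to 2/3 and reduces to G = 2(max−min)/(9μ).  The *variance* shown to
participants in the task is this Gini coefficient, so the dispersion
predictor of the trajectory model is a Gini difference; the statistical
pay-off variance (population divisor n, the mean–variance convention;
`ddof=1` selectable) is used only inside the mean–variance utility.

Per problem the predictors are |Δmin| (yen), |ΔGini| and optionally
|Δtotal|; each column is standardized to mean 0, variance 1 (population
divisor) within the problem set so that coefficient magnitudes are
comparable across predictors.

## Synthetic experiment generator

Defaults encode the study conditions: 36 participants × 48 problems, 60 Hz
sampling, a target Pearson correlation of 0.49 between |Δmin| and |ΔGini|
across problems (tolerance ±0.1), ~73% non-Utilitarian choices, and
log-normal response times with median 1.8 s (mean ≈ 2.0 s, sd ≈ 0.95 s).

**Problems.**  The non-Utilitarian option draws its minimum from
U(450, 750) yen and a modest spread; the Utilitarian option takes a minimum
lower by |Δmin| ~ clipped-N(170, 90²) ∈ [30, 420] yen, a total larger by
U(120, 520) yen, and a Gini targeted at an independently drawn offset
(≈ N(0.13, 0.08²)) above the non-Utilitarian Gini, clipped into the band
attainable for a 3-recipient allocation with that minimum and mean
(G ∈ [(1−k)/3, 2(1−k)/3] for k = min/mean).  The clipping induces a
moderate positive correlation between the two predictors — the same
ecological coupling between worst-off and dispersion differences the design
reflects — so no explicit correlation knob is needed; whole problem sets
are redrawn until the realized r is within ±0.1 of the target (skipped
below 5 problems, where r is unstable; rejection budgets raise a
`GenerationFailure` naming the unsatisfiable constraint).  Pay-offs are
rounded to 10 yen.

**Choices.**  Each simulated participant draws a maximin concern
α ~ N(0.85, 0.1²) clipped to [0, 1] (or an egalitarian weight
β ~ N(1.0, 0.5²) for mean–variance agents) and an inverse temperature
τ ~ LogNormal(0, 0.5²), then chooses the non-Utilitarian option with
probability logistic(τ·(U_N − U_U)) on 100-yen-scaled utilities.  The
logistic rule is the standard binary-choice likelihood; utilities are
translation-invariant inside it, so only differences matter.  Presentation
side and trial order are randomized per participant.  Under these defaults
the overall non-Utilitarian rate falls in ≈ 0.66–0.75 across seeds.

**Trajectories.**  Each trial's 101-step latent x-path (analysis
coordinates, positive toward the non-Utilitarian option) is the sum of a
smoothstep baseline ramp toward the chosen side and the state-space process
below evaluated at configured true coefficient series (defaults: a smooth
min-series rising to 0.12 and a var-series to 0.04), with per-participant
drift (sd 0.02/bin), per-bin participant coefficient deviations (sd 0.03)
and observation noise (sd 0.005).  Endpoints are pinned exactly to (0, 0)
and the chosen target; y rises monotonically.  The path is mapped to screen
pixels through the anchor affine map and resampled onto the 60 Hz clock
over the trial's response time.  The generator does *not* model kinematic
realism (velocity peaks, submovements, jitter correlated in time), so
passing tests demonstrate statistical recovery under the model's own noise
structure, not robustness to violations of it.

Endpoint pinning and the choice-dependent ramp are outside the fitted
state-space model; recovery tests for the trajectory model therefore use
`statespace.simulate_panel`, the same process without ramp or pinning.

## Utility models and evidence

Model A (quasi-maximin): U = α·min + (1−α)·total, α ∈ [0, 1].
Model B (mean–variance): U = mean − β·var.  Pay-offs are rescaled to
100-yen units internally (variance to (100 yen)², so β is order 1); this is
a pure reparameterization and utilities are reported in yen.

Two fitting modes are provided.  *Independent* mode evaluates each
participant's 2-parameter posterior (α or β, τ) on a deterministic
Gauss–Legendre grid — α ~ U(0, 1) (non-informative), β ~ N(0, 1) on the
rescaled variance (informative), log τ ~ N(0, 1), each prior renormalized
on its quadrature box — yielding exact posterior summaries and marginal
likelihoods up to quadrature error.  *Hierarchical* mode (the default for
`fit_choice_model`) places logit-normal / normal / log-normal population
distributions over α, β and τ and samples by affine-invariant ensemble
MCMC (differential-evolution moves, non-centered parameterization);
split-walker R̂ is reported for every parameter and any fit with R̂ ≥ 1.1
is flagged non-converged (CLI exit status 3).

Evidence for model A over model B is the Bayes factor
BF_AB = exp(logml_A − logml_B).  The package computes marginal likelihoods
two independent ways: (1) the per-participant quadrature above, summed over
participants (deterministic; the default for `compare_models`), and (2) an
in-package bridge-sampling estimator (moment-matched normal proposal fitted
on half the posterior draws, iterated to the optimal bridge, bootstrap
MCSE) applicable to any fit with draws.  The two routes agree within
0.05 nats on single-participant fixtures, which is the package's oracle
check on the bridge estimator.

Because the mean–variance prior is informative, `prior_sensitivity` re-runs
the comparison across a range of β prior scales (default 0.5–2.0) and
reports how the Bayes factor and posterior β move; on synthetic data the
direction of the comparison is unchanged across the range.

Auxiliary regressions mirror the behavioural analyses: a hierarchical
intercept-only logistic model of choosing the non-Utilitarian option
(participant random intercepts) and a mixed-effects linear model of
response time on choice type (participant random intercepts and slopes,
marginalized in closed form via the Woodbury identity so the sampler only
explores five parameters).

## Trajectory state-space model

With bins t = 1..101 (t = 1 at onset, t = 101 at the click):

    x[t,i,j] = μ[t,i] + βMin[t,i]·Diff_min[j] + βVar[t,i]·Diff_var[j] + ε
    βMin[t,i] = βMin_pop[t] + ηMin[t,i],   ηMin[t,i] ~ N(0, σηMin)
    βMin_pop[t] = βMin_pop[t−1] + ζMin,    ζMin ~ N(0, σζMin)

(and symmetrically for the variance predictor; a third total-difference
covariate is optional).  All N(·,·) scale arguments are standard
deviations; ε has fixed sd 0.005 (configurable).  At t = 1 the cursor is
pinned at the origin, so every series starts at exactly 0.  The intercept
follows μ[t,i] = μ[t−1,i] + δᵢ with a constant per-participant drift
δᵢ ~ N(0, σδ) — read literally this is a linear trend, the default
(`mu_dynamics="linear_drift"`); a per-participant random walk is
selectable.  Deviation sds are shared across bins: a per-bin sd (101
hyperparameters per coefficient) is weakly identified and not supported.

**Inference.**  Conditional on the sd hyperparameters
(σδ, σηMin, σηVar, σζMin, σζVar; +2 with the total covariate) the model is
jointly linear-Gaussian: participant deviations fold into a per-participant
observation covariance D·diag(ση²)·Dᵀ + σε²I, and the population series
plus drifts form a small latent state (K + N dimensions).  The package
therefore marginalizes the latent series exactly with a Kalman filter
(scalar sequential updates on whitened observations, numba-compiled) and
samples only the hyperparameters (half-normal priors, unit scale after
standardization) with an ensemble sampler initialized at a Nelder–Mead MAP.
Each retained hyperparameter draw contributes one exact joint draw of the
coefficient series via forward-filter backward-sampling.  This
Rao-Blackwellization gives full posteriors over ~10³ latent states in well
under a minute on one CPU at the desk-scale fixture (10 participants × 16
problems), the default test size; the full 36 × 48 design is supported and
simply scales the filter linearly.  R̂ is computed for every hyperparameter
and for the series draws (walkers grouped into pseudo-chains); fits with
any R̂ ≥ 1.1 are flagged non-converged, never silently reported.

**Bands and departures.**  Pointwise 95% intervals are
narrowest-interval HDIs per bin.  The simultaneous band scales the
pointwise posterior sds by the 95th percentile of each draw's maximum
standardized deviation across bins, then is widened (elementwise) to
contain the pointwise interval, so nesting holds by construction and joint
coverage is at least nominal.  The departure time of a coefficient is the
first bin whose pointwise HDI excludes zero; the report also marks the bins
where the min coefficient credibly exceeds the var coefficient (HDI of the
difference above zero).

**Caveats on departure times.**  Two properties of pointwise bands matter
when reading departures.  First, before a true onset the 95% interval
retains its nominal ~5% false-exclusion rate per (correlated) bin, so over
~30 pre-onset bins the *first* exclusion can land early in a sizeable
fraction of replicates even when the fit is correct.  Second, the random
walk smooths discontinuities: the posterior leaks a sharp post-onset level
a few bins backward.  In 10 seeded replicates of a step of 0.15 at bin 30
(desk-scale fixture), departures were detected in all replicates, never
after bin 30, with median 27–29.  Departure times are therefore best read
as aggregate, slightly early-biased onset estimates; transiently excluded
intervals (e.g. a briefly negative variance coefficient) are reported as
such and the package takes no stance on their interpretation.

## Numerical choices

- Kalman updates process one whitened scalar observation at a time
  (innovation variance ≥ 1 by construction: numerically stable without
  Joseph form); backward sampling adds 1e−14 jitter before the 
  conditional-covariance Cholesky.
- Utilities enter the logistic link on the 100-yen scale to keep τ order 1.
- The quadrature grid uses 161 × 101 Gauss–Legendre nodes; the adaptive
  oracle integrates the natural parameterization with Gauss–Kronrod
  (`dblquad`) after shifting by the coarse-grid maximum to avoid underflow.
- Bridge sampling splits draws in half (proposal fit vs evaluation),
  iterates the optimal bridge in log space, and reports a bootstrap MCSE.
- Degenerate inputs fail loudly: all-zero allocations (undefined Gini),
  constant feature columns (undefined correlation/standardization),
  non-increasing timestamps, trajectories without exactly 101 bins,
  non-standardized predictors, single-sided choice data for the RT model.

## Design decisions taken where the design was open

- Interpolation for time normalization is linear (bin 1 = first sample,
  bin 101 = last); interpolation and the affine coordinate map commute, so
  their order is immaterial.
- Model comparison defaults to the deterministic quadrature route
  (independent-participant priors); bridge sampling on hierarchical fits is
  available and oracle-checked.  Both fitting modes are first-class.
- The pipeline fits the trajectory model on a 10 × 16 subset of the
  experiment by default so a full run completes in minutes; all behavioural
  analyses use every trial.
- Half-normal(1) priors on all sd hyperparameters after standardization.

## Known limitations

- The trajectory generator's noise model matches the fitted model by
  construction (plus ramp and endpoint pinning); real cursor data violate
  iid-per-bin deviations, so recovery results bound what the method can do
  under its own assumptions only.
- The ensemble sampler explores the hierarchical choice model's ~76
  dimensions adequately for the population and participant summaries
  reported here, but posterior tails of participant-level τ are less well
  resolved than a gradient-based sampler would give.
- `deviation_sd_mode="per_time"` is declared but not implemented (weakly
  identified; see above).
- Bridge sampling assumes a roughly elliptical posterior on the
  unconstrained scale; it is oracle-checked only at 2 dimensions.
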