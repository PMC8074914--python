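# alloctrace

Analysis pipeline for third-party resource-allocation experiments with
mouse tracking.  People dislike unequal allocations, but "inequality
aversion" conflates two distinct concerns: an *egalitarian* concern about
dispersion (variance / Gini) and a *maximin* concern about the worst-off
recipient.  In the task this package analyses, a decision maker repeatedly
chooses — for three anonymous recipients — between a **Utilitarian** option
(larger total pay-off) and a **non-Utilitarian** option (higher minimum
pay-off and lower Gini coefficient), while the mouse cursor is recorded at
60 Hz.  The pipeline separates the two concerns at both the choice level
and the cognitive (trajectory) level.

It is aimed at researchers in judgement & decision making / social
preference measurement who want a fully synthetic, reproducible test bed:
every stage runs off a generator that emulates the experimental design
(36 participants × 48 problems), so the whole analysis is exercisable with
no participant data.

## The models

**Choice level.**  Two utility models are compared on the binary choices:

- quasi-maximin (model A):  U(x) = α·min(π₁,π₂,π₃) + (1−α)·(π₁+π₂+π₃),
  with α ∈ [0,1] the weight on the worst-off recipient;
- mean–variance (model B):  U(x) = (π₁+π₂+π₃)/3 − β·Var[π₁,π₂,π₃],
  with β ∈ ℝ the weight on dispersion.

Choices follow a logistic rule on the utility difference with a
participant-specific inverse temperature.  Evidence is summarized by the
Bayes factor BF_AB = exp(logml_A − logml_B), computed by deterministic
per-participant quadrature and, independently, by an in-package
bridge-sampling estimator (oracle-checked against the quadrature).

**Cognitive level.**  The time-normalized cursor x-position (101 bins,
positive toward the non-Utilitarian option) is modelled by a hierarchical
state-space regression with time-varying coefficients:

    x[t,i,j] = μ[t,i] + βMin[t,i]·Diff_min[j] + βVar[t,i]·Diff_var[j] + ε,

where the population-level series βMin_pop[t], βVar_pop[t] evolve as
Gaussian random walks pinned to 0 at t = 1, participant coefficients
scatter around them, and ε ~ N(0, sd 0.005).  The fitted series come with
pointwise and simultaneous 95% highest-density bands and *departure
times* — the first bin at which a coefficient's pointwise band excludes
zero, i.e. when that attribute starts driving the cursor.  Inference is
exact-in-the-states (Kalman marginalization + forward-filter
backward-sampling) with MCMC only over the handful of sd hyperparameters;
see `docs/methods.md`.

## Worked example

```python
import numpy as np
import alloctrace as at

cfg = at.SimulationConfig(seed=1)                     # 36 x 48 study design
rng = np.random.default_rng(1)
problems = at.generate_problems(cfg, rng)
features = at.compute_features(problems)
print(round(at.feature_correlation(features), 3))     # 0.482

trials, truth = at.simulate_choices(problems, cfg, rng)
print(round(np.mean([t.choice == "N" for t in trials]), 3))   # 0.729

from alloctrace import choicemodels as cm
comp = cm.compare_models(trials, problems)
print(round(comp.logml_a - comp.logml_b, 1))          # 180.8
```

The three printed numbers say: the generated problem set couples the
|Δmin| and |ΔGini| predictors at r = 0.48 (the design targets the moderate
ecological correlation 0.49 ± 0.1); simulated quasi-maximin agents choose
the non-Utilitarian option on 72.9% of trials (strong inequality
aversion); and the data favour the quasi-maximin over the mean–variance
model by 180.8 nats of log marginal likelihood — overwhelming evidence for
the generating model, i.e. choices are driven by the worst-off pay-off
rather than dispersion.

A full run — simulation, preprocessing, both utility-model fits, Bayes
factor, choice-rate and response-time regressions, the trajectory
state-space fit, departure table, figures — is one call:

```bash
alloctrace run-all --seed 1 --out run1/
```

or `alloctrace simulate / preprocess / fit-choice / compare /
fit-statespace / report` for the individual stages.  Outputs are CSV/JSON
per stage plus `report.md`; any fit with R̂ ≥ 1.1 stamps the report
NON-CONVERGED and sets exit status 3.

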