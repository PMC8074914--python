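"""Bayesian social-preference utility models for allocation choices.

Two utility models are compared on the binary choice between the Utilitarian
option (larger total) and the non-Utilitarian option (higher minimum, lower
Gini):

* model A, quasi-maximin:  U(x) = alpha * min(pi) + (1 - alpha) * sum(pi),
  alpha in [0, 1] the concern for the worst-off;
* model B, mean-variance:  U(x) = mean(pi) - beta * var(pi), beta
  unconstrained, the concern for dispersion.

Choices follow a logistic rule on the utility difference with a
participant-specific inverse temperature tau.  Pay-offs are rescaled to
100-yen units internally (variance to (100 yen)^2) so tau and beta are
order-1; utilities are reported on the natural yen scale.

Evidence is compared through marginal likelihoods: deterministic 2-D
quadrature for independent per-participant fits (exact up to quadrature
error), and an in-package bridge-sampling estimator for MCMC fits,
cross-checkable against the quadrature oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
from scipy.special import expit, log_expit, logsumexp

from .allocations import Allocation, ChoiceProblem, payoff_variance

__all__ = [
    "utility_quasi_maximin",
    "utility_mean_variance",
    "ChoiceData",
    "ChoiceModelFit",
    "ModelComparison",
    "fit_choice_model",
    "marginal_likelihood",
    "quadrature_oracle_logml",
    "compare_models",
    "fit_choice_rate",
    "fit_rt_model",
    "bridge_sampling_logml",
]

RHAT_THRESHOLD = 1.1
_SCALE = 100.0  # yen per internal utility unit


def utility_quasi_maximin(allocation: Allocation, alpha: float) -> float:
    """U = alpha * min + (1 - alpha) * total, in yen."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * allocation.minimum + (1.0 - alpha) * allocation.total


def utility_mean_variance(allocation: Allocation, beta: float) -> float:
    """U = mean - beta * population variance, in yen."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return allocation.mean - beta * payoff_variance(allocation)


# ---------------------------------------------------------------------------
# data container


@dataclass
class ChoiceData:
    """Per-trial design arrays on the internal (100-yen) scale.

    du_a(alpha)  = c_a + alpha * m_a  per trial  (model A utility difference N-U)
    du_b(beta)   = c_b - beta * v_b   per trial  (model B)
    y = +1 for a non-Utilitarian choice, -1 otherwise.
    """

    participants: np.ndarray     # participant label per trial
    y: np.ndarray
    c_a: np.ndarray
    m_a: np.ndarray
    c_b: np.ndarray
    v_b: np.ndarray
    rt: np.ndarray

    @classmethod
    def build(cls, trials, problems: list[ChoiceProblem]) -> "ChoiceData":
        by_id = {p.problem_id: p for p in problems}
        rows = []
        for t in trials:
            if t.problem_id not in by_id:
                raise KeyError(f"trial references unknown problem {t.problem_id!r}")
            p = by_id[t.problem_id]
            u, n = p.utilitarian, p.non_utilitarian
            dmin = (n.minimum - u.minimum) / _SCALE
            dtot = (n.total - u.total) / _SCALE
            dmean = (n.mean - u.mean) / _SCALE
            dvar = (payoff_variance(n) - payoff_variance(u)) / _SCALE**2
            rows.append(
                (t.participant_id, 1.0 if t.choice == "N" else -1.0,
                 dtot, dmin - dtot, dmean, dvar, t.rt)
            )
        arr = list(zip(*rows))
        return cls(
            participants=np.array(arr[0]),
            y=np.array(arr[1]),
            c_a=np.array(arr[2]),
            m_a=np.array(arr[3]),
            c_b=np.array(arr[4]),
            v_b=np.array(arr[5]),
            rt=np.array(arr[6]),
        )

    def split(self):
        labels = sorted(set(self.participants.tolist()))
        for lab in labels:
            sel = self.participants == lab
            yield lab, ChoiceData(
                self.participants[sel], self.y[sel], self.c_a[sel],
                self.m_a[sel], self.c_b[sel], self.v_b[sel], self.rt[sel],
            )


def _du(data: ChoiceData, model: str, param):
    """Utility difference N-U per trial, broadcastable in `param`."""
    param = np.asarray(param)[..., None]
    if model == "A":
        return data.c_a + param * data.m_a
    if model == "B":
        return data.c_b - param * data.v_b
    raise ValueError(f"model must be 'A' or 'B', got {model!r}")


def _loglik(data: ChoiceData, model: str, param, tau):
    """Sum over trials of log P(choice); param/tau broadcast together."""
    du = _du(data, model, param)
    with np.errstate(over="ignore", invalid="ignore"):
        return log_expit(data.y * np.asarray(tau)[..., None] * du).sum(axis=-1)


# ---------------------------------------------------------------------------
# priors (unconstrained parameterizations)

# independent-participant priors: alpha ~ U(0,1) (non-informative),
# beta ~ N(0,1) (informative, on the rescaled variance), log tau ~ N(0,1)


def _log_prior_indep(model: str, param, log_tau):
    if model == "A":
        inside = (param >= 0.0) & (param <= 1.0)
        lp = np.where(inside, 0.0, -np.inf)
    else:
        lp = -0.5 * param**2 - 0.5 * np.log(2 * np.pi)
    lp = lp - 0.5 * log_tau**2 - 0.5 * np.log(2 * np.pi)
    return lp


@dataclass
class ChoiceModelFit:
    model: str                       # "A" | "B"
    mode: str                        # "independent" | "hierarchical"
    participants: list
    param_mean: np.ndarray           # posterior mean alpha_i or beta_i
    param_sd: np.ndarray
    param_interval: np.ndarray       # (n_part, 2) central 95%
    tau_mean: np.ndarray
    draws: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    logml: float | None = None
    logml_mcse: float | None = None
    # hooks for bridge sampling
    unconstrained_draws: np.ndarray | None = None
    log_post_fn: object = None
    data: ChoiceData | None = None


@dataclass
class ModelComparison:
    logml_a: float
    logml_b: float
    method: str
    mcse: float = 0.0

    @property
    def bayes_factor_ab(self) -> float:
        return float(np.exp(self.logml_a - self.logml_b))


# ---------------------------------------------------------------------------
# independent-participant fit: deterministic 2-D grid posterior


def _grid(model: str, n_param: int = 161, n_tau: int = 101, beta_prior_sd: float = 1.0):
    from numpy.polynomial.legendre import leggauss
    from scipy.stats import norm

    xp, wp = leggauss(n_param)
    if model == "A":
        param = 0.5 * (xp + 1.0)             # alpha on (0, 1)
        w_param = np.log(wp * 0.5)           # uniform prior folded in
    else:
        half = 4.0 * beta_prior_sd           # informative N(0, sd^2) on its box
        param = half * xp
        w_param = (np.log(wp * half)
                   - 0.5 * (param / beta_prior_sd) ** 2
                   - 0.5 * np.log(2 * np.pi) - np.log(beta_prior_sd)
                   - np.log(norm.cdf(4.0) - norm.cdf(-4.0)))   # proper on the box
    xt, wt = leggauss(n_tau)
    log_tau = 4.0 * xt                       # log tau on (-4, 4), prior N(0,1)
    w_tau = (np.log(wt * 4.0) - 0.5 * log_tau**2 - 0.5 * np.log(2 * np.pi)
             - np.log(norm.cdf(4.0) - norm.cdf(-4.0)))
    return param, w_param, log_tau, w_tau


def _fit_one_grid(data: ChoiceData, model: str, beta_prior_sd: float = 1.0):
    param, w_param, log_tau, w_tau = _grid(model, beta_prior_sd=beta_prior_sd)
    P, T = np.meshgrid(param, log_tau, indexing="ij")
    ll = _loglik(data, model, P.ravel(), np.exp(T.ravel())).reshape(P.shape)
    logw = ll + w_param[:, None] + w_tau[None, :]
    logml = float(logsumexp(logw))
    w = np.exp(logw - logml)
    p_marg = w.sum(axis=1)
    mean = float(param @ p_marg)
    sd = float(np.sqrt(max((param - mean) ** 2 @ p_marg, 0.0)))
    cdf = np.cumsum(p_marg)
    lo = float(np.interp(0.025, cdf, param))
    hi = float(np.interp(0.975, cdf, param))
    tau_mean = float(np.exp(log_tau) @ w.sum(axis=0))
    return mean, sd, (lo, hi), tau_mean, logml


def fit_choice_model(
    trials, problems, model: str, *, mode: str = "hierarchical",
    mcmc: dict | None = None, seed: int = 0,
) -> ChoiceModelFit:
    """Fit model A (quasi-maximin) or B (mean-variance) to choices.

    mode="independent" evaluates each participant's 2-parameter posterior on
    a deterministic quadrature grid (exact marginal likelihood as a
    by-product); mode="hierarchical" samples the population model (logit-
    normal alpha / normal beta, log-normal tau) by ensemble MCMC, with
    per-parameter R-hat and a convergence flag.
    """
    data = trials if isinstance(trials, ChoiceData) else ChoiceData.build(trials, problems)
    if model not in ("A", "B"):
        raise ValueError("model must be 'A' or 'B'")
    if mode == "independent":
        return _fit_independent(data, model)
    if mode == "hierarchical":
        return _fit_hierarchical(data, model, mcmc or {}, seed)
    raise ValueError(f"unknown mode {mode!r}")


def _fit_independent(data: ChoiceData, model: str,
                     beta_prior_sd: float = 1.0) -> ChoiceModelFit:
    labels, means, sds, ivals, taus, logmls = [], [], [], [], [], []
    for lab, d in data.split():
        mean, sd, (lo, hi), tau_mean, logml = _fit_one_grid(d, model, beta_prior_sd)
        labels.append(lab)
        means.append(mean)
        sds.append(sd)
        ivals.append((lo, hi))
        taus.append(tau_mean)
        logmls.append(logml)
    return ChoiceModelFit(
        model=model, mode="independent", participants=labels,
        param_mean=np.array(means), param_sd=np.array(sds),
        param_interval=np.array(ivals), tau_mean=np.array(taus),
        logml=float(np.sum(logmls)), logml_mcse=0.0, data=data,
    )


# ---------------------------------------------------------------------------
# hierarchical fit (ensemble MCMC, non-centered)


def _hier_log_post(theta, data_by_part, model):
    """Vectorized over walkers: theta (W, 4 + 2N)."""
    theta = np.atleast_2d(theta)
    W = theta.shape[0]
    N = len(data_by_part)
    m_p, ls_p, m_t, ls_t = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
    z_p = theta[:, 4 : 4 + N]
    z_t = theta[:, 4 + N :]
    s_p, s_t = np.exp(ls_p), np.exp(ls_t)
    if model == "A":
        # logit-normal population for alpha; weak hyperpriors (non-informative)
        param = expit(m_p[:, None] + s_p[:, None] * z_p)
        lp_hyper = -0.5 * (m_p / 3.0) ** 2 - 0.5 * (s_p / 2.0) ** 2 + ls_p
    else:
        param = m_p[:, None] + s_p[:, None] * z_p
        lp_hyper = -0.5 * m_p**2 - 0.5 * (s_p / 1.0) ** 2 + ls_p
    tau = np.exp(m_t[:, None] + s_t[:, None] * z_t)
    lp_hyper = lp_hyper - 0.5 * (m_t / 1.5) ** 2 - 0.5 * (s_t / 1.0) ** 2 + ls_t
    lp = lp_hyper - 0.5 * (z_p**2).sum(axis=1) - 0.5 * (z_t**2).sum(axis=1)
    ll = np.zeros(W)
    for i, d in enumerate(data_by_part):
        ll += _loglik(d, model, param[:, i], tau[:, i])
    bad = ~np.isfinite(lp + ll)
    out = lp + ll
    out[bad] = -np.inf
    return out


def _hier_param_tau(theta, model, N):
    theta = np.atleast_2d(theta)
    m_p, ls_p, m_t, ls_t = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
    z_p = theta[:, 4 : 4 + N]
    z_t = theta[:, 4 + N :]
    raw = m_p[:, None] + np.exp(ls_p)[:, None] * z_p
    param = expit(raw) if model == "A" else raw
    tau = np.exp(m_t[:, None] + np.exp(ls_t)[:, None] * z_t)
    return param, tau


def _fit_hierarchical(data: ChoiceData, model: str, mcmc: dict, seed: int) -> ChoiceModelFit:
    parts = list(data.split())
    labels = [lab for lab, _ in parts]
    data_by_part = [d for _, d in parts]
    N = len(labels)
    ndim = 4 + 2 * N
    nwalkers = mcmc.get("walkers", max(2 * ndim + 2, 80))
    nwalkers += (-nwalkers) % 4        # equal pseudo-chains for R-hat
    warmup = mcmc.get("warmup", 1200)
    draws = mcmc.get("draws", 800)
    rng = np.random.default_rng(seed)

    p0 = 0.3 * rng.standard_normal((nwalkers, ndim))
    p0[:, 0] += 1.5 if model == "A" else 1.0   # start near inequality-averse pop.
    p0[:, 1] -= 1.0
    p0[:, 3] -= 1.0
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, _hier_log_post, args=(data_by_part, model),
        vectorize=True, moves=moves,
    )
    sampler._random = np.random.RandomState(seed % 2**32)
    state = sampler.run_mcmc(p0, warmup, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, draws, skip_initial_state_check=True)
    chain = sampler.get_chain()                  # (draws, walkers, ndim)

    param, tau = _hier_param_tau(chain.reshape(-1, ndim), model, N)
    n_chains = 4
    groups = np.array_split(np.arange(nwalkers), n_chains)
    rhat = {}
    for k, name in enumerate(["pop_mean", "pop_log_sd", "tau_log_mean", "tau_log_sd"]):
        per = np.stack([chain[:, g, k].reshape(-1) for g in groups])
        rhat[name] = float(az.rhat(per))
    # worst-case participant-level R-hat
    worst = 1.0
    pc = chain.reshape(draws, nwalkers, ndim)
    for k in range(4, ndim):
        per = np.stack([pc[:, g, k].reshape(-1) for g in groups])
        r = float(az.rhat(per))
        worst = max(worst, r)
    rhat["participant_worst"] = worst
    converged = all(v < RHAT_THRESHOLD for v in rhat.values())
    if not converged:
        warnings.warn(
            f"hierarchical model {model} flagged non-converged "
            f"(max R-hat {max(rhat.values()):.3f})", stacklevel=2,
        )
    interval = np.stack(
        [np.quantile(param, 0.025, axis=0), np.quantile(param, 0.975, axis=0)], axis=1
    )
    return ChoiceModelFit(
        model=model, mode="hierarchical", participants=labels,
        param_mean=param.mean(axis=0), param_sd=param.std(axis=0),
        param_interval=interval, tau_mean=tau.mean(axis=0),
        draws={"param": param, "tau": tau, "chain": chain},
        rhat=rhat, converged=converged,
        unconstrained_draws=chain.reshape(-1, ndim),
        log_post_fn=lambda th: _hier_log_post(th, data_by_part, model),
        data=data,
    )


# ---------------------------------------------------------------------------
# marginal likelihoods


def bridge_sampling_logml(
    draws: np.ndarray, log_post_fn, rng: np.random.Generator,
    *, max_iter: int = 200, tol: float = 1e-8, n_boot: int = 10,
) -> tuple[float, float]:
    """Bridge-sampling estimate of log integral of exp(log_post_fn).

    `draws` are posterior samples on an unconstrained scale; the proposal is
    a moment-matched multivariate normal fitted on one half of the draws and
    evaluated against the other half (so proposal fitting and estimation do
    not reuse the same samples).  Returns (log marginal likelihood,
    bootstrap MCSE).
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    M, d = draws.shape
    half = M // 2
    fit_half, eval_half = draws[:half], draws[half:]
    mean = fit_half.mean(axis=0)
    cov = np.cov(fit_half.T) + 1e-10 * np.eye(d)
    L = np.linalg.cholesky(cov)
    n1 = len(eval_half)
    prop = mean + rng.standard_normal((n1, d)) @ L.T

    def logq(x):
        z = np.linalg.solve(L, (x - mean).T)
        return (
            -0.5 * (z**2).sum(axis=0)
            - 0.5 * d * np.log(2 * np.pi)
            - np.log(np.diag(L)).sum()
        )

    l_post = np.asarray(log_post_fn(eval_half)) - logq(eval_half)   # l2
    l_prop = np.asarray(log_post_fn(prop)) - logq(prop)             # l1
    finite = np.isfinite(l_prop)
    n_inf = int((~finite).sum())
    l_prop = np.where(finite, l_prop, -np.inf)

    def estimate(l1, l2):
        n_1, n_2 = len(l1), len(l2)
        ls1, ls2 = np.log(n_1 / (n_1 + n_2)), np.log(n_2 / (n_1 + n_2))
        shift = np.median(l2[np.isfinite(l2)])
        logr = 0.0
        for _ in range(max_iter):
            num = logsumexp(
                l1 - shift - np.logaddexp(ls1 + l1 - shift, ls2 + logr)
            ) - np.log(n_1)
            den = logsumexp(
                -np.logaddexp(ls1 + l2 - shift, ls2 + logr)
            ) - np.log(n_2)
            new = num - den
            if abs(new - logr) < tol:
                logr = new
                break
            logr = new
        return logr + shift

    logml = estimate(l_prop, l_post)
    boots = []
    for _ in range(n_boot):
        i1 = rng.integers(0, len(l_prop), len(l_prop))
        i2 = rng.integers(0, len(l_post), len(l_post))
        boots.append(estimate(l_prop[i1], l_post[i2]))
    mcse = float(np.std(boots))
    if n_inf > 0.5 * n1:
        warnings.warn(
            f"bridge sampling: {n_inf}/{n1} proposal draws fell outside the "
            "posterior support; estimate may be unreliable", stacklevel=2,
        )
    return float(logml), mcse


def _indep_log_post_fn(data: ChoiceData, model: str):
    """Unnormalized log posterior on the unconstrained (u, log tau) scale."""

    def fn(theta):
        theta = np.atleast_2d(theta)
        u, log_tau = theta[:, 0], theta[:, 1]
        if model == "A":
            param = expit(u)
            # uniform prior on alpha + logit Jacobian
            lp = log_expit(u) + log_expit(-u)
        else:
            param = u
            lp = -0.5 * u**2 - 0.5 * np.log(2 * np.pi)
        lp = lp - 0.5 * log_tau**2 - 0.5 * np.log(2 * np.pi)
        return lp + _loglik(data, model, param, np.exp(log_tau))

    return fn


def sample_single_participant(
    data: ChoiceData, model: str, rng: np.random.Generator,
    *, walkers: int = 32, warmup: int = 500, draws: int = 500,
) -> tuple[np.ndarray, object]:
    """MCMC draws for one participant's (param, tau) under the independent prior."""
    fn = _indep_log_post_fn(data, model)
    p0 = 0.5 * rng.standard_normal((walkers, 2))
    sampler = emcee.EnsembleSampler(walkers, 2, fn, vectorize=True)
    sampler._random = np.random.RandomState(int(rng.integers(2**32)))
    state = sampler.run_mcmc(p0, warmup, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, draws, skip_initial_state_check=True)
    return sampler.get_chain(flat=True), fn


def marginal_likelihood(
    fit: ChoiceModelFit, *, seed: int = 0,
    draws: np.ndarray | None = None, log_post_fn=None,
) -> tuple[float, float]:
    """Bridge-sampling log marginal likelihood of a fitted model.

    For independent-mode fits the exact quadrature value is already stored;
    this function re-estimates it from MCMC draws (supplied or generated)
    so the two routes can be compared.
    """
    rng = np.random.default_rng(seed)
    if draws is None or log_post_fn is None:
        if fit.unconstrained_draws is not None:
            draws, log_post_fn = fit.unconstrained_draws, fit.log_post_fn
        elif fit.mode == "independent":
            labels = list(fit.participants)
            if len(labels) != 1:
                raise ValueError(
                    "bridge sampling on independent fits is per participant; "
                    "pass a single-participant fit or explicit draws"
                )
            _, d = next(fit.data.split())
            draws, log_post_fn = sample_single_participant(d, fit.model, rng)
        else:
            raise ValueError("fit carries no draws for bridge sampling")
    logml, mcse = bridge_sampling_logml(draws, log_post_fn, rng)
    fit.logml, fit.logml_mcse = logml, mcse
    return logml, mcse


def quadrature_oracle_logml(trials, problems, model: str, *, data: ChoiceData | None = None) -> float:
    """Independent oracle: adaptive 2-D quadrature of prior x likelihood.

    Single participant, 2 free parameters.  Deliberately does not share code
    with the grid fit: scipy's adaptive Gauss-Kronrod rule on the natural
    parameterization.
    """
    from scipy.integrate import dblquad

    d = data if data is not None else ChoiceData.build(trials, problems)
    if len(set(d.participants.tolist())) > 1:
        raise ValueError("oracle handles a single participant only")
    if len(d.y) == 0:
        return 0.0

    # locate the mode on a coarse mesh to stabilize the exponentiation
    if model == "A":
        pg = np.linspace(1e-3, 1 - 1e-3, 41)
    else:
        pg = np.linspace(-4, 4, 41)
    tg = np.linspace(-4, 4, 41)
    P, T = np.meshgrid(pg, tg, indexing="ij")
    ll = _loglik(d, model, P.ravel(), np.exp(T.ravel()))
    shift = float(ll.max())

    def integrand(log_tau, param):
        lp = _log_prior_indep(model, np.asarray(param), np.asarray(log_tau))
        ll = _loglik(d, model, np.asarray([param]), np.asarray([np.exp(log_tau)]))[0]
        return float(np.exp(lp + ll - shift))

    lo, hi = (0.0, 1.0) if model == "A" else (-6.0, 6.0)
    val, err = dblquad(integrand, lo, hi, -6.0, 6.0, epsabs=1e-10, epsrel=1e-8)
    if val <= 0 or err > max(1e-6, 1e-4 * val):
        raise RuntimeError(f"quadrature failed to converge (value {val}, err {err})")
    return float(np.log(val) + shift)


def compare_models(trials, problems, *, method: str = "quadrature", seed: int = 0) -> ModelComparison:
    """Bayes-factor comparison of model A vs model B.

    method="quadrature": exact per-participant marginal likelihoods under the
    independent-participant priors, summed over participants (deterministic).
    method="bridge": bridge sampling on hierarchical fits.
    """
    data = trials if isinstance(trials, ChoiceData) else ChoiceData.build(trials, problems)
    if method == "quadrature":
        fa = _fit_independent(data, "A")
        fb = _fit_independent(data, "B")
        return ModelComparison(logml_a=fa.logml, logml_b=fb.logml, method="quadrature")
    if method == "bridge":
        fa = fit_choice_model(data, None, "A", mode="hierarchical", seed=seed)
        fb = fit_choice_model(data, None, "B", mode="hierarchical", seed=seed + 1)
        la, ea = marginal_likelihood(fa, seed=seed + 2)
        lb, eb = marginal_likelihood(fb, seed=seed + 3)
        return ModelComparison(logml_a=la, logml_b=lb, method="bridge",
                               mcse=float(np.hypot(ea, eb)))
    raise ValueError(f"unknown method {method!r}")


def prior_sensitivity(
    trials, problems, *, beta_prior_sds: tuple[float, ...] = (0.5, 1.0, 2.0)
) -> list[dict]:
    """Robustness of the model comparison to the informative beta prior.

    Re-runs the mean-variance fit and the Bayes-factor comparison under a
    range of prior scales for beta; the quasi-maximin side uses its
    non-informative prior throughout.  Returns one record per scale with
    the log marginal likelihoods, BF_AB, and the mean posterior beta.
    """
    data = trials if isinstance(trials, ChoiceData) else ChoiceData.build(trials, problems)
    fa = _fit_independent(data, "A")
    out = []
    for sd in beta_prior_sds:
        fb = _fit_independent(data, "B", beta_prior_sd=sd)
        out.append({
            "beta_prior_sd": float(sd),
            "logml_A": fa.logml,
            "logml_B": fb.logml,
            "bayes_factor_AB": float(np.exp(fa.logml - fb.logml)),
            "beta_posterior_mean": float(fb.param_mean.mean()),
        })
    return out


# ---------------------------------------------------------------------------
# auxiliary hierarchical regressions


@dataclass
class RegressionResult:
    coef_median: float
    interval: np.ndarray             # central 95%
    draws: np.ndarray
    rhat: float
    converged: bool
    extra: dict = field(default_factory=dict)


def fit_choice_rate(trials, *, seed: int = 0, walkers: int = 0,
                    warmup: int = 800, draws: int = 600) -> RegressionResult:
    """Hierarchical intercept-only logistic regression on choosing N.

    Posterior of the population log-odds of a non-Utilitarian choice with
    participant random intercepts; reports the 95% credible interval.
    """
    import pandas as pd

    frame = trials if isinstance(trials, pd.DataFrame) else pd.DataFrame(
        [t.__dict__ for t in trials]
    )
    grp = frame.groupby("participant_id")["choice"]
    k = grp.apply(lambda c: (c == "N").sum()).to_numpy(dtype=float)
    n = grp.size().to_numpy(dtype=float)
    if len(k) < 2:
        raise ValueError("need >= 2 participants")
    N = len(k)
    if (k == n).all() or (k == 0).all():
        warnings.warn("all choices identical; intercept is prior-bounded", stacklevel=2)
    ndim = 2 + N

    def log_post(theta):
        theta = np.atleast_2d(theta)
        b0, ls = theta[:, 0], theta[:, 1]
        z = theta[:, 2:]
        s = np.exp(ls)
        lp = -0.5 * (b0 / 5.0) ** 2 - 0.5 * (s / 2.0) ** 2 + ls - 0.5 * (z**2).sum(axis=1)
        eta = b0[:, None] + s[:, None] * z
        ll = (k * log_expit(eta) + (n - k) * log_expit(-eta)).sum(axis=1)
        return lp + ll

    nwalkers = walkers or max(2 * ndim + 2, 64)
    nwalkers += (-nwalkers) % 4
    rng = np.random.default_rng(seed)
    p0 = 0.3 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, log_post, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler._random = np.random.RandomState(seed % 2**32)
    state = sampler.run_mcmc(p0, warmup, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, draws, skip_initial_state_check=True)
    chain = sampler.get_chain()[:, :, 0]
    groups = np.array_split(np.arange(nwalkers), 4)
    r = float(az.rhat(np.stack([chain[:, g].reshape(-1) for g in groups])))
    flat = chain.reshape(-1)
    return RegressionResult(
        coef_median=float(np.median(flat)),
        interval=np.quantile(flat, [0.025, 0.975]),
        draws=flat, rhat=r, converged=r < RHAT_THRESHOLD,
        extra={"rate": float(k.sum() / n.sum())},
    )


def fit_rt_model(trials, *, seed: int = 0, walkers: int = 32,
                 warmup: int = 800, draws: int = 600) -> RegressionResult:
    """Mixed-effects linear regression of rt on choice type.

    Fixed intercept and non-Utilitarian-choice effect, participant random
    intercepts and slopes (marginalized in closed form via the Woodbury
    identity, so the sampler only explores the 5 variance/fixed parameters).
    """
    import pandas as pd

    frame = trials if isinstance(trials, pd.DataFrame) else pd.DataFrame(
        [t.__dict__ for t in trials]
    )
    if frame["choice"].nunique() < 2:
        raise ValueError("both choice types must be present to estimate the effect")
    stats = []
    for _, g in frame.groupby("participant_id"):
        y = g["rt"].to_numpy(dtype=float)
        x = (g["choice"] == "N").to_numpy(dtype=float)
        U = np.column_stack([np.ones_like(x), x])
        stats.append((len(y), y @ y, U.T @ y, U.T @ U))
    n_i = np.array([s[0] for s in stats], dtype=float)
    yty = np.array([s[1] for s in stats])
    Uty = np.stack([s[2] for s in stats])          # (P, 2)
    UtU = np.stack([s[3] for s in stats])          # (P, 2, 2)

    def log_post(theta):
        # Woodbury in closed 2x2 form, vectorized over walkers x participants
        theta = np.atleast_2d(theta)
        b0, b1 = theta[:, 0], theta[:, 1]
        ls0, ls1, lse = theta[:, 2], theta[:, 3], theta[:, 4]
        bad = (theta[:, 2:].max(axis=1) > 3) | (theta[:, 2:].min(axis=1) < -8)
        s0sq, s1sq, sesq = np.exp(2 * ls0), np.exp(2 * ls1), np.exp(2 * lse)
        # A = diag(1/s0^2, 1/s1^2) + U'U / se^2, per walker w and participant i
        a11 = 1 / s0sq[:, None] + UtU[None, :, 0, 0] / sesq[:, None]
        a12 = UtU[None, :, 0, 1] / sesq[:, None]
        a22 = 1 / s1sq[:, None] + UtU[None, :, 1, 1] / sesq[:, None]
        detA = a11 * a22 - a12**2
        b = np.stack([b0, b1], axis=1)                       # (W, 2)
        Ub = np.einsum("pij,wj->wpi", UtU, b)                # (W, P, 2)
        Utr = Uty[None, :, :] - Ub
        rtr = (
            yty[None, :]
            - 2 * np.einsum("wj,pj->wp", b, Uty)
            + np.einsum("wi,pij,wj->wp", b, UtU, b)
        )
        # Utr' A^-1 Utr with 2x2 inverse
        q = (
            a22 * Utr[..., 0] ** 2 - 2 * a12 * Utr[..., 0] * Utr[..., 1]
            + a11 * Utr[..., 1] ** 2
        ) / detA
        quad = (rtr - q / sesq[:, None]) / sesq[:, None]
        logdet = (
            n_i[None, :] * 2 * lse[:, None] + np.log(detA)
            + 2 * (ls0 + ls1)[:, None]
        )
        ll = -0.5 * (logdet + quad + n_i[None, :] * np.log(2 * np.pi)).sum(axis=1)
        lp = (
            -0.5 * (b0 / 5) ** 2 - 0.5 * (b1 / 5) ** 2
            - 0.5 * s0sq + ls0 - 0.5 * s1sq + ls1 - 0.5 * sesq / 4 + lse
        )
        out = ll + lp
        out[bad | ~np.isfinite(out)] = -np.inf
        return out

    rng = np.random.default_rng(seed)
    p0 = np.tile([frame["rt"].mean(), 0.0, -1.5, -1.5, np.log(frame["rt"].std() + 1e-3)],
                 (walkers, 1)) + 0.1 * rng.standard_normal((walkers, 5))
    sampler = emcee.EnsembleSampler(walkers, 5, log_post, vectorize=True)
    sampler._random = np.random.RandomState(seed % 2**32)
    state = sampler.run_mcmc(p0, warmup, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, draws, skip_initial_state_check=True)
    chain = sampler.get_chain()[:, :, 1]
    groups = np.array_split(np.arange(walkers), 4)
    r = float(az.rhat(np.stack([chain[:, g].reshape(-1) for g in groups])))
    flat = chain.reshape(-1)
    return RegressionResult(
        coef_median=float(np.median(flat)),
        interval=np.quantile(flat, [0.025, 0.975]),
        draws=flat, rhat=r, converged=r < RHAT_THRESHOLD,
    )
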