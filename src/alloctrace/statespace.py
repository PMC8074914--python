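"""Hierarchical time-varying-coefficient state-space model of cursor position.

The observed, time-normalized cursor x-position at bin t (1..101) for
participant i on trial j is modelled as

    x[t,i,j] = mu[t,i] + bMin[t,i] * Diff_min[j] + bVar[t,i] * Diff_var[j] + eps,

with eps ~ N(0, sd=0.005), participant coefficients scattered around
population series (bMin[t,i] = bMin_pop[t] + etaMin[t,i]), population series
evolving as Gaussian random walks pinned to zero at t = 1, and the
participant intercept mu[t,i] following either a constant per-participant
drift (mu[t,i] = (t-1)*delta_i, the literal reading of the model) or a
per-participant random walk.

Conditional on the handful of sd hyperparameters the model is jointly
linear-Gaussian, so the latent series are marginalized exactly with a Kalman
filter (participant deviations folded into the observation covariance) and
sampled with forward-filter backward-sampling.  Only the sd hyperparameters
are explored by MCMC (affine-invariant ensemble sampler); every retained
hyperparameter draw contributes one exact joint draw of the coefficient
series.  This Rao-Blackwellization is what makes full posterior inference on
~10^3 latent states run in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
from numba import njit
from scipy.optimize import minimize

__all__ = [
    "StateSpaceSpec",
    "CoefficientTrajectories",
    "DepartureReport",
    "simulate_panel",
    "fit_statespace",
    "fit_statespace_with_total",
    "pointwise_hdi",
    "simultaneous_band",
    "departure_times",
]

N_BINS = 101
_LOG2PI = float(np.log(2.0 * np.pi))
RHAT_THRESHOLD = 1.1


class NonStandardizedFeaturesError(ValueError):
    """Predictors must be standardized so coefficient magnitudes are comparable."""


@dataclass
class StateSpaceSpec:
    """Model and sampler settings.

    obs_noise_sd
        Fixed observation sd of the cursor position (analysis coordinates).
        The model's N(., 0.005) is read as a standard deviation.
    mu_dynamics
        "linear_drift": mu[t,i] = (t-1) * delta_i with delta_i ~ N(0, sd_delta)
        (the literal per-participant constant drift); "random_walk": mu[t,i]
        is a participant-level random walk with innovation sd sd_delta.
    deviation_sd_mode
        "shared": one deviation sd per coefficient, shared over bins.  A
        per-bin sd (101 hyperparameters per coefficient) is weakly identified
        and not supported by the marginalized sampler.
    sd_prior_scale
        Half-normal prior scale for every sd hyperparameter (features are
        standardized, so unit scale is weakly informative).
    """

    obs_noise_sd: float = 0.005
    include_total: bool = False
    mu_dynamics: str = "linear_drift"
    deviation_sd_mode: str = "shared"
    sd_prior_scale: float = 1.0
    chains: int = 4
    walkers: int = 16
    warmup: int = 250
    draws: int = 250
    n_state_draws: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.obs_noise_sd <= 0:
            raise ValueError("observation noise scale must be positive")
        if self.chains < 2:
            raise ValueError("R-hat needs at least 2 chains")
        if self.mu_dynamics not in ("linear_drift", "random_walk"):
            raise ValueError(f"unknown mu_dynamics {self.mu_dynamics!r}")
        if self.deviation_sd_mode == "per_time":
            raise NotImplementedError(
                "per-bin deviation sds (101 hyperparameters per coefficient) are "
                "weakly identified and not supported; use 'shared'"
            )
        if self.deviation_sd_mode != "shared":
            raise ValueError(f"unknown deviation_sd_mode {self.deviation_sd_mode!r}")


@dataclass
class CoefficientTrajectories:
    """Posterior of the population coefficient series and its bands."""

    t: np.ndarray                      # 1..101
    coef_names: list[str]              # e.g. ["beta_min", "beta_var"]
    draws: dict[str, np.ndarray]       # name -> (n_draws, 101)
    pointwise: dict[str, np.ndarray]   # name -> (101, 2) HDI bounds
    simultaneous: dict[str, np.ndarray]
    hyper_names: list[str]
    hyper_draws: np.ndarray            # (n_chains, n_draws_per_chain, n_hyper) sds
    delta_draws: np.ndarray            # (n_draws, n_participants)
    participant_means: dict[str, np.ndarray]  # name -> (101, n_participants)
    rhat: dict[str, float]
    converged: bool
    log_posts: np.ndarray
    spec: StateSpaceSpec
    draw_chain_id: np.ndarray = field(default=None)

    def summary_frame(self):
        import pandas as pd

        rows = []
        for name in self.coef_names:
            d = self.draws[name]
            pw, sm = self.pointwise[name], self.simultaneous[name]
            for k in range(len(self.t)):
                rows.append(
                    dict(
                        t=int(self.t[k]),
                        coefficient=name,
                        mean=d[:, k].mean(),
                        hdi_low=pw[k, 0],
                        hdi_high=pw[k, 1],
                        simult_low=sm[k, 0],
                        simult_high=sm[k, 1],
                    )
                )
        return pd.DataFrame(rows)


@dataclass
class DepartureReport:
    """First bins where each coefficient's pointwise HDI excludes zero."""

    departure: dict[str, int | None]
    sign_at_departure: dict[str, int | None]
    per_t_sign: dict[str, np.ndarray]          # -1 / 0 / +1 per bin
    min_exceeds_var: np.ndarray                # bool per bin (difference HDI > 0)


# ---------------------------------------------------------------------------
# forward simulation (the model run generatively)


def simulate_panel(
    features: np.ndarray,
    participant_idx: np.ndarray,
    true_series: dict[str, np.ndarray],
    rng: np.random.Generator,
    *,
    obs_noise_sd: float = 0.005,
    eta_sds: tuple[float, ...] = (0.03, 0.03),
    delta_sd: float = 0.02,
    mu_dynamics: str = "linear_drift",
) -> np.ndarray:
    """Draw a panel of 101-bin x-trajectories from the model itself.

    Parameters
    ----------
    features
        (n_trials, K) standardized predictors (columns match the order of
        ``true_series``).
    participant_idx
        (n_trials,) integer participant of each trial.
    true_series
        Ordered mapping name -> (101,) population coefficient series; each
        must start at exactly 0 (the cursor is pinned at the origin at t=1).

    Returns
    -------
    (n_trials, 101) array; column 0 is exactly 0.
    """
    feats = np.asarray(features, dtype=float)
    pidx = np.asarray(participant_idx)
    n_trials, K = feats.shape
    if len(true_series) != K:
        raise ValueError("one true series per feature column required")
    series = np.column_stack([np.asarray(v, dtype=float) for v in true_series.values()])
    if series.shape[0] != N_BINS:
        raise ValueError(f"true series must have {N_BINS} bins")
    if not np.all(series[0] == 0.0):
        raise ValueError("population coefficients must be exactly 0 at t = 1")
    n_part = int(pidx.max()) + 1

    if mu_dynamics == "linear_drift":
        delta = rng.normal(0.0, delta_sd, size=n_part)
        mu = np.arange(N_BINS)[:, None] * delta[None, :]      # (T, n_part)
    elif mu_dynamics == "random_walk":
        steps = rng.normal(0.0, delta_sd, size=(N_BINS - 1, n_part))
        mu = np.vstack([np.zeros(n_part), np.cumsum(steps, axis=0)])
    else:
        raise ValueError(f"unknown mu_dynamics {mu_dynamics!r}")

    # participant coefficient deviations, iid over bins, zero at t = 1
    eta = np.zeros((N_BINS, n_part, K))
    for k in range(K):
        eta[1:, :, k] = rng.normal(0.0, eta_sds[k], size=(N_BINS - 1, n_part))

    coef = series[:, None, :] + eta                            # (T, n_part, K)
    x = mu[:, pidx] + np.einsum("tjk,jk->tj", coef[:, pidx, :], feats)
    x[1:] += rng.normal(0.0, obs_noise_sd, size=(N_BINS - 1, n_trials))
    x[0] = 0.0
    return x.T.copy()


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _kf_pass(yw, Dw, cw, pidx, n_part, qz, vd, drift_mode, store, A, Pf):
    n_rows, T = yw.shape
    K = Dw.shape[1]
    n = K + n_part
    a = np.zeros(n)
    P = np.zeros((n, n))
    for k in range(K):
        P[k, k] = qz[k]
    for i in range(n_part):
        P[K + i, K + i] = vd
    ll = 0.0
    Ph = np.zeros(n)
    for t in range(1, T):
        if t > 1:
            for k in range(K):
                P[k, k] += qz[k]
            if not drift_mode:
                for i in range(n_part):
                    P[K + i, K + i] += vd
        for r in range(n_rows):
            i = pidx[r]
            cc = cw[r] * t if drift_mode else cw[r]
            for m in range(n):
                s = 0.0
                for k in range(K):
                    s += P[m, k] * Dw[r, k]
                s += P[m, K + i] * cc
                Ph[m] = s
            S = 1.0
            for k in range(K):
                S += Dw[r, k] * Ph[k]
            S += cc * Ph[K + i]
            mean = 0.0
            for k in range(K):
                mean += a[k] * Dw[r, k]
            mean += a[K + i] * cc
            v = yw[r, t] - mean
            ll += -0.5 * (_LOG2PI + np.log(S) + v * v / S)
            inv = v / S
            for m in range(n):
                a[m] += Ph[m] * inv
            for m in range(n):
                pm = Ph[m] / S
                for m2 in range(n):
                    P[m, m2] -= pm * Ph[m2]
        if store:
            for m in range(n):
                A[t, m] = a[m]
                for m2 in range(n):
                    Pf[t, m, m2] = P[m, m2]
    return ll


@njit(cache=True)
def _chol_jitter(M):
    n = M.shape[0]
    jitter = 0.0
    scale = 0.0
    for i in range(n):
        scale += M[i, i]
    scale = max(scale / n, 1e-300)
    for _ in range(8):
        ok = True
        A = M.copy()
        for i in range(n):
            A[i, i] += jitter
        L = np.zeros_like(A)
        for i in range(n):
            for j in range(i + 1):
                s = A[i, j]
                for k in range(j):
                    s -= L[i, k] * L[j, k]
                if i == j:
                    if s <= 0.0:
                        ok = False
                        break
                    L[i, i] = np.sqrt(s)
                else:
                    L[i, j] = s / L[j, j]
            if not ok:
                break
        if ok:
            return L
        jitter = max(jitter * 10.0, scale * 1e-12)
    return L


@njit(cache=True)
def _ffbs(A, Pf, q, normals):
    """One backward-sampling pass given filtered moments.

    A, Pf: filtered mean/cov for t = 1..T-1 (index 0 unused, state is exactly
    zero there).  q: diagonal of the transition innovation covariance.
    normals: (T, n) standard normals.  Returns (T, n) state draw.
    """
    T, n = A.shape
    out = np.zeros((T, n))
    L = _chol_jitter(Pf[T - 1])
    for m in range(n):
        s = A[T - 1, m]
        for k in range(m + 1):
            s += L[m, k] * normals[T - 1, k]
        out[T - 1, m] = s
    for t in range(T - 2, 0, -1):
        # s_t | s_{t+1} ~ N(a + P (P+Q)^-1 (s_{t+1} - a), P - P (P+Q)^-1 P)
        PQ = Pf[t].copy()
        for m in range(n):
            PQ[m, m] += q[m] + 1e-14
        G = np.linalg.solve(PQ, Pf[t]).T       # P (P+Q)^-1
        diff = out[t + 1] - A[t]
        mean = A[t] + G @ diff
        cov = Pf[t] - G @ Pf[t]
        cov = 0.5 * (cov + cov.T)
        L = _chol_jitter(cov)
        for m in range(n):
            s = mean[m]
            for k in range(m + 1):
                s += L[m, k] * normals[t, k]
            out[t, m] = s
    return out


# ---------------------------------------------------------------------------
# fitting


def _check_standardized(feats: np.ndarray) -> None:
    mu = feats.mean(axis=0)
    var = feats.var(axis=0)
    if np.any(np.abs(mu) > 1e-6) or np.any(np.abs(var - 1.0) > 1e-3):
        raise NonStandardizedFeaturesError(
            "predictors must be standardized (mean 0, variance 1) so that "
            "coefficient magnitudes are comparable"
        )


class _MarginalModel:
    """Whitening + Kalman marginal likelihood for fixed data."""

    def __init__(self, x, participant_idx, feats, spec: StateSpaceSpec):
        self.spec = spec
        self.K = feats.shape[1]
        pidx = np.asarray(participant_idx)
        parts = np.unique(pidx)
        self.n_part = len(parts)
        self.remap = {p: i for i, p in enumerate(parts)}
        # per-participant blocks (trials of one participant share deviation draws)
        self.blocks = []
        for p in parts:
            sel = np.where(pidx == p)[0]
            self.blocks.append((feats[sel], x[sel]))   # (J,K), (J,T)
        self.drift = spec.mu_dynamics == "linear_drift"

    def _whiten(self, eta_sds):
        from scipy.linalg import cho_factor, solve_triangular

        obs2 = self.spec.obs_noise_sd ** 2
        Dw_rows, cw_rows, yw_rows, pidx_rows = [], [], [], []
        logdet = 0.0
        T = self.blocks[0][1].shape[1]
        for i, (D, y) in enumerate(self.blocks):
            J = D.shape[0]
            R = D @ np.diag(eta_sds ** 2) @ D.T + obs2 * np.eye(J)
            L = np.linalg.cholesky(R)
            logdet += np.log(np.diag(L)).sum()
            Dw_rows.append(solve_triangular(L, D, lower=True))
            cw_rows.append(solve_triangular(L, np.ones(J), lower=True))
            yw_rows.append(solve_triangular(L, y, lower=True))
            pidx_rows.append(np.full(J, i, dtype=np.int64))
        return (
            np.concatenate(yw_rows, axis=0),
            np.concatenate(Dw_rows, axis=0),
            np.concatenate(cw_rows),
            np.concatenate(pidx_rows),
            (T - 1) * logdet,
        )

    def unpack(self, log_sds):
        sds = np.exp(log_sds)
        delta_sd = sds[0]
        eta_sds = sds[1 : 1 + self.K]
        zeta_sds = sds[1 + self.K :]
        return delta_sd, eta_sds, zeta_sds

    def log_prior(self, log_sds):
        sds = np.exp(log_sds)
        scale = self.spec.sd_prior_scale
        # half-normal on sd plus log-Jacobian of the log transform
        return float(np.sum(-0.5 * (sds / scale) ** 2 + log_sds))

    def log_post(self, log_sds, store=False):
        if np.any(log_sds > 4.0) or np.any(log_sds < -14.0):
            return -np.inf, None
        delta_sd, eta_sds, zeta_sds = self.unpack(log_sds)
        yw, Dw, cw, pidx, logdet = self._whiten(eta_sds)
        n = self.K + self.n_part
        T = yw.shape[1]
        if store:
            A = np.zeros((T, n))
            Pf = np.zeros((T, n, n))
        else:
            A = np.zeros((1, 1))
            Pf = np.zeros((1, 1, 1))
        ll = _kf_pass(
            yw, Dw, cw, pidx, self.n_part,
            zeta_sds ** 2, delta_sd ** 2, self.drift, store, A, Pf,
        )
        lp = self.log_prior(log_sds) + ll - logdet
        if store:
            return lp, (A, Pf)
        return lp, None

    def q_diag(self, log_sds):
        delta_sd, _, zeta_sds = self.unpack(log_sds)
        q = np.zeros(self.K + self.n_part)
        q[: self.K] = zeta_sds ** 2
        if not self.drift:
            q[self.K :] = delta_sd ** 2
        return q


def fit_statespace(
    x: np.ndarray,
    participant_idx: np.ndarray,
    features: np.ndarray,
    spec: StateSpaceSpec | None = None,
    *,
    coef_names: list[str] | None = None,
) -> CoefficientTrajectories:
    """Fit the time-varying-coefficient model to a panel of trajectories.

    Parameters
    ----------
    x
        (n_trials, 101) time-normalized, side-inverted x-positions.
    participant_idx
        (n_trials,) participant of each trial (any hashable labels).
    features
        (n_trials, K) standardized predictors per trial (K = 2, or 3 when a
        total covariate is included).
    """
    spec = spec or StateSpaceSpec()
    x = np.asarray(x, dtype=float)
    feats = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_BINS:
        raise ValueError(f"each trajectory must have exactly {N_BINS} bins")
    if np.any(np.abs(x[:, 0]) > 1e-9):
        raise ValueError("bin 1 must be exactly 0 (the cursor starts at the origin)")
    # standardization is checked on the problem-level design, not per trial:
    # repeated problems repeat feature rows, so reduce to unique rows first
    uniq = np.unique(np.round(feats, 12), axis=0)
    _check_standardized(uniq if len(uniq) >= 3 else feats)
    K = feats.shape[1]
    if coef_names is None:
        coef_names = ["beta_min", "beta_var", "beta_total"][:K]
    if len(coef_names) != K:
        raise ValueError("one coefficient name per feature column")

    model = _MarginalModel(x, participant_idx, feats, spec)
    rng = np.random.default_rng(spec.seed)
    ndim = 1 + 2 * K

    def neg(ls):
        lp, _ = model.log_post(ls)
        return -lp if np.isfinite(lp) else 1e12

    x0 = np.log(np.full(ndim, 0.05))
    opt = minimize(neg, x0, method="Nelder-Mead",
                   options=dict(maxfev=400, xatol=1e-3, fatol=1e-2))
    center = opt.x if np.isfinite(opt.fun) else x0

    nwalkers = max(spec.walkers, 2 * ndim + 2)
    nwalkers += (-nwalkers) % spec.chains      # equal pseudo-chain sizes
    p0 = center[None, :] + 0.15 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, lambda ls: model.log_post(ls)[0],
        moves=[(emcee.moves.DEMove(), 0.7), (emcee.moves.DESnookerMove(), 0.3)],
    )
    sampler._random = np.random.RandomState(spec.seed % 2**32)  # reproducible runs
    state = sampler.run_mcmc(p0, spec.warmup, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, spec.draws, skip_initial_state_check=True)
    chain = sampler.get_chain()                     # (draws, walkers, ndim)
    logps = sampler.get_log_prob()

    hyper_names = (
        ["sd_delta"]
        + [f"sd_eta_{c.removeprefix('beta_')}" for c in coef_names]
        + [f"sd_zeta_{c.removeprefix('beta_')}" for c in coef_names]
    )
    sd_chain = np.exp(chain)

    # hyperparameter R-hat: walkers grouped into spec.chains pseudo-chains
    groups = np.array_split(np.arange(nwalkers), spec.chains)
    rhat: dict[str, float] = {}
    for k, name in enumerate(hyper_names):
        per_chain = np.stack([sd_chain[:, g, k].reshape(-1) for g in groups])
        rhat[name] = float(az.rhat(per_chain))

    # thin hyper draws and draw one state trajectory per retained draw
    total = spec.draws * nwalkers
    M = min(spec.n_state_draws, total)
    flat = chain.reshape(-1, ndim)                       # draw-major
    walker_of = np.tile(np.arange(nwalkers), spec.draws)
    keep = np.linspace(0, total - 1, M).astype(int)

    n_state = K + model.n_part
    series_draws = np.zeros((M, K, N_BINS))
    delta_draws = np.zeros((M, model.n_part))
    rw = spec.mu_dynamics == "random_walk"
    mu_draws = np.zeros((M, N_BINS, model.n_part)) if rw else None
    draw_chain_id = np.zeros(M, dtype=int)
    chain_of_walker = np.zeros(nwalkers, dtype=int)
    for ci, g in enumerate(groups):
        chain_of_walker[g] = ci
    for m, idx in enumerate(keep):
        ls = flat[idx]
        _, moments = model.log_post(ls, store=True)
        A, Pf = moments
        normals = rng.standard_normal((N_BINS, n_state))
        s = _ffbs(A, Pf, model.q_diag(ls), normals)
        series_draws[m] = s[:, :K].T
        if rw:
            mu_draws[m] = s[:, K:]
            delta_draws[m] = s[-1, K:]
        else:
            delta_draws[m] = s[1, K:]
        draw_chain_id[m] = chain_of_walker[walker_of[idx]]

    draws = {name: series_draws[:, k, :] for k, name in enumerate(coef_names)}

    # series R-hat from the pseudo-chain labels of each draw
    for name in coef_names:
        worst = 1.0
        for t in range(1, N_BINS):
            per_chain = [draws[name][draw_chain_id == ci, t] for ci in range(spec.chains)]
            nmin = min(len(p) for p in per_chain)
            if nmin < 4:
                continue
            arr = np.stack([p[:nmin] for p in per_chain])
            r = float(az.rhat(arr))
            if np.isfinite(r):
                worst = max(worst, r)
        rhat[name] = worst

    converged = all(v < RHAT_THRESHOLD for v in rhat.values() if np.isfinite(v))
    if not converged:
        warnings.warn(
            "state-space fit flagged non-converged: max R-hat "
            f"{max(rhat.values()):.3f} >= {RHAT_THRESHOLD}", stacklevel=2,
        )

    pointwise = {n: pointwise_hdi(draws[n]) for n in coef_names}
    simultaneous = {n: simultaneous_band(draws[n]) for n in coef_names}
    # enforce nesting of the pointwise interval inside the simultaneous band
    for n in coef_names:
        simultaneous[n][:, 0] = np.minimum(simultaneous[n][:, 0], pointwise[n][:, 0])
        simultaneous[n][:, 1] = np.maximum(simultaneous[n][:, 1], pointwise[n][:, 1])

    participant_means = _participant_series_means(
        model, flat[keep], series_draws, delta_draws, mu_draws,
        x, participant_idx, feats, spec,
    )

    hyper_grouped = np.stack(
        [sd_chain[:, g, :].reshape(-1, ndim) for g in groups]
    )
    return CoefficientTrajectories(
        t=np.arange(1, N_BINS + 1),
        coef_names=coef_names,
        draws=draws,
        pointwise=pointwise,
        simultaneous=simultaneous,
        hyper_names=hyper_names,
        hyper_draws=hyper_grouped,
        delta_draws=delta_draws,
        participant_means=participant_means,
        rhat=rhat,
        converged=converged,
        log_posts=logps.reshape(-1),
        spec=spec,
        draw_chain_id=draw_chain_id,
    )


def _participant_series_means(model, log_sd_draws, series_draws, delta_draws,
                              mu_draws, x, participant_idx, feats, spec):
    """Posterior-mean participant coefficient series (population + deviation)."""
    K = model.K
    obs2 = spec.obs_noise_sd ** 2
    pidx = np.asarray(participant_idx)
    parts = np.unique(pidx)
    means = {n: np.zeros((N_BINS, model.n_part)) for n in
             ["beta_min", "beta_var", "beta_total"][:K]}
    names = list(means)
    M = len(log_sd_draws)
    for i, p in enumerate(parts):
        sel = pidx == p
        D = feats[sel]                       # (J, K)
        y = x[sel]                           # (J, T)
        DtD = D.T @ D
        acc = np.zeros((N_BINS, K))
        for m in range(M):
            _, eta_sds, _ = model.unpack(log_sd_draws[m])
            b = series_draws[m]              # (K, T)
            if spec.mu_dynamics == "linear_drift":
                mu = np.arange(N_BINS) * delta_draws[m, i]
            else:
                mu = mu_draws[m, :, i]
            resid = y - mu[None, :] - D @ b  # (J, T)
            V = np.linalg.inv(DtD / obs2 + np.diag(1.0 / np.maximum(eta_sds ** 2, 1e-300)))
            eta_mean = V @ (D.T @ resid) / obs2        # (K, T)
            acc += (b + eta_mean).T
        for k, n in enumerate(names):
            means[n][:, i] = acc[:, k] / M
        means[names[0]][0, i] = 0.0
    for n in names:
        means[n][0, :] = 0.0
    return means


def fit_statespace_with_total(x, participant_idx, features3, spec=None):
    """Three-covariate variant: min, variance (Gini) and total difference."""
    spec = spec or StateSpaceSpec(include_total=True)
    feats = np.asarray(features3, dtype=float)
    if feats.shape[1] != 3:
        raise ValueError("expected 3 feature columns (min, var, total)")
    spec.include_total = True
    return fit_statespace(
        x, participant_idx, feats, spec,
        coef_names=["beta_min", "beta_var", "beta_total"],
    )


# ---------------------------------------------------------------------------
# posterior bands and departures


def pointwise_hdi(draws: np.ndarray, mass: float = 0.95) -> np.ndarray:
    """Narrowest interval containing `mass` posterior probability per bin.

    draws: (n_draws,) or (n_draws, T); returns (2,) or (T, 2).
    """
    draws = np.asarray(draws, dtype=float)
    single = draws.ndim == 1
    if single:
        draws = draws[:, None]
    M, T = draws.shape
    out = np.empty((T, 2))
    n_keep = max(int(np.ceil(mass * M)), 1)
    srt = np.sort(draws, axis=0)
    span = srt[n_keep - 1 :, :] - srt[: M - n_keep + 1, :]
    lo_idx = np.argmin(span, axis=0)
    out[:, 0] = srt[lo_idx, np.arange(T)]
    out[:, 1] = srt[lo_idx + n_keep - 1, np.arange(T)]
    return out[0] if single else out


def simultaneous_band(draws: np.ndarray, mass: float = 0.95) -> np.ndarray:
    """Band with joint coverage >= mass over all bins.

    Pointwise posterior sds are scaled by the `mass` quantile of the per-draw
    maximum standardized deviation across bins.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[:, None]
    M, T = draws.shape
    if T == 1:
        return pointwise_hdi(draws[:, 0])[None, :]
    m = draws.mean(axis=0)
    s = draws.std(axis=0)
    s_safe = np.where(s > 0, s, 1.0)
    dev = np.abs(draws - m) / s_safe
    dev[:, s == 0] = 0.0
    cmax = np.max(dev, axis=1)
    q = np.quantile(cmax, mass)
    return np.column_stack([m - q * s, m + q * s])


def departure_times(ct: CoefficientTrajectories, mass: float = 0.95) -> DepartureReport:
    """First bin per coefficient whose pointwise HDI excludes zero."""
    departure: dict[str, int | None] = {}
    sign_at: dict[str, int | None] = {}
    per_t_sign: dict[str, np.ndarray] = {}
    for name in ct.coef_names:
        hdi = ct.pointwise[name]
        sign = np.zeros(N_BINS, dtype=int)
        sign[hdi[:, 0] > 0] = 1
        sign[hdi[:, 1] < 0] = -1
        sign[0] = 0
        per_t_sign[name] = sign
        nz = np.nonzero(sign[1:])[0]
        if len(nz):
            t_dep = int(nz[0] + 2)           # bins are 1-based
            departure[name] = t_dep
            sign_at[name] = int(sign[t_dep - 1])
        else:
            departure[name] = None
            sign_at[name] = None
    if {"beta_min", "beta_var"} <= set(ct.coef_names):
        diff = ct.draws["beta_min"] - ct.draws["beta_var"]
        dh = pointwise_hdi(diff, mass)
        exceeds = dh[:, 0] > 0
        exceeds[0] = False
    else:
        exceeds = np.zeros(N_BINS, dtype=bool)
    return DepartureReport(
        departure=departure,
        sign_at_departure=sign_at,
        per_t_sign=per_t_sign,
        min_exceeds_var=exceeds,
    )
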