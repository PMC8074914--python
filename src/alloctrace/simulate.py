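"""Synthetic third-party allocation experiments.

Emulates the study design end to end: 36 participants x 48 choice problems,
each problem opposing a Utilitarian option (larger total) to a
non-Utilitarian option (higher minimum, lower Gini), with a moderate
correlation (~0.49) between the |Delta min| and |Delta Gini| predictors
across problems; choices from quasi-maximin agents through a logistic choice
rule (~73% non-Utilitarian overall); log-normal response times around 2 s;
and 60 Hz cursor trajectories generated from the same time-varying
coefficient process the state-space module fits.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .allocations import (
    Allocation,
    ChoiceProblem,
    ProblemFeatures,
    compute_features,
    feature_correlation,
)
from . import statespace as ss

__all__ = [
    "SimulationConfig",
    "TrialRecord",
    "RawTrajectory",
    "ScreenGeometry",
    "GenerationFailure",
    "generate_problems",
    "simulate_choices",
    "simulate_trajectories",
    "simulate_experiment",
    "default_true_series",
    "trials_frame",
    "trajectories_frame",
]

MIN_PROBLEMS_FOR_CORRELATION = 5


class GenerationFailure(RuntimeError):
    """Rejection budget exhausted while generating a problem set."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Anchor pixels of the task screen (1920 x 1080, y grows downward)."""

    start: tuple[float, float] = (960.0, 940.0)
    left_target: tuple[float, float] = (260.0, 140.0)
    right_target: tuple[float, float] = (1660.0, 140.0)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic experiment.

    Defaults mirror the experimental design being emulated: 36 participants,
    48 problems, 60 Hz cursor sampling, predictor correlation targeted at
    0.49, quasi-maximin agents whose concern for the minimum averages 0.85
    (yielding roughly 73% non-Utilitarian choices), and response times with
    median ~1.8 s (mean ~2 s).  Trajectory-process parameters are the true
    values of the state-space model run generatively.
    """

    n_participants: int = 36
    n_problems: int = 48
    sampling_rate_hz: float = 60.0
    target_feature_correlation: float = 0.49
    correlation_tolerance: float = 0.1
    agent_model: str = "quasi_maximin"
    alpha_mean: float = 0.85
    alpha_sd: float = 0.10
    beta_mean: float = 1.0
    beta_sd: float = 0.5
    tau_log_mean: float = 0.0        # inverse temperature ~ LogNormal(mu, sigma)
    tau_log_sd: float = 0.5
    rt_median_s: float = 1.8
    rt_log_sd: float = 0.45
    rt_choice_effect_s: float = 0.0  # added to U-choice rts (0 = null, as observed)
    # trajectory process (true values of the state-space model)
    traj_obs_noise_sd: float = 0.005
    traj_delta_sd: float = 0.02
    traj_eta_min_sd: float = 0.03
    traj_eta_var_sd: float = 0.03
    traj_mu_dynamics: str = "linear_drift"
    true_beta_min_amp: float = 0.12
    true_beta_var_amp: float = 0.04
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_problems < 2:
            raise ValueError("need >= 1 participant and >= 2 problems")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        for name in ("alpha_sd", "beta_sd", "tau_log_sd", "rt_log_sd",
                     "traj_delta_sd", "traj_eta_min_sd", "traj_eta_var_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            g = {k: tuple(v) for k, v in d["geometry"].items()}
            d["geometry"] = ScreenGeometry(**g)
        return cls(**d)


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    problem_id: str
    trial_index: int
    side_of_non_utilitarian: str     # "left" | "right"
    choice: str                      # "U" | "N"
    rt: float                        # seconds

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("response time must be positive")
        if self.choice not in ("U", "N"):
            raise ValueError(f"choice must be U or N, got {self.choice!r}")
        if self.side_of_non_utilitarian not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass(frozen=True)
class RawTrajectory:
    participant_id: str
    trial_index: int
    samples: np.ndarray              # (n, 3): t_ms, x_px, y_px
    geometry: ScreenGeometry

    def __post_init__(self) -> None:
        t = self.samples[:, 0]
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("need >= 2 samples with strictly increasing timestamps")


# ---------------------------------------------------------------------------
# choice problems


def _round10(v):
    return np.round(np.asarray(v) / 10.0) * 10.0


def _draw_problem(rng: np.random.Generator, pid: str) -> ChoiceProblem | None:
    """One attempt at a problem.

    The non-Utilitarian option is drawn first (high minimum, modest spread);
    the Utilitarian option then takes a lower minimum (|Delta min| in the
    low hundreds of yen, matching the task's magnitudes), a larger total,
    and a Gini coefficient targeted at an independently drawn offset above
    the non-Utilitarian one — clipped into the band attainable for a
    3-recipient allocation with that minimum and mean.  The clipping leaves
    a moderate positive correlation between |Delta min| and |Delta Gini|,
    the same ecological coupling the design aims for; no explicit coupling
    is needed to land near the 0.49 target.
    """
    z = rng.standard_normal()
    min_n = _round10(rng.uniform(450, 750))
    range_n = _round10(rng.uniform(30, 320))
    frac = rng.uniform(0.25, 0.75)
    n_opt = (min_n, _round10(min_n + frac * range_n), min_n + range_n)
    total_n = float(sum(n_opt))
    gini_n = 2.0 * range_n / (3.0 * total_n)

    d = float(np.clip(_round10(170 + 90 * z), 30, 420))    # |Delta min|
    min_u = min_n - d
    if min_u < 10:
        return None
    total_u = float(_round10(total_n + rng.uniform(120, 520)))
    mu_u = total_u / 3.0
    k = min_u / mu_u
    if k >= 1.0:
        return None
    # Gini of a 3-recipient allocation with minimum min_u and mean mu_u can
    # only lie in [(1-k)/3, 2(1-k)/3] (pay-offs sorted, middle between ends)
    lo, hi = (1.0 - k) / 3.0, 2.0 * (1.0 - k) / 3.0
    g_lo = max(0.015, lo - gini_n + 0.005)
    g_hi = hi - gini_n - 0.005
    if g_hi <= g_lo:
        return None
    g_diff = float(np.clip(0.13 + 0.08 * rng.standard_normal(), g_lo, g_hi))
    range_u = _round10((gini_n + g_diff) * 4.5 * mu_u)
    high_u = min_u + range_u
    med_u = total_u - min_u - high_u
    if not (min_u <= med_u <= high_u):
        return None
    try:
        return ChoiceProblem(
            problem_id=pid,
            utilitarian=Allocation((min_u, med_u, high_u)),
            non_utilitarian=Allocation(n_opt),
        )
    except ValueError:
        return None


def generate_problems(
    config: SimulationConfig, rng: np.random.Generator,
    *, max_set_attempts: int = 400, max_problem_attempts: int = 200,
) -> list[ChoiceProblem]:
    """Rejection-sample a problem set with the target predictor correlation.

    Every problem satisfies the dominance invariants by construction (checked
    by ChoiceProblem).  For sets of >= 5 problems, whole sets are redrawn
    until the realized Pearson r between |Delta min| and |Delta Gini| falls
    within ``correlation_tolerance`` of ``target_feature_correlation``;
    below 5 problems the correlation is too unstable to constrain and the
    check is skipped.
    """
    check_corr = config.n_problems >= MIN_PROBLEMS_FOR_CORRELATION
    for _ in range(max_set_attempts):
        problems: list[ChoiceProblem] = []
        for k in range(config.n_problems):
            for _ in range(max_problem_attempts):
                p = _draw_problem(rng, f"p{k + 1:02d}")
                if p is not None:
                    problems.append(p)
                    break
            else:
                raise GenerationFailure(
                    "could not draw a valid problem (dominance invariants "
                    "unsatisfiable under the configured pay-off ranges)"
                )
        if not check_corr:
            return problems
        r = feature_correlation(compute_features(problems))
        if abs(r - config.target_feature_correlation) <= config.correlation_tolerance:
            return problems
    raise GenerationFailure(
        f"no problem set reached r within +/-{config.correlation_tolerance} of "
        f"{config.target_feature_correlation} in {max_set_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# choices and response times


def _scaled_option_utilities(problem: ChoiceProblem, model: str, param: float):
    """Utilities of (U, N) in 100-yen units under the agent's model."""
    from .choicemodels import utility_mean_variance, utility_quasi_maximin

    if model == "quasi_maximin":
        return tuple(
            utility_quasi_maximin(o, param) / 100.0
            for o in (problem.utilitarian, problem.non_utilitarian)
        )
    if model == "mean_variance":
        # beta is expressed on the 100-yen scale (variance / 1e4)
        return tuple(
            utility_mean_variance(o, param / 100.0) / 100.0
            for o in (problem.utilitarian, problem.non_utilitarian)
        )
    raise ValueError(f"unknown agent model {model!r}")


def simulate_choices(
    problems: list[ChoiceProblem], config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[TrialRecord], dict]:
    """Simulate every participant choosing on every problem once.

    Agents draw (alpha or beta, tau) from the configured population
    distributions and choose the non-Utilitarian option with probability
    expit(tau * (U_N - U_U)) on 100-yen-scaled utilities.  Presentation
    order and side assignment are randomized per participant; response
    times are log-normal.  Returns the trials and the truth record of the
    drawn agent parameters.
    """
    from scipy.special import expit

    trials: list[TrialRecord] = []
    truth: dict = {"agent_model": config.agent_model, "participants": {}}
    min_rt = 2.0 / config.sampling_rate_hz
    for i in range(config.n_participants):
        pid = f"s{i + 1:02d}"
        if config.agent_model == "quasi_maximin":
            param = float(np.clip(rng.normal(config.alpha_mean, config.alpha_sd), 0.0, 1.0))
        else:
            param = float(rng.normal(config.beta_mean, config.beta_sd))
        tau = float(np.exp(rng.normal(config.tau_log_mean, config.tau_log_sd)))
        truth["participants"][pid] = {"param": param, "tau": tau}
        order = rng.permutation(len(problems))
        for t_idx, j in enumerate(order):
            prob = problems[j]
            u_u, u_n = _scaled_option_utilities(prob, config.agent_model, param)
            p_n = expit(tau * (u_n - u_u))
            choice = "N" if rng.random() < p_n else "U"
            rt = float(np.exp(rng.normal(np.log(config.rt_median_s), config.rt_log_sd)))
            if choice == "U":
                rt += config.rt_choice_effect_s
            rt = max(rt, min_rt * 1.5)
            side = "left" if rng.random() < 0.5 else "right"
            trials.append(
                TrialRecord(
                    participant_id=pid, problem_id=prob.problem_id,
                    trial_index=t_idx, side_of_non_utilitarian=side,
                    choice=choice, rt=rt,
                )
            )
    return trials, truth


# ---------------------------------------------------------------------------
# trajectories


def default_true_series(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Smooth population coefficient series pinned to 0 at t = 1.

    The minimum-difference series ramps up earlier and higher than the
    variance series, the qualitative pattern the analysis is designed to
    detect.
    """
    u = np.linspace(0.0, 1.0, ss.N_BINS)
    return {
        "beta_min": config.true_beta_min_amp * u ** 1.2,
        "beta_var": config.true_beta_var_amp * u ** 2.0,
    }


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def analysis_to_pixels(xy: np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    """Affine map from analysis coordinates to pixels.

    (0,0) -> start anchor, (-1,1) -> left target, (1,1) -> right target.
    """
    s = np.asarray(geometry.start)
    left = np.asarray(geometry.left_target)
    right = np.asarray(geometry.right_target)
    ex = (right - left) / 2.0
    ey = (right + left) / 2.0 - s
    return s + np.outer(xy[:, 0], ex) + np.outer(xy[:, 1], ey)


def simulate_trajectories(
    trials: list[TrialRecord],
    features: list[ProblemFeatures],
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    true_series: dict[str, np.ndarray] | None = None,
) -> tuple[list[RawTrajectory], dict]:
    """60 Hz raw cursor paths generated from the coefficient process.

    Each trial's 101-step latent x-path (analysis coordinates, positive
    toward the non-Utilitarian option) is the sum of a smooth baseline ramp
    toward the chosen side and the state-space process evaluated with the
    configured true coefficient series; endpoints are pinned exactly to
    (0,0) and the chosen side's target, y rises monotonically from 0 to 1.
    The path is mapped to pixels (un-inverting x onto the actual screen
    side) and resampled onto the 60 Hz clock over the trial's response time.
    """
    if true_series is None:
        true_series = default_true_series(config)
    feat_by_id = {f.problem_id: f for f in features}
    pids = sorted({t.participant_id for t in trials})
    pmap = {p: i for i, p in enumerate(pids)}
    feats = np.array(
        [[feat_by_id[t.problem_id].z_diff_min, feat_by_id[t.problem_id].z_diff_var]
         for t in trials]
    )
    pidx = np.array([pmap[t.participant_id] for t in trials])
    panel = ss.simulate_panel(
        feats, pidx, true_series, rng,
        obs_noise_sd=config.traj_obs_noise_sd,
        eta_sds=(config.traj_eta_min_sd, config.traj_eta_var_sd),
        delta_sd=config.traj_delta_sd,
        mu_dynamics=config.traj_mu_dynamics,
    )
    u = np.linspace(0.0, 1.0, ss.N_BINS)
    y_path = _smoothstep(u)
    ramp = _smoothstep(u)
    min_rt = 2.0 / config.sampling_rate_hz

    raws: list[RawTrajectory] = []
    for row, trial in enumerate(trials):
        if trial.rt < min_rt:
            raise ValueError(
                f"rt {trial.rt:.3f}s too short for 2 samples at "
                f"{config.sampling_rate_hz} Hz"
            )
        target = 1.0 if trial.choice == "N" else -1.0
        x = target * ramp + panel[row]
        x[0], x[-1] = 0.0, target
        flip = 1.0 if trial.side_of_non_utilitarian == "right" else -1.0
        screen = np.column_stack([flip * x, y_path])
        px = analysis_to_pixels(screen, config.geometry)
        t_path = np.linspace(0.0, trial.rt, ss.N_BINS)
        t_clock = np.arange(0.0, trial.rt, 1.0 / config.sampling_rate_hz)
        if t_clock[-1] < trial.rt:
            t_clock = np.append(t_clock, trial.rt)
        samples = np.column_stack(
            [
                t_clock * 1000.0,
                np.interp(t_clock, t_path, px[:, 0]),
                np.interp(t_clock, t_path, px[:, 1]),
            ]
        )
        raws.append(
            RawTrajectory(
                participant_id=trial.participant_id,
                trial_index=trial.trial_index,
                samples=samples,
                geometry=config.geometry,
            )
        )
    truth = {
        "true_series": {k: v.tolist() for k, v in true_series.items()},
        "obs_noise_sd": config.traj_obs_noise_sd,
        "delta_sd": config.traj_delta_sd,
        "eta_sds": [config.traj_eta_min_sd, config.traj_eta_var_sd],
        "mu_dynamics": config.traj_mu_dynamics,
    }
    return raws, truth


def simulate_experiment(config: SimulationConfig, seed: int | None = None):
    """Full synthetic experiment: problems, features, trials, trajectories.

    Returns (problems, features, trials, raw_trajectories, truth).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    problems = generate_problems(config, rng)
    features = compute_features(problems)
    trials, agent_truth = simulate_choices(problems, config, rng)
    raws, traj_truth = simulate_trajectories(trials, features, config, rng)
    truth = {
        "seed": seed,
        "feature_correlation": feature_correlation(features),
        "agents": agent_truth,
        "trajectories": traj_truth,
    }
    return problems, features, trials, raws, truth


# ---------------------------------------------------------------------------
# tabular round-trips


def trials_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in trials])


def trials_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            participant_id=str(r.participant_id), problem_id=str(r.problem_id),
            trial_index=int(r.trial_index),
            side_of_non_utilitarian=str(r.side_of_non_utilitarian),
            choice=str(r.choice), rt=float(r.rt),
        )
        for r in frame.itertuples()
    ]


def trajectories_frame(raws: list[RawTrajectory]) -> pd.DataFrame:
    parts = []
    for raw in raws:
        df = pd.DataFrame(raw.samples, columns=["t_ms", "x_px", "y_px"])
        df.insert(0, "trial_index", raw.trial_index)
        df.insert(0, "participant_id", raw.participant_id)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def trajectories_from_frame(
    frame: pd.DataFrame, geometry: ScreenGeometry
) -> list[RawTrajectory]:
    out = []
    for (pid, tix), grp in frame.groupby(["participant_id", "trial_index"], sort=False):
        out.append(
            RawTrajectory(
                participant_id=str(pid), trial_index=int(tix),
                samples=grp[["t_ms", "x_px", "y_px"]].to_numpy(dtype=float),
                geometry=geometry,
            )
        )
    return out
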