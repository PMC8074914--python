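import warnings

import numpy as np
import pytest

import alloctrace as at
from alloctrace import statespace as ss

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_experiment():
    """One 8-participant x 12-problem synthetic experiment (seed 11)."""
    cfg = at.SimulationConfig(n_participants=8, n_problems=12, seed=11)
    problems, features, trials, raws, truth = at.simulate_experiment(cfg, seed=11)
    return cfg, problems, features, trials, raws, truth


@pytest.fixture(scope="session")
def default_problems():
    """A full 48-problem set at the default study conditions (seed 1)."""
    cfg = at.SimulationConfig(seed=1)
    rng = np.random.default_rng(1)
    problems = at.generate_problems(cfg, rng)
    return cfg, problems


def make_panel(seed, series_kind, n_part=10, n_prob=16):
    """Standardized features + model-generated 101-bin panel."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_prob, 2))
    fp = (raw - raw.mean(0)) / raw.std(0)
    pidx = np.repeat(np.arange(n_part), n_prob)
    feats = np.tile(fp, (n_part, 1))
    u = np.linspace(0, 1, 101)
    if series_kind == "smooth":
        true = {"beta_min": 0.12 * u**1.2, "beta_var": 0.04 * u**2}
    elif series_kind == "step":
        bmin = np.where(np.arange(1, 102) >= 30, 0.15, 0.0)
        bmin[0] = 0.0
        true = {"beta_min": bmin, "beta_var": 0.0 * u}
    elif series_kind == "null":
        true = {"beta_min": 0.0 * u, "beta_var": 0.0 * u}
    else:
        raise ValueError(series_kind)
    x = ss.simulate_panel(feats, pidx, true, rng)
    return x, pidx, feats, true


@pytest.fixture(scope="session")
def recovery_fit():
    """Shared state-space fit on a smooth-series panel (seed 7)."""
    x, pidx, feats, true = make_panel(7, "smooth")
    ct = ss.fit_statespace(x, pidx, feats, ss.StateSpaceSpec(seed=7))
    return ct, true
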