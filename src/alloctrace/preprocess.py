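"""Raw cursor paths -> analysis coordinates -> 101 equal time bins.

The screen-to-analysis map is the affine transform sending the start button
to (0, 0), the left option target to (-1, 1) and the right target to (1, 1);
x is then inverted on trials where the non-Utilitarian option was shown on
the left, so positive x always points toward the non-Utilitarian option.
Each trial is finally interpolated onto 101 equally spaced times from onset
to click.  No trial is ever excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import RawTrajectory, ScreenGeometry, TrialRecord

__all__ = [
    "NormalizedTrajectory",
    "to_analysis_coords",
    "invert_for_nonutilitarian",
    "time_normalize",
    "normalize_trials",
    "mean_trajectories",
    "normalized_frame",
]

N_BINS = 101


@dataclass(frozen=True)
class NormalizedTrajectory:
    participant_id: str
    trial_index: int
    x: np.ndarray            # (101,), positive toward the non-Utilitarian option
    y: np.ndarray            # (101,), 0 at onset, 1 at click
    choice: str
    rt: float

    def __post_init__(self) -> None:
        if len(self.x) != N_BINS or len(self.y) != N_BINS:
            raise ValueError(f"normalized trajectories have exactly {N_BINS} bins")


def _affine_from_anchors(geometry: ScreenGeometry) -> np.ndarray:
    """3x2 matrix A such that [px, py, 1] @ A = [x, y] in analysis coords."""
    src = np.array([
        [*geometry.start, 1.0],
        [*geometry.left_target, 1.0],
        [*geometry.right_target, 1.0],
    ])
    if abs(np.linalg.det(src)) < 1e-9:
        raise ValueError("degenerate screen geometry: anchor points are collinear")
    dst = np.array([[0.0, 0.0], [-1.0, 1.0], [1.0, 1.0]])
    return np.linalg.solve(src, dst)


def to_analysis_coords(raw: RawTrajectory, geometry: ScreenGeometry | None = None) -> np.ndarray:
    """Map pixel samples to analysis coordinates; returns (n, 3): t_s, x, y."""
    geometry = geometry or raw.geometry
    A = _affine_from_anchors(geometry)
    pix = np.column_stack([raw.samples[:, 1:3], np.ones(len(raw.samples))])
    xy = pix @ A
    return np.column_stack([raw.samples[:, 0] / 1000.0, xy])


def invert_for_nonutilitarian(txy: np.ndarray, side_of_non_utilitarian: str) -> np.ndarray:
    """Negate x iff the non-Utilitarian option was shown on the left."""
    out = txy.copy()
    if side_of_non_utilitarian == "left":
        out[:, 1] = -out[:, 1]
    elif side_of_non_utilitarian != "right":
        raise ValueError("side must be 'left' or 'right'")
    return out


def time_normalize(txy: np.ndarray) -> np.ndarray:
    """Linear interpolation onto 101 equally spaced times from onset to click.

    Bin 1 reproduces the first sample exactly and bin 101 the last.
    """
    t = txy[:, 0]
    if len(t) < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    grid = np.linspace(t[0], t[-1], N_BINS)
    x = np.interp(grid, t, txy[:, 1])
    y = np.interp(grid, t, txy[:, 2])
    x[0], y[0] = txy[0, 1], txy[0, 2]
    x[-1], y[-1] = txy[-1, 1], txy[-1, 2]
    return np.column_stack([grid, x, y])


def normalize_trials(
    raws: list[RawTrajectory],
    trials: list[TrialRecord],
    geometry: ScreenGeometry | None = None,
) -> list[NormalizedTrajectory]:
    """Full chain for a set of trials: coordinates, inversion, time bins."""
    by_key = {(t.participant_id, t.trial_index): t for t in trials}
    out = []
    for raw in raws:
        trial = by_key[(raw.participant_id, raw.trial_index)]
        txy = to_analysis_coords(raw, geometry)
        txy = invert_for_nonutilitarian(txy, trial.side_of_non_utilitarian)
        txy = time_normalize(txy)
        out.append(
            NormalizedTrajectory(
                participant_id=raw.participant_id,
                trial_index=raw.trial_index,
                x=txy[:, 1], y=txy[:, 2],
                choice=trial.choice, rt=trial.rt,
            )
        )
    return out


def mean_trajectories(
    normalized: list[NormalizedTrajectory],
) -> dict[str, dict[str, np.ndarray]]:
    """Per-bin mean x with standard error, grouped by choice."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for choice in ("U", "N"):
        xs = np.array([n.x for n in normalized if n.choice == choice])
        if len(xs) == 0:
            warnings.warn(f"no trajectories with choice {choice!r}; group skipped",
                          stacklevel=2)
            continue
        mean = xs.mean(axis=0)
        sem = (
            xs.std(axis=0, ddof=1) / np.sqrt(len(xs)) if len(xs) > 1
            else np.full(N_BINS, np.nan)
        )
        out[choice] = {"mean": mean, "sem": sem, "n": np.array(len(xs))}
    return out


def normalized_frame(normalized: list[NormalizedTrajectory]) -> pd.DataFrame:
    rows = []
    for n in normalized:
        for b in range(N_BINS):
            rows.append(
                (n.participant_id, n.trial_index, b + 1, n.x[b], n.y[b])
            )
    return pd.DataFrame(rows, columns=["participant_id", "trial_index", "bin", "x", "y"])
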