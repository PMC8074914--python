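"""Allocation options and their deterministic summaries.

A choice problem presents two three-recipient allocations: a *Utilitarian*
option with the larger total pay-off, and a *non-Utilitarian* option with
the higher minimum pay-off and the lower Gini coefficient.  Everything the
downstream models consume — minima, population variances, Gini coefficients,
between-option absolute differences and their standardized versions — is
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Allocation",
    "ChoiceProblem",
    "ProblemFeatures",
    "gini",
    "payoff_variance",
    "compute_features",
    "feature_correlation",
    "features_frame",
    "problems_frame",
    "problems_from_frame",
]

N_RECIPIENTS = 3


class UndefinedGiniError(ValueError):
    """Raised when the Gini coefficient is requested for an all-zero allocation."""


class StandardizationError(ValueError):
    """Raised when a feature column cannot be standardized (too few problems)."""


@dataclass(frozen=True)
class Allocation:
    """Pay-offs (yen) to three anonymous recipients.

    ``payoffs`` is stored as given; :attr:`sorted_payoffs` exposes the
    (minimum, medium, high) view used throughout the analysis.
    """

    payoffs: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.payoffs) != N_RECIPIENTS:
            raise ValueError(f"expected {N_RECIPIENTS} pay-offs, got {len(self.payoffs)}")
        if any(p < 0 for p in self.payoffs):
            raise ValueError(f"pay-offs must be non-negative, got {self.payoffs}")
        object.__setattr__(self, "payoffs", tuple(float(p) for p in self.payoffs))

    @property
    def sorted_payoffs(self) -> tuple[float, float, float]:
        return tuple(sorted(self.payoffs))

    @property
    def minimum(self) -> float:
        return min(self.payoffs)

    @property
    def total(self) -> float:
        return float(sum(self.payoffs))

    @property
    def mean(self) -> float:
        return self.total / N_RECIPIENTS


def gini(allocation: Allocation) -> float:
    """Gini coefficient of a three-recipient allocation.

    G = sum_ij |pi_i - pi_j| / (2 n^2 mu); ranges from 0 (perfect equality)
    to (n-1)/n = 2/3 for n = 3 recipients with one taking everything.

    Raises
    ------
    UndefinedGiniError
        If all pay-offs are zero (mean is zero, G undefined).
    """
    p = np.asarray(allocation.payoffs, dtype=float)
    mu = p.mean()
    if mu <= 0.0:
        raise UndefinedGiniError("Gini undefined for an all-zero allocation")
    mad = np.abs(p[:, None] - p[None, :]).sum()
    return float(mad / (2.0 * N_RECIPIENTS**2 * mu))


def payoff_variance(allocation: Allocation, *, ddof: int = 0) -> float:
    """Variance (yen^2) of the three pay-offs.

    Population variance (divisor n) by default, matching the mean-variance
    utility convention; ``ddof=1`` selects the sample variance.
    """
    return float(np.var(allocation.payoffs, ddof=ddof))


@dataclass(frozen=True)
class ChoiceProblem:
    """One problem's two options, with dominance invariants checked on build.

    The Utilitarian option has the strictly larger total; the
    non-Utilitarian option has the strictly larger minimum and strictly
    smaller Gini coefficient.
    """

    problem_id: str
    utilitarian: Allocation
    non_utilitarian: Allocation

    def __post_init__(self) -> None:
        u, n = self.utilitarian, self.non_utilitarian
        if not u.total > n.total:
            raise ValueError(
                f"{self.problem_id}: utilitarian total {u.total} must exceed "
                f"non-utilitarian total {n.total}"
            )
        if not n.minimum > u.minimum:
            raise ValueError(
                f"{self.problem_id}: non-utilitarian minimum {n.minimum} must exceed "
                f"utilitarian minimum {u.minimum}"
            )
        if not gini(n) < gini(u):
            raise ValueError(
                f"{self.problem_id}: non-utilitarian Gini {gini(n):.4f} must be below "
                f"utilitarian Gini {gini(u):.4f}"
            )

    @property
    def diff_min(self) -> float:
        """|Δ minimum| between the two options (yen)."""
        return abs(self.non_utilitarian.minimum - self.utilitarian.minimum)

    @property
    def diff_var(self) -> float:
        """|Δ Gini| between the two options (dimensionless).

        The 'variance' label shown to participants is the Gini coefficient,
        so the variance predictor is a Gini difference, not a yen^2 variance.
        """
        return abs(gini(self.non_utilitarian) - gini(self.utilitarian))

    @property
    def diff_total(self) -> float:
        """|Δ total| between the two options (yen); optional covariate."""
        return abs(self.utilitarian.total - self.non_utilitarian.total)


@dataclass(frozen=True)
class ProblemFeatures:
    """Raw and standardized between-option difference predictors for one problem."""

    problem_id: str
    diff_min: float
    diff_var: float
    diff_total: float
    z_diff_min: float = field(default=np.nan)
    z_diff_var: float = field(default=np.nan)
    z_diff_total: float = field(default=np.nan)


def _standardize(column: np.ndarray) -> np.ndarray:
    # population sd so the standardized column has variance exactly 1
    sd = column.std(ddof=0)
    if sd == 0.0:
        raise StandardizationError("cannot standardize a constant feature column")
    return (column - column.mean()) / sd


def compute_features(problems: list[ChoiceProblem]) -> list[ProblemFeatures]:
    """Difference predictors for a problem set, standardized within the set.

    Per problem: diff_min = |min_N - min_U|, diff_var = |Gini_N - Gini_U|,
    diff_total = |total_U - total_N|; z_* columns are standardized to mean 0
    and variance 1 using the set's own mean and population sd, so that the
    state-space coefficient magnitudes are directly comparable.
    """
    if len(problems) < 2:
        raise StandardizationError("need at least 2 problems to standardize features")
    raw = np.array([[p.diff_min, p.diff_var, p.diff_total] for p in problems])
    z = np.column_stack([_standardize(raw[:, k]) for k in range(3)])
    return [
        ProblemFeatures(
            problem_id=p.problem_id,
            diff_min=raw[i, 0],
            diff_var=raw[i, 1],
            diff_total=raw[i, 2],
            z_diff_min=z[i, 0],
            z_diff_var=z[i, 1],
            z_diff_total=z[i, 2],
        )
        for i, p in enumerate(problems)
    ]


def feature_correlation(features: list[ProblemFeatures]) -> float:
    """Pearson correlation between diff_min and diff_var across problems."""
    if len(features) < 3:
        raise ValueError("need at least 3 problems for a meaningful correlation")
    x = np.array([f.diff_min for f in features])
    y = np.array([f.diff_var for f in features])
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined for a constant feature column")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# tabular round-trips


def problems_frame(problems: list[ChoiceProblem]) -> pd.DataFrame:
    """Long-format table: two rows per problem (option U and N)."""
    rows = []
    for p in problems:
        for label, alloc in (("U", p.utilitarian), ("N", p.non_utilitarian)):
            lo, mid, hi = alloc.sorted_payoffs
            rows.append(
                dict(
                    problem_id=p.problem_id,
                    option=label,
                    pay_min=lo,
                    pay_med=mid,
                    pay_high=hi,
                    gini=gini(alloc),
                    total=alloc.total,
                )
            )
    return pd.DataFrame(rows)


def problems_from_frame(frame: pd.DataFrame) -> list[ChoiceProblem]:
    problems = []
    for pid, grp in frame.groupby("problem_id", sort=False):
        opts = {}
        for _, row in grp.iterrows():
            opts[row["option"]] = Allocation(
                (row["pay_min"], row["pay_med"], row["pay_high"])
            )
        problems.append(
            ChoiceProblem(problem_id=str(pid), utilitarian=opts["U"], non_utilitarian=opts["N"])
        )
    return problems


def features_frame(features: list[ProblemFeatures]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in features])
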