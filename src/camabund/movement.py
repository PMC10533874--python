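"""Grouped, activity-adjusted home-ranging movement simulation.

Animal groups move by a discrete-time bivariate Ornstein--Uhlenbeck (OU)
process around a fixed home-range centre ``s``:

    u[t+1] | u[t] ~ Normal( s + rho * (u[t] - s),  sigma^2 (1 - rho^2) I )

whose stationary distribution is ``Normal(s, sigma^2 I)``.  ``rho`` in (0, 1)
sets the serial autocorrelation of hourly positions and ``sigma`` (metres)
the stationary spread, from which the home-range area (HRA) emerges as the
area of a high-density contour of the stationary Gaussian.  During rest
hours (a nocturnal activity schedule by default) groups stay exactly in
place.  Hourly positions are refined to sub-hourly resolution with a
Brownian bridge so that brief viewshed crossings are not missed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "DEFAULT_REST_HOURS",
    "DEFAULT_GROUP_SIZE_POOL",
    "MovementScenario",
    "GroupTrajectory",
    "draw_home_range_centers",
    "draw_group_sizes",
    "simulate_ou_trajectory",
    "brownian_bridge_refine",
    "refine_trajectory",
    "stationary_hra",
    "simulate_population",
]

#: Hour-of-day indices during which groups are stationary.  The schedule is
#: nocturnal: activity from hour 6 through 17, rest otherwise, i.e. a new
#: position with 1-based index t+1 is frozen when (t+1) % 24 falls in
#: {0..5} or {18..23}.
DEFAULT_REST_HOURS = frozenset(range(0, 6)) | frozenset(range(18, 24))

#: Default pool of group sizes (geometric-like decay on 1..30).  Stands in
#: for empirical group sizes of a group-living ungulate such as wild boar
#: (many small family groups, occasional large sounders); synthetic,
#: overridable.  The upper support must admit the mean size N/G that the
#: sum constraint forces (12 at N=480, G=40).
DEFAULT_GROUP_SIZE_POOL: dict[int, float] = {
    k: 0.8 ** (k - 1) for k in range(1, 31)
}


@dataclass(frozen=True)
class MovementScenario:
    """Configuration of one movement scenario.

    Parameters
    ----------
    N : total population size (individuals).
    G : number of groups; capped at ``N`` so every group has >= 1 member.
    sigma : OU stationary standard deviation per coordinate (metres).
    rho : hourly serial-autocorrelation coefficient, in (0, 1).
    closure : ``"closed"`` (centres on grid centroids) or ``"open"``
        (centres uniform over the study extent).
    n_days, steps_per_day : survey duration; T = n_days * steps_per_day.
    rest_hours : hour-of-day indices with no movement.
    extent : side of the square study area (metres).
    substeps : Brownian-bridge substeps per active hour.
    bridge_scale : bridge diffusion scale (metres over one hour); ``None``
        means ``sigma * sqrt(1 - rho^2) / 2``.
    """

    N: int
    sigma: float
    rho: float
    closure: str = "closed"
    G: int = 40
    n_days: int = 25
    steps_per_day: int = 24
    rest_hours: frozenset[int] = DEFAULT_REST_HOURS
    extent: float = 10_800.0
    substeps: int = 6
    bridge_scale: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size N must be >= 1")
        if self.G < 1:
            raise ValueError("number of groups G must be >= 1")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.closure not in ("closed", "open"):
            raise ValueError("closure must be 'closed' or 'open'")
        if not self.rest_hours <= set(range(self.steps_per_day)):
            raise ValueError("rest_hours must be hour-of-day indices")
        if self.N < self.G:
            # fewer individuals than the default group count: one group per
            # individual, all sizes 1
            object.__setattr__(self, "G", self.N)

    @property
    def n_steps(self) -> int:
        return self.n_days * self.steps_per_day

    @property
    def bridge_scale_value(self) -> float:
        if self.bridge_scale is not None:
            return self.bridge_scale
        return self.sigma * np.sqrt(1.0 - self.rho**2) / 2.0

    def with_population(self, N: int) -> "MovementScenario":
        """Same scenario for a different population size (e.g. a decline)."""
        return replace(self, N=N, G=min(self.G, N))

    @classmethod
    def from_dict(cls, raw: dict) -> "MovementScenario":
        if "rest_hours" in raw:
            raw = dict(raw, rest_hours=frozenset(raw["rest_hours"]))
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "MovementScenario":
        """Load a scenario from a YAML (or JSON) mapping of the fields above."""
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroupTrajectory:
    """One group's movement over the survey.

    ``hourly_positions`` has shape (T, 2); ``fine_positions`` has shape
    ((T-1)*B + 1, 2) and contains the hourly positions as every B-th row.
    """

    group_id: int
    size: int
    center: np.ndarray
    hourly_positions: np.ndarray
    fine_positions: np.ndarray | None = None


def draw_home_range_centers(
    scenario: MovementScenario, grid_centroids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw G home-range centres.

    Closed populations draw centres with replacement from the grid-cell
    centroids (groups are anchored to cells); open populations draw them
    uniformly over the full study square, so home ranges straddle cell
    boundaries and the geographical-closure assumption is violated.
    """
    if scenario.G < 1:
        raise ValueError("invalid scenario: G must be >= 1")
    if scenario.closure == "closed":
        idx = rng.integers(0, len(grid_centroids), size=scenario.G)
        return np.asarray(grid_centroids, dtype=float)[idx]
    return rng.uniform(0.0, scenario.extent, size=(scenario.G, 2))


def draw_group_sizes(
    N: int,
    G: int,
    size_distribution: dict[int, float] | Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw G positive group sizes summing exactly to N.

    Sizes are drawn from the pool distribution *conditioned on the sum*:
    a dynamic-programming pass computes the probability that g iid pool
    draws total n, and sizes are then sampled sequentially from the exact
    conditional distribution, so every size stays inside the pool's
    support and the constraint N = Σ N_g holds by construction.
    """
    if N < G:
        raise ValueError(f"infeasible allocation: N={N} < G={G}")
    if rng is None:
        rng = np.random.default_rng()
    if size_distribution is None:
        size_distribution = DEFAULT_GROUP_SIZE_POOL
    if isinstance(size_distribution, dict):
        values = np.array(sorted(size_distribution), dtype=int)
        probs = np.array([size_distribution[v] for v in values], dtype=float)
    else:
        values, counts = np.unique(
            np.asarray(size_distribution, dtype=int), return_counts=True
        )
        probs = counts.astype(float)
    if (values < 1).any():
        raise ValueError("group sizes must be positive integers")
    probs = probs / probs.sum()
    if N > G * values.max():
        raise ValueError(
            f"infeasible allocation: N={N} exceeds G={G} groups of at most "
            f"{values.max()} individuals"
        )

    # f[g, n] = P(g iid pool draws sum to n); normalised per g to avoid
    # underflow at large G
    f = np.zeros((G + 1, N + 1))
    f[0, 0] = 1.0
    for g in range(1, G + 1):
        for v, q in zip(values, probs):
            if v > N:
                break
            f[g, v:] += q * f[g - 1, : N + 1 - v]
        tot = f[g].sum()
        if tot > 0:
            f[g] /= tot
    if f[G, N] == 0:
        raise ValueError("size distribution cannot reach the requested total")

    sizes = np.empty(G, dtype=int)
    remaining = N
    for g in range(G, 0, -1):
        w = np.array(
            [
                q * f[g - 1, remaining - v] if 0 <= remaining - v <= N else 0.0
                for v, q in zip(values, probs)
            ]
        )
        w /= w.sum()
        k = rng.choice(len(values), p=w)
        sizes[G - g] = values[k]
        remaining -= values[k]
    return sizes


def simulate_ou_trajectory(
    center: np.ndarray,
    sigma: float,
    rho: float,
    n_steps: int,
    rest_hours: frozenset[int] | set[int] = DEFAULT_REST_HOURS,
    rng: np.random.Generator | None = None,
    steps_per_day: int = 24,
) -> np.ndarray:
    """Simulate T hourly positions of one group.

    The first position is drawn from the stationary distribution
    ``Normal(center, sigma^2 I)``.  A transition into (1-based) hour index
    ``t+1`` with ``(t+1) % steps_per_day`` in ``rest_hours`` copies the
    previous position exactly.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    center = np.asarray(center, dtype=float)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    pos = np.empty((n_steps, 2))
    pos[0] = center + sigma * rng.standard_normal(2)
    for k in range(1, n_steps):
        # row k holds the paper's position index t+1 = k+1 (1-based)
        if (k + 1) % steps_per_day in rest_hours:
            pos[k] = pos[k - 1]
        else:
            pos[k] = center + rho * (pos[k - 1] - center) + innov_sd * rng.standard_normal(2)
    return pos


def brownian_bridge_refine(
    p_start: np.ndarray,
    p_end: np.ndarray,
    substeps: int,
    bridge_scale: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Interior points of a Brownian bridge between two hourly positions.

    Returns ``substeps - 1`` points; the point at fraction f = k/substeps
    has mean ``(1-f) p_start + f p_end`` and per-coordinate variance
    ``bridge_scale^2 f (1-f)``.  ``substeps=1`` returns an empty array
    (straight hop); endpoints are never altered.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    if bridge_scale < 0:
        raise ValueError("bridge_scale must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    B = substeps
    p_start = np.asarray(p_start, dtype=float)
    p_end = np.asarray(p_end, dtype=float)
    f = np.arange(1, B)[:, None] / B
    mean = (1.0 - f) * p_start + f * p_end
    if bridge_scale == 0.0 or B == 1:
        return mean
    # Brownian path pinned at both ends: W_f - f * W_1 has var f(1-f)
    incr = rng.standard_normal((B, 2)) * (bridge_scale / np.sqrt(B))
    w = np.cumsum(incr, axis=0)
    return mean + w[:-1] - f * w[-1]


def refine_trajectory(
    hourly: np.ndarray,
    substeps: int,
    bridge_scale: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Refine T hourly positions to ((T-1)*B + 1) sub-hourly positions.

    Active transitions are bridged; rest transitions (zero displacement)
    repeat the rest position exactly, so resting groups do not jitter.
    """
    if rng is None:
        rng = np.random.default_rng()
    hourly = np.asarray(hourly, dtype=float)
    T = hourly.shape[0]
    B = substeps
    fine = np.empty(((T - 1) * B + 1, 2))
    fine[::B] = hourly
    for t in range(T - 1):
        p0, p1 = hourly[t], hourly[t + 1]
        if np.array_equal(p0, p1):
            fine[t * B + 1 : (t + 1) * B] = p0
        else:
            fine[t * B + 1 : (t + 1) * B] = brownian_bridge_refine(
                p0, p1, B, bridge_scale, rng
            )
    return fine


def stationary_hra(sigma: float, quantile: float = 0.99) -> float:
    """Home-range area (km^2): the `quantile` contour of Normal(s, sigma^2 I).

    The squared distance from the centre, scaled by sigma^2, is
    chi-square(2), so the contour is a disc of radius
    sigma * sqrt(chi2.ppf(quantile, 2)) and area pi * q * sigma^2.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    q = chi2.ppf(quantile, df=2)
    return np.pi * q * sigma**2 / 1e6


def hra_radius(sigma: float, quantile: float = 0.99) -> float:
    """Radius (metres) of the stationary home-range disc."""
    return float(sigma * np.sqrt(chi2.ppf(quantile, df=2)))


def simulate_population(
    scenario: MovementScenario,
    grid_centroids: np.ndarray,
    rng: np.random.Generator,
    size_distribution: dict[int, float] | None = None,
    refine: bool = True,
) -> list[GroupTrajectory]:
    """Simulate all group trajectories for one scenario replicate."""
    centers = draw_home_range_centers(scenario, grid_centroids, rng)
    sizes = draw_group_sizes(scenario.N, scenario.G, size_distribution, rng)
    groups: list[GroupTrajectory] = []
    for g in range(scenario.G):
        hourly = simulate_ou_trajectory(
            centers[g],
            scenario.sigma,
            scenario.rho,
            scenario.n_steps,
            scenario.rest_hours,
            rng,
            scenario.steps_per_day,
        )
        fine = None
        if refine:
            fine = refine_trajectory(
                hourly, scenario.substeps, scenario.bridge_scale_value, rng
            )
        groups.append(
            GroupTrajectory(
                group_id=g,
                size=int(sizes[g]),
                center=centers[g],
                hourly_positions=hourly,
                fine_positions=fine,
            )
        )
    return groups


def trajectories_to_frame(groups: list[GroupTrajectory], substeps: int):
    """Long-format export: group_id, step_index, substep_index, x_m, y_m."""
    import pandas as pd

    rows = []
    for g in groups:
        fine = g.fine_positions
        if fine is None:
            raise ValueError("trajectories were not refined; no fine positions")
        n = len(fine)
        idx = np.arange(n)
        rows.append(
            pd.DataFrame(
                {
                    "group_id": g.group_id,
                    "step_index": idx // substeps,
                    "substep_index": idx % substeps,
                    "x_m": fine[:, 0],
                    "y_m": fine[:, 1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
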