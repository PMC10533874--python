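"""Scenario ground truths: abundance, site-use frequency, trends.

True abundance λ is the mean number of activity centres per grid cell
(N / n_cells, regardless of movement).  Site-use frequency λ_use is the
mean number of individuals whose home-range disc (the 99% contour of the
stationary movement distribution) overlaps a grid cell — individuals are
assumed to cover their whole home range during the survey, and a group's
members share its home range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .detection import Grid
from .movement import hra_radius, stationary_hra

__all__ = [
    "TruthSummary",
    "true_abundance",
    "site_use_frequency",
    "true_trend",
    "per_cell_center_counts",
    "compute_truth",
]


@dataclass
class TruthSummary:
    lambda_true: float
    lambda_use_true: float
    hra_km2: float
    decline_factor: float
    per_cell_center_counts: list[int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSummary":
        return cls(**json.loads(Path(path).read_text()))


def true_abundance(N: int, n_cells: int) -> float:
    """Mean activity centres per grid cell: N / n_cells."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return N / n_cells


def _disc_intersects_rect(center: np.ndarray, radius: float, bounds) -> bool:
    """Closed disc vs axis-aligned rectangle, via the clamped-point distance."""
    xmin, ymin, xmax, ymax = bounds
    cx = min(max(center[0], xmin), xmax)
    cy = min(max(center[1], ymin), ymax)
    return (center[0] - cx) ** 2 + (center[1] - cy) ** 2 <= radius**2


def site_use_frequency(
    centers: np.ndarray,
    group_sizes: np.ndarray,
    sigma: float,
    grid: Grid,
    quantile: float = 0.99,
) -> float:
    """Mean number of individuals whose home-range disc overlaps a cell.

    Each group's disc has radius sqrt(chi2_2(quantile)) * sigma around its
    centre; every overlapped grid cell receives the full group size, and
    the result is averaged over all grid cells (discs may extend beyond
    the grid; only grid cells enter the average).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    group_sizes = np.asarray(group_sizes)
    R = hra_radius(sigma, quantile)
    total = 0.0
    for cell in range(grid.n_cells):
        bounds = grid.cell_bounds(cell)
        for c, sz in zip(centers, group_sizes):
            if _disc_intersects_rect(c, R, bounds):
                total += sz
    return total / grid.n_cells


def per_cell_center_counts(
    centers: np.ndarray, group_sizes: np.ndarray, grid: Grid
) -> np.ndarray:
    """Individuals per cell, attributing each group to its centre's cell."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    counts = np.zeros(grid.n_cells, dtype=int)
    side = grid.cell_side
    n = grid.n_side
    for c, sz in zip(centers, np.asarray(group_sizes)):
        col = int(c[0] // side)
        row = int(c[1] // side)
        if 0 <= col < n and 0 <= row < n:
            counts[row * n + col] += sz
    return counts


def true_trend(decline_factor: float) -> float:
    """True abundance ratio λ_N / λ_fN for a decline to f·N: 1/f."""
    if not 0.0 < decline_factor <= 1.0:
        raise ValueError("decline_factor must lie in (0, 1]")
    return 1.0 / decline_factor


def compute_truth(
    centers: np.ndarray,
    group_sizes: np.ndarray,
    sigma: float,
    grid: Grid,
    N: int,
    decline_factor: float = 1.0,
    quantile: float = 0.99,
    closure: str = "open",
) -> TruthSummary:
    """Ground truths for one replicate.

    Under geographical closure individuals are bounded to the cells that
    hold their activity centres, so site use equals abundance; disc
    overlap drives λ_use only for open populations.
    """
    lam = true_abundance(N, grid.n_cells)
    if closure == "closed":
        lam_use = lam
    else:
        lam_use = site_use_frequency(centers, group_sizes, sigma, grid, quantile)
    return TruthSummary(
        lambda_true=lam,
        lambda_use_true=lam_use,
        hra_km2=stationary_hra(sigma, quantile),
        decline_factor=decline_factor,
        per_cell_center_counts=per_cell_center_counts(centers, group_sizes, grid).tolist(),
    )
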