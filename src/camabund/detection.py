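"""Camera grid, viewshed-crossing detection, and count aggregation.

Cameras sit at grid-cell centroids with a small circular-sector viewshed
(radius 15 m, opening 42 degrees, facing North by default).  A group is
"in view" during an hour when any of its sub-hourly movement segments
intersects the sector; all individuals of a group crossing the viewshed are
counted together, and a group contributes at most once per camera-hour
(it may re-appear in later hours).  Hourly crossing totals ``n_ijh`` are
thinned by the per-camera conditional detection probability
P(detected | in viewshed) — either perfect (1) or spatially varying around
2/3 via a Matérn Gaussian field on the logit scale — and aggregated to the
daily counts ``y_ij`` the abundance models consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.gaussian_process.kernels import Matern

from .movement import GroupTrajectory

__all__ = [
    "Grid",
    "Camera",
    "DetectionField",
    "SurveyData",
    "sample_camera_cells",
    "place_cameras",
    "segment_crosses_viewshed",
    "count_viewshed_crossings",
    "perfect_detection_field",
    "simulate_matern_detection_field",
    "thin_and_aggregate",
]


@dataclass(frozen=True)
class Grid:
    """Square sampling grid; cells are indexed row-major from the SW corner."""

    n_cells: int = 144
    cell_side: float = 900.0

    def __post_init__(self) -> None:
        n_side = int(round(np.sqrt(self.n_cells)))
        if n_side * n_side != self.n_cells:
            raise ValueError("n_cells must be a perfect square")

    @property
    def n_side(self) -> int:
        return int(round(np.sqrt(self.n_cells)))

    @property
    def extent(self) -> float:
        return self.n_side * self.cell_side

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of cell centroids, row-major."""
        n = self.n_side
        rows, cols = np.divmod(np.arange(self.n_cells), n)
        x = (cols + 0.5) * self.cell_side
        y = (rows + 0.5) * self.cell_side
        return np.column_stack([x, y])

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one cell."""
        row, col = divmod(cell_id, self.n_side)
        s = self.cell_side
        return (col * s, row * s, (col + 1) * s, (row + 1) * s)


@dataclass(frozen=True)
class Camera:
    """A camera-trap detector: circular-sector viewshed at a cell centroid.

    ``bearing`` is degrees clockwise from North (0 = facing North); the
    sector spans ``bearing +/- view_angle / 2`` out to ``radius`` metres.
    """

    cell_id: int
    x: float
    y: float
    radius: float = 15.0
    view_angle: float = 42.0
    bearing: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 < self.view_angle <= 360.0:
            raise ValueError("view_angle must lie in (0, 360]")


@dataclass
class DetectionField:
    """Per-camera conditional detection probabilities P(detected | in view).

    ``covariate`` holds the zero-mean Matérn field values (logit scale) used
    as the covariate x in covariate submodels; the perfect regime has all
    probabilities equal to 1 and a zero covariate.
    """

    prob: np.ndarray
    covariate: np.ndarray
    regime: str  # "perfect" | "spatial"

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        self.covariate = np.asarray(self.covariate, dtype=float)
        if ((self.prob < 0) | (self.prob > 1)).any():
            raise ValueError("detection probabilities must lie in [0, 1]")


@dataclass
class SurveyData:
    """Daily camera counts and metadata for one simulated survey.

    ``counts`` is the (n_cameras, n_days) matrix y_ij; ``binary`` its
    detection/non-detection reduction w_ij = 1{y_ij > 0}.
    """

    counts: np.ndarray
    cameras: list[Camera]
    detection: DetectionField
    hourly_counts: np.ndarray | None = None

    @property
    def n_cameras(self) -> int:
        return self.counts.shape[0]

    @property
    def n_days(self) -> int:
        return self.counts.shape[1]

    @property
    def binary(self) -> np.ndarray:
        return (self.counts > 0).astype(int)

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV (camera_id, day, count) + JSON metadata sidecar."""
        path = Path(path)
        cam_ids = np.repeat([c.cell_id for c in self.cameras], self.n_days)
        days = np.tile(np.arange(1, self.n_days + 1), self.n_cameras)
        pd.DataFrame(
            {"camera_id": cam_ids, "day": days, "count": self.counts.ravel()}
        ).to_csv(path, index=False)
        meta = {
            "cameras": [
                {
                    "cell_id": c.cell_id,
                    "x": c.x,
                    "y": c.y,
                    "radius": c.radius,
                    "view_angle": c.view_angle,
                    "bearing": c.bearing,
                }
                for c in self.cameras
            ],
            "detection": {
                "regime": self.detection.regime,
                "prob": self.detection.prob.tolist(),
                "covariate": self.detection.covariate.tolist(),
            },
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurveyData":
        path = Path(path)
        df = pd.read_csv(path)
        wide = df.pivot(index="camera_id", columns="day", values="count")
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            cameras = [Camera(**c) for c in meta["cameras"]]
            order = {c.cell_id: k for k, c in enumerate(cameras)}
            wide = wide.loc[sorted(wide.index, key=order.get)]
            det = DetectionField(
                prob=np.array(meta["detection"]["prob"]),
                covariate=np.array(meta["detection"]["covariate"]),
                regime=meta["detection"]["regime"],
            )
        else:
            cameras = [
                Camera(cell_id=int(cid), x=np.nan, y=np.nan) for cid in wide.index
            ]
            det = perfect_detection_field(len(cameras))
        return cls(counts=wide.to_numpy(dtype=int), cameras=cameras, detection=det)


def sample_camera_cells(
    grid: Grid, fraction: float = 0.25, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Choose camera cells by a randomised regularly-spaced design.

    When 1/fraction is a perfect square b^2 and b divides the grid side,
    the grid is partitioned into b x b blocks and one cell is drawn
    uniformly per block (at defaults: 36 cameras, one per 2x2 block).
    Otherwise a simple random sample of round(fraction * n_cells) cells
    is drawn.
    """
    if fraction <= 0 or fraction > 1:
        raise ValueError("fraction must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    if fraction == 1.0:
        return np.arange(grid.n_cells)
    n = grid.n_side
    b = int(round(np.sqrt(1.0 / fraction)))
    if abs(b * b - 1.0 / fraction) < 1e-9 and n % b == 0:
        cells = []
        for brow in range(n // b):
            for bcol in range(n // b):
                r = brow * b + rng.integers(0, b)
                c = bcol * b + rng.integers(0, b)
                cells.append(r * n + c)
        return np.array(sorted(cells))
    k = int(round(fraction * grid.n_cells))
    return np.sort(rng.choice(grid.n_cells, size=k, replace=False))


def place_cameras(
    grid: Grid,
    cell_ids: np.ndarray,
    radius: float = 15.0,
    view_angle: float = 42.0,
    bearing: float = 0.0,
) -> list[Camera]:
    cents = grid.centroids()
    return [
        Camera(
            cell_id=int(cid),
            x=float(cents[cid, 0]),
            y=float(cents[cid, 1]),
            radius=radius,
            view_angle=view_angle,
            bearing=bearing,
        )
        for cid in cell_ids
    ]


# ---------------------------------------------------------------------------
# sector geometry


def _in_sector(pts: np.ndarray, camera: Camera) -> np.ndarray:
    """Boolean mask: points inside the closed viewshed sector."""
    pts = np.atleast_2d(pts)
    d = pts - np.array([camera.x, camera.y])
    r2 = (d**2).sum(axis=1)
    inside_r = r2 <= camera.radius**2 + 1e-12
    # bearing of the point measured clockwise from North
    ang = np.degrees(np.arctan2(d[:, 0], d[:, 1]))
    dev = (ang - camera.bearing + 180.0) % 360.0 - 180.0
    inside_a = np.abs(dev) <= camera.view_angle / 2.0 + 1e-12
    # the apex belongs to the sector regardless of bearing
    return inside_r & (inside_a | (r2 <= 1e-18))


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _on_segment(pt, a, b) -> bool:
    """Collinearity assumed; is pt within the bounding box of [a, b]?"""
    return (
        min(a[0], b[0]) - 1e-12 <= pt[0] <= max(a[0], b[0]) + 1e-12
        and min(a[1], b[1]) - 1e-12 <= pt[1] <= max(a[1], b[1]) + 1e-12
    )


def _seg_seg_intersect(p0, p1, q0, q1) -> bool:
    """Closed-segment intersection test via orientation signs."""
    d1 = _cross(q0, q1, p0)
    d2 = _cross(q0, q1, p1)
    d3 = _cross(p0, p1, q0)
    d4 = _cross(p0, p1, q1)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 * d2 < 0 and d3 * d4 < 0:
        return True
    if d1 == 0 and _on_segment(p0, q0, q1):
        return True
    if d2 == 0 and _on_segment(p1, q0, q1):
        return True
    if d3 == 0 and _on_segment(q0, p0, p1):
        return True
    if d4 == 0 and _on_segment(q1, p0, p1):
        return True
    return False


def segment_crosses_viewshed(p_start, p_end, camera: Camera) -> bool:
    """Exact test: does the closed segment intersect the viewshed sector?

    The sector is {|p - c| <= r, |bearing(p) - bearing| <= view_angle/2}.
    A segment meets it iff an endpoint lies inside, or it crosses one of
    the two radial edges, or it crosses the bounding arc inside the wedge.
    """
    p0 = np.asarray(p_start, dtype=float)
    p1 = np.asarray(p_end, dtype=float)
    if _in_sector(np.vstack([p0, p1]), camera).any():
        return True
    c = np.array([camera.x, camera.y])
    half = np.radians(camera.view_angle / 2.0)
    b = np.radians(camera.bearing)
    for a in (b - half, b + half):
        edge_end = c + camera.radius * np.array([np.sin(a), np.cos(a)])
        if _seg_seg_intersect(p0, p1, c, edge_end):
            return True
    # segment ∩ circle of radius r, then check the wedge angle
    d = p1 - p0
    f = p0 - c
    a2 = d @ d
    if a2 == 0.0:
        return False
    bq = 2.0 * (f @ d)
    cq = f @ f - camera.radius**2
    disc = bq * bq - 4.0 * a2 * cq
    if disc < 0:
        return False
    sq = np.sqrt(disc)
    for t in ((-bq - sq) / (2 * a2), (-bq + sq) / (2 * a2)):
        if 0.0 <= t <= 1.0:
            if _in_sector(p0 + t * d, camera)[0]:
                return True
    return False


def _point_segment_dist2(c: np.ndarray, P0: np.ndarray, P1: np.ndarray) -> np.ndarray:
    """Squared distance from point c to each segment (vectorised)."""
    d = P1 - P0
    f = c - P0
    denom = (d**2).sum(axis=1)
    t = np.zeros(len(P0))
    nz = denom > 0
    t[nz] = np.clip((f[nz] * d[nz]).sum(axis=1) / denom[nz], 0.0, 1.0)
    proj = P0 + t[:, None] * d
    return ((c - proj) ** 2).sum(axis=1)


def count_viewshed_crossings(
    trajectories: list[GroupTrajectory],
    cameras: list[Camera],
    n_days: int,
    steps_per_day: int = 24,
    substeps: int = 6,
    return_group_hours: bool = False,
):
    """Hourly crossing totals n_ijh, shape (n_cameras, n_days, steps_per_day).

    Hour k (0-based, k = day * steps_per_day + h) owns the fine-scale
    sub-segments of the transition from hourly position k to k+1 (the last
    hour owns only its position).  A group whose path intersects a viewshed
    during hour k contributes its full size once to that camera-hour.

    With ``return_group_hours`` also returns a (n_groups, n_cameras,
    n_days) array of the number of crossing hours per group, camera, and
    day, used to compute realized detection-parameter truths.
    """
    n_cams = len(cameras)
    n = np.zeros((n_cams, n_days, steps_per_day), dtype=int)
    group_hours = np.zeros((len(trajectories), n_cams, n_days), dtype=int)
    T = n_days * steps_per_day
    cam_xy = np.array([[c.x, c.y] for c in cameras])
    cam_r = np.array([c.radius for c in cameras])
    for gi, g in enumerate(trajectories):
        fine = g.fine_positions
        if fine is None:
            raise ValueError("fine positions missing; refine trajectories first")
        if len(fine) != (T - 1) * substeps + 1:
            raise ValueError("trajectory length does not match the survey layout")
        P0 = fine[:-1]
        P1 = fine[1:]
        seg_hour = np.arange(len(P0)) // substeps
        for ci in range(n_cams):
            hit_hours = set()
            # the final hour owns only its (stationary) position
            if _in_sector(fine[-1], cameras[ci])[0]:
                hit_hours.add(T - 1)
            d2 = _point_segment_dist2(cam_xy[ci], P0, P1)
            for m in np.flatnonzero(d2 <= cam_r[ci] ** 2):
                hk = seg_hour[m]
                if hk in hit_hours:
                    continue
                if segment_crosses_viewshed(P0[m], P1[m], cameras[ci]):
                    hit_hours.add(hk)
            for hk in hit_hours:
                n[ci, hk // steps_per_day, hk % steps_per_day] += g.size
                group_hours[gi, ci, hk // steps_per_day] += 1
    if return_group_hours:
        return n, group_hours
    return n


def perfect_detection_field(n_cameras: int) -> DetectionField:
    return DetectionField(
        prob=np.ones(n_cameras), covariate=np.zeros(n_cameras), regime="perfect"
    )


def simulate_matern_detection_field(
    cameras: list[Camera],
    variance: float = 0.75**2,
    length_scale: float = 2_700.0,
    smoothness: float = 1.5,
    mean_prob: float = 2.0 / 3.0,
    rng: np.random.Generator | None = None,
) -> DetectionField:
    """Spatially varying P(detected | in view) from a Matérn Gaussian field.

    A zero-mean Matérn field x is drawn at the camera locations and
    P_i = invlogit(logit(mean_prob) + x_i), so probabilities vary around
    ``mean_prob`` with spatial correlation; x_i doubles as the covariate
    for covariate submodels.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.array([[c.x, c.y] for c in cameras])
    if variance == 0.0:
        x = np.zeros(len(cameras))
    else:
        kern = Matern(length_scale=length_scale, nu=smoothness)
        C = variance * kern(X)
        jitter = 1e-10 * variance
        for _ in range(6):
            try:
                L = np.linalg.cholesky(C + jitter * np.eye(len(C)))
                break
            except np.linalg.LinAlgError:
                jitter *= 100.0
        else:
            raise np.linalg.LinAlgError("Matérn covariance is not positive definite")
        x = L @ rng.standard_normal(len(cameras))
    prob = expit(logit(mean_prob) + x)
    return DetectionField(prob=prob, covariate=x, regime="spatial")


def thin_and_aggregate(
    n_ijh: np.ndarray,
    detection: DetectionField,
    cameras: list[Camera],
    rng: np.random.Generator | None = None,
    keep_hourly: bool = True,
) -> SurveyData:
    """Binomial thinning y_ijh ~ Binomial(n_ijh, P_i), then daily sums y_ij."""
    if rng is None:
        rng = np.random.default_rng()
    n_ijh = np.asarray(n_ijh)
    if (n_ijh < 0).any():
        raise ValueError("crossing counts must be non-negative")
    p = detection.prob[:, None, None]
    if detection.regime == "perfect":
        y_ijh = n_ijh.copy()
    else:
        y_ijh = rng.binomial(n_ijh, np.broadcast_to(p, n_ijh.shape))
    counts = y_ijh.sum(axis=2)
    return SurveyData(
        counts=counts,
        cameras=cameras,
        detection=detection,
        hourly_counts=y_ijh if keep_hourly else None,
    )
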