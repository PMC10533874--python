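"""Scenario grids, replicate orchestration, seeding, and persistence.

One replicate runs the full chain: movement simulation → viewshed
detection → ground truths → model fits (per family and submodel, for the
full population and its induced 10%/20% declines) → metrics rows.  A
study expands the scenario grid, runs every (scenario, replicate) job,
and summarizes the collected metrics into study tables.

Declined populations are simulated as independent populations of size
round(f·N) (fresh centres, trajectories, detections): trends are compared
post hoc between independent fits, mirroring how practitioners compare
surveys across years.

Seeding: every stage of every job derives its RNG from a CRC32 hash of
(master seed, scenario id, replicate, stage), so any single artifact can
be regenerated in isolation, in any order, bit-for-bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import detection as det
from . import movement as mov
from . import truth as tr
from .evaluation import MetricsRow, metrics_row, rows_to_frame, summarize_study, trend_metrics
from .models import FitResult, ModelSpec, fit_hm

__all__ = [
    "Scenario",
    "StudyConfig",
    "default_scenario_grid",
    "stage_seed",
    "simulate_survey",
    "run_replicate",
    "run_study",
]

#: (closure, sigma, N) rows of the study design; rho and detection regime
#: are crossed with these.
DESIGN_ROWS: tuple[tuple[str, float, int], ...] = (
    ("closed", 150.0, 480),
    ("closed", 150.0, 240),
    ("open", 150.0, 480),
    ("open", 150.0, 240),
    ("open", 300.0, 240),
    ("open", 300.0, 120),
    ("open", 600.0, 120),
    ("open", 600.0, 60),
    ("open", 1200.0, 60),
    ("open", 1200.0, 30),
)


@dataclass(frozen=True)
class Scenario:
    """One cell of the study design."""

    N: int
    sigma: float
    rho: float
    closure: str
    detection_regime: str = "perfect"  # "perfect" | "spatial"

    @property
    def scenario_id(self) -> str:
        reg = "" if self.detection_regime == "perfect" else "-spatial"
        return f"{self.closure}-s{self.sigma:g}-N{self.N}-rho{self.rho:g}{reg}"

    def movement_scenario(self, N: int | None = None, **kwargs) -> mov.MovementScenario:
        return mov.MovementScenario(
            N=self.N if N is None else N,
            sigma=self.sigma,
            rho=self.rho,
            closure=self.closure,
            **kwargs,
        )


def default_scenario_grid(
    rho_values: tuple[float, ...] = (0.7, 0.95),
    include_spatial: bool = True,
    rows: tuple[tuple[str, float, int], ...] = DESIGN_ROWS,
) -> list[Scenario]:
    """Expand the design rows × rho values (+ spatial-detection variants).

    The spatially varying detection regime is simulated only for the
    sigma = 300 rows, the home-range size closest to the target species'.
    """
    grid = []
    for closure, sigma, N in rows:
        for rho in rho_values:
            grid.append(Scenario(N=N, sigma=sigma, rho=rho, closure=closure))
            if include_spatial and sigma == 300.0:
                grid.append(
                    Scenario(
                        N=N, sigma=sigma, rho=rho, closure=closure,
                        detection_regime="spatial",
                    )
                )
    return grid


@dataclass
class StudyConfig:
    scenarios: list[Scenario] = field(default_factory=default_scenario_grid)
    n_replicates: int = 40
    families: tuple[str, ...] = ("BernP", "BP", "PP")
    decline_factors: tuple[float, ...] = (1.0, 0.9, 0.8)
    master_seed: int = 0
    fit_method: str = "mcmc"
    out_dir: str | None = None
    sampler_steps: int = 1000
    sampler_warmup: int = 300
    n_jobs: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        scenarios = [Scenario(**s) for s in raw.pop("scenarios", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k != "scenarios"})
        if scenarios:
            cfg.scenarios = scenarios
        cfg.families = tuple(cfg.families)
        cfg.decline_factors = tuple(cfg.decline_factors)
        return cfg


def stage_seed(master_seed: int, scenario_id: str, replicate: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    key = f"{master_seed}|{scenario_id}|{replicate}|{stage}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def simulate_survey(
    scenario: Scenario,
    replicate: int,
    master_seed: int,
    decline_factor: float = 1.0,
    grid: det.Grid | None = None,
    camera_cells: np.ndarray | None = None,
    movement_kwargs: dict | None = None,
):
    """Simulate one population and its survey; returns (SurveyData, TruthSummary).

    The declined population (f < 1) is an independent population of
    round(f·N) individuals on the same camera layout.
    """
    grid = grid or det.Grid()
    sid = scenario.scenario_id
    tag = f"f{decline_factor:g}"
    if camera_cells is None:
        rng_design = np.random.default_rng(
            stage_seed(master_seed, sid, replicate, "design")
        )
        camera_cells = det.sample_camera_cells(grid, 0.25, rng_design)
    cameras = det.place_cameras(grid, camera_cells)

    N = int(round(decline_factor * scenario.N))
    mscn = scenario.movement_scenario(N=N, **(movement_kwargs or {}))
    rng_move = np.random.default_rng(
        stage_seed(master_seed, sid, replicate, f"movement-{tag}")
    )
    groups = mov.simulate_population(mscn, grid.centroids(), rng_move)

    n_ijh, group_hours = det.count_viewshed_crossings(
        groups, cameras, mscn.n_days, mscn.steps_per_day, mscn.substeps,
        return_group_hours=True,
    )
    rng_det = np.random.default_rng(
        stage_seed(master_seed, sid, replicate, f"detection-{tag}")
    )
    if scenario.detection_regime == "spatial":
        fld = det.simulate_matern_detection_field(cameras, rng=rng_det)
    else:
        fld = det.perfect_detection_field(len(cameras))
    survey = det.thin_and_aggregate(n_ijh, fld, cameras, rng_det)

    centers = np.array([g.center for g in groups])
    sizes = np.array([g.size for g in groups])
    truth = tr.compute_truth(
        centers, sizes, scenario.sigma, grid, N, decline_factor,
        closure=scenario.closure,
    )
    extra = _realized_detection_truth(group_hours, sizes, fld.prob, N)
    return survey, truth, extra


def _realized_detection_truth(
    group_hours: np.ndarray, sizes: np.ndarray, probs: np.ndarray, N: int
) -> dict[str, float]:
    """Realized per-capita daily detection probability p and rate μ.

    Per capita means per individual in the population and per survey day:
    p is the expected number of individual detection events per day (a
    group crossing a camera in H hours detects each member with
    probability 1 − (1 − P_i)^H) divided by N; μ is the expected daily
    count total per individual.  ``per_camera_daily_p`` splits p by
    camera.
    """
    n_groups, n_cams, n_days = group_hours.shape
    P = probs[None, :, None]
    p_ind = 1.0 - (1.0 - P) ** group_hours  # (groups, cams, days)
    w = sizes[:, None, None]
    p_true = float((w * p_ind).sum() / (N * n_days))
    mu_true = float((w * group_hours * P).sum() / (N * n_days))
    per_cam_p = (w * p_ind).sum(axis=(0, 2)) / (N * n_days)
    return {
        "p_true": p_true,
        "mu_true": mu_true,
        "per_camera_daily_p": per_cam_p,
    }


def run_replicate(
    scenario: Scenario,
    replicate: int,
    config: StudyConfig,
    out_dir: Path | None = None,
) -> list[MetricsRow]:
    """Run one (scenario, replicate) job end to end; returns metrics rows.

    When ``out_dir`` is given, artifacts (survey CSVs, truth JSON, fit
    summaries, metrics CSV) are persisted under
    ``out_dir/<scenario_id>/rep<k>/`` and the job is skipped if its
    metrics file already exists (idempotent re-runs).
    """
    sid = scenario.scenario_id
    job_dir = None
    if out_dir is not None:
        job_dir = Path(out_dir) / sid / f"rep{replicate:03d}"
        done = job_dir / "metrics.csv"
        if done.exists():
            import pandas as pd

            df = pd.read_csv(done)
            return [
                MetricsRow(
                    **{
                        k: r[k]
                        for k in (
                            "scenario", "family", "submodel", "target",
                            "replicate", "estimate", "truth", "ci_low", "ci_high",
                        )
                    }
                )
                for r in df.to_dict("records")
            ]
        job_dir.mkdir(parents=True, exist_ok=True)

    submodels = (
        ("naive", "covariate") if scenario.detection_regime == "spatial" else ("naive",)
    )
    surveys: dict[float, tuple] = {}
    for f in config.decline_factors:
        surveys[f] = simulate_survey(scenario, replicate, config.master_seed, f)
        if job_dir is not None:
            surveys[f][0].to_csv(job_dir / f"survey_f{f:g}.csv")
            surveys[f][1].to_json(job_dir / f"truth_f{f:g}.json")

    rows: list[MetricsRow] = []
    fits: dict[tuple, FitResult] = {}
    for family in config.families:
        for submodel in submodels:
            for f in config.decline_factors:
                survey, truth, extra = surveys[f]
                spec = ModelSpec(
                    family=family,
                    submodel=submodel,
                    n_steps=config.sampler_steps,
                    n_warmup=config.sampler_warmup,
                    seed=stage_seed(
                        config.master_seed, sid, replicate,
                        f"fit-{family}-{submodel}-f{f:g}",
                    ),
                )
                fit = fit_hm(spec, survey, method=config.fit_method)
                fits[(family, submodel, f)] = fit
                if job_dir is not None:
                    (job_dir / f"fit_{family}_{submodel}_f{f:g}.json").write_text(
                        json.dumps(fit.to_json_dict(), indent=1)
                    )
                if f == 1.0:
                    theta_truth = (
                        extra["mu_true"] if family == "PP" else extra["p_true"]
                    )
                    rows.append(
                        metrics_row(sid, fit, "theta_det", theta_truth, replicate)
                    )
                    rows.append(
                        metrics_row(sid, fit, "lambda", truth.lambda_true, replicate)
                    )
                    rows.append(
                        metrics_row(
                            sid, fit, "lambda_use", truth.lambda_use_true, replicate
                        )
                    )
            full = fits.get((family, submodel, 1.0))
            for f in config.decline_factors:
                if f >= 1.0 or (family, submodel, f) not in fits:
                    continue
                rng = np.random.default_rng(
                    stage_seed(
                        config.master_seed, sid, replicate,
                        f"trend-{family}-{submodel}-f{f:g}",
                    )
                )
                rows.append(
                    trend_metrics(
                        full, fits[(family, submodel, f)], f,
                        scenario=sid, replicate=replicate, rng=rng,
                    )
                )
    if job_dir is not None:
        rows_to_frame(rows).to_csv(job_dir / "metrics.csv", index=False)
    return rows


def _safe_replicate(scenario, rep, config, out_dir):
    try:
        return run_replicate(scenario, rep, config, out_dir), None
    except Exception as exc:  # pragma: no cover - defensive
        return [], repr(exc)


def run_study(config: StudyConfig) -> dict:
    """Run every job of the study and summarize.

    Returns {"rows": all metrics rows, "summaries": summary tables,
    "manifest": job bookkeeping}.  Partial failures are recorded in the
    manifest (a failed fit never aborts the study) and summaries cover
    completed jobs only.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    all_rows: list[MetricsRow] = []
    manifest = {
        "master_seed": config.master_seed,
        "n_replicates": config.n_replicates,
        "jobs": [],
    }
    job_args = [
        (scenario, rep)
        for scenario in config.scenarios
        for rep in range(config.n_replicates)
    ]
    if config.n_jobs > 1:
        # all randomness is derived per (scenario, replicate, stage), so
        # parallel results are byte-identical to serial ones
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=config.n_jobs)(
            delayed(_safe_replicate)(scenario, rep, config, out_dir)
            for scenario, rep in job_args
        )
    else:
        outcomes = [
            _safe_replicate(scenario, rep, config, out_dir)
            for scenario, rep in job_args
        ]
    for (scenario, rep), (rows, err) in zip(job_args, outcomes):
        job = {"scenario": scenario.scenario_id, "replicate": rep}
        if err is None:
            all_rows.extend(rows)
            job["status"] = "ok"
            job["n_rows"] = len(rows)
        else:
            job["status"] = f"failed: {err}"
        manifest["jobs"].append(job)
    summaries = summarize_study(all_rows)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        rows_to_frame(all_rows).to_csv(out_dir / "metrics_long.csv", index=False)
        summaries["table1"].to_csv(out_dir / "table1.csv")
        summaries["table2"].to_csv(out_dir / "table2.csv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"rows": all_rows, "summaries": summaries, "manifest": manifest}
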