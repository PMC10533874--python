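"""Estimator-quality metrics across replicates and scenarios.

Relative bias (θ̂ − θ)/θ, RMSE, 95% credible-interval coverage, and the
accuracy proportion — the fraction of replicates with |relative bias| at
or below 0.5 — are computed per scenario, family, and target quantity, and
summarized into wide study tables with study-level medians.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .models import FitResult

__all__ = [
    "ACCURACY_THRESHOLD",
    "MetricsRow",
    "relative_bias",
    "rmse",
    "is_accurate",
    "ci_coverage",
    "metrics_row",
    "trend_metrics",
    "summarize_study",
]

ACCURACY_THRESHOLD = 0.5


@dataclass
class MetricsRow:
    """One estimate-versus-truth record for one replicate."""

    scenario: str
    family: str
    submodel: str
    target: str  # theta_det | lambda | lambda_use | trend10 | trend20
    replicate: int
    estimate: float
    truth: float
    ci_low: float
    ci_high: float

    @property
    def bias(self) -> float:
        return self.estimate - self.truth

    @property
    def rel_bias(self) -> float:
        return relative_bias(self.estimate, self.truth)

    @property
    def covered(self) -> int:
        return int(self.ci_low <= self.truth <= self.ci_high)

    @property
    def accurate(self) -> int:
        return int(is_accurate(self.estimate, self.truth))

    def as_record(self) -> dict:
        d = asdict(self)
        d.update(
            bias=self.bias,
            rel_bias=self.rel_bias,
            covered=self.covered,
            accurate=self.accurate,
        )
        return d


def relative_bias(estimate: float, truth: float) -> float:
    """(θ̂ − θ) / θ; undefined at θ = 0."""
    if truth == 0:
        raise ValueError("relative bias is undefined for a zero truth")
    return (estimate - truth) / truth


def is_accurate(
    estimate: float,
    truth: float,
    threshold: float = ACCURACY_THRESHOLD,
    inclusive: bool = True,
) -> bool:
    """|relative bias| ≤ threshold (``inclusive=False`` for strict <)."""
    rb = abs(relative_bias(estimate, truth))
    return rb <= threshold if inclusive else rb < threshold


def rmse(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Root mean squared error over paired estimates and truths."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must have equal length")
    if estimates.size == 0:
        raise ValueError("rmse of an empty vector is undefined")
    return float(np.sqrt(np.mean((estimates - truths) ** 2)))


def ci_coverage(rows: list[MetricsRow]) -> tuple[float, bool]:
    """Proportion of replicates whose 95% CI encloses the truth.

    Returns (coverage, reaches_nominal) where the flag marks coverage
    ≥ 0.95, the benchmark for good uncertainty quantification.
    """
    if not rows:
        raise ValueError("coverage of an empty replicate set is undefined")
    cov = float(np.mean([r.covered for r in rows]))
    return cov, cov >= 0.95


def metrics_row(
    scenario: str,
    fit: FitResult,
    target: str,
    truth: float,
    replicate: int,
    param: str | None = None,
    point: str = "mean",
) -> MetricsRow:
    """Build a MetricsRow from a fit's posterior summary."""
    param = param or ("lambda" if target in ("lambda", "lambda_use") else "theta_det")
    s = fit.summary[param]
    estimate = s["mean"] if point == "mean" else s["q50"]
    return MetricsRow(
        scenario=scenario,
        family=fit.family,
        submodel=fit.submodel,
        target=target,
        replicate=replicate,
        estimate=estimate,
        truth=truth,
        ci_low=s["q2.5"],
        ci_high=s["q97.5"],
    )


def trend_metrics(
    fit_full: FitResult,
    fit_declined: FitResult,
    decline_factor: float,
    scenario: str = "",
    replicate: int = 0,
    point: str = "mean",
    n_ratio_draws: int = 2000,
    rng: np.random.Generator | None = None,
) -> MetricsRow:
    """Relative-abundance trend metrics: λ̂_N / λ̂_fN against truth 1/f.

    The point estimate is the ratio of posterior means; the CI comes from
    independently resampled draw pairs (fits are independent populations).
    """
    if fit_full.family != fit_declined.family:
        raise ValueError("trend requires fits from the same family")
    key = "mean" if point == "mean" else "q50"
    lam_full = fit_full.summary["lambda"][key]
    lam_dec = fit_declined.summary["lambda"][key]
    if lam_full <= 0 or lam_dec <= 0:
        raise ValueError("non-positive posterior abundance")
    ratio = lam_full / lam_dec
    truth = 1.0 / decline_factor
    if rng is None:
        rng = np.random.default_rng(0)
    a = rng.choice(fit_full.draws["lambda"], size=n_ratio_draws)
    b = rng.choice(fit_declined.draws["lambda"], size=n_ratio_draws)
    lo, hi = np.percentile(a / b, [2.5, 97.5])
    target = f"trend{round((1 - decline_factor) * 100)}"
    return MetricsRow(
        scenario=scenario,
        family=fit_full.family,
        submodel=fit_full.submodel,
        target=target,
        replicate=replicate,
        estimate=ratio,
        truth=truth,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def rows_to_frame(rows: list[MetricsRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_record() for r in rows])


def summarize_study(rows: list[MetricsRow] | pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-scenario and study-level summaries.

    Returns ``long`` (per scenario × family × submodel × target: mean and
    replicate-quantile relative bias, RMSE, coverage, accuracy), ``table1``
    (accuracy proportions for θ_det, λ, λ_use, wide by family) and
    ``table2`` (accuracy proportions for the 10% and 20% trends), each with
    a study-level median row appended.
    """
    df = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    if df.empty:
        raise ValueError("no metrics rows to summarize")

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(g),
                "mean_rel_bias": g["rel_bias"].mean(),
                "rel_bias_q2.5": g["rel_bias"].quantile(0.025),
                "rel_bias_q97.5": g["rel_bias"].quantile(0.975),
                "rmse": rmse(g["estimate"].to_numpy(), g["truth"].to_numpy()),
                "coverage": g["covered"].mean(),
                "accuracy": g["accurate"].mean(),
            }
        )

    keys = ["scenario", "family", "submodel", "target"]
    long = df.groupby(keys, sort=True).apply(_agg, include_groups=False).reset_index()

    def _wide(targets: list[str]) -> pd.DataFrame:
        sub = long[long["target"].isin(targets)]
        wide = sub.pivot_table(
            index="scenario",
            columns=["target", "family"],
            values="accuracy",
            aggfunc="mean",
        ).sort_index()
        med = wide.median(axis=0).to_frame().T
        med.index = ["median"]
        return pd.concat([wide, med])

    return {
        "long": long,
        "table1": _wide(["theta_det", "lambda", "lambda_use"]),
        "table2": _wide(["trend10", "trend20"]),
    }
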