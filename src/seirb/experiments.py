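"""The nine-cell calibration experiment grid and its summaries.

Three hypotheses x three observation windows (Table-style design):

* H1 — perfect model, deaths data only (SEIRb, daily deaths);
* H2 — imperfect model neglecting behavior (SEIR, daily deaths);
* H3 — perfect model plus behavior data (SEIRb, deaths + contact rate);

each calibrated on the first 60 (early), 120 (mid), or 365 (late) days of
every stochastic replicate, followed by a 365-day-ahead deterministic
deaths projection scored against the replicate's own stochastic future by
cumulative daily MAPE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import (
    MAPE_EPSILON,
    CalibrationSpec,
    fit,
    mape_cumulative,
    project,
)
from .model_core import ParameterError
from .synthetic_data import DataWindow, SyntheticDataset, window

__all__ = [
    "ExperimentCell",
    "ExperimentReport",
    "HYPOTHESES",
    "STAGES",
    "run_cell",
    "run_grid",
    "estimate_error_stats",
    "compare_conditions",
    "normalized_error_change",
    "summarize_distributions",
]

# Table-1-style hypothesis definitions: model and data channels.
HYPOTHESES: Dict[str, Dict] = {
    "H1": {"model": "SEIRb", "channels": ("daily_deaths",)},
    "H2": {"model": "SEIR", "channels": ("daily_deaths",)},
    "H3": {"model": "SEIRb", "channels": ("daily_deaths", "contact_multiplier")},
}

STAGES: Dict[str, int] = {"early": 60, "mid": 120, "late": 365}

PROJECTION_HORIZON = 365


@dataclass(frozen=True)
class ExperimentCell:
    """One cell of the grid: a hypothesis and an observation window."""

    hypothesis: str
    window: int

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESES:
            raise ParameterError(f"unknown hypothesis {self.hypothesis!r}")
        if self.window < 1:
            raise ParameterError("window must be >= 1 day")

    @property
    def model(self) -> str:
        return HYPOTHESES[self.hypothesis]["model"]

    @property
    def channels(self) -> Tuple[str, ...]:
        return HYPOTHESES[self.hypothesis]["channels"]

    @property
    def free_params(self) -> Tuple[str, ...]:
        if self.model == "SEIR":
            return ("beta0",)
        return ("beta0", "alpha", "lambda_p")

    def spec(self, **overrides) -> CalibrationSpec:
        kwargs = dict(model=self.model, free_params=self.free_params)
        kwargs.update(overrides)
        return CalibrationSpec(**kwargs)


@dataclass
class ExperimentReport:
    """Long-format per-replicate results plus the generating truth."""

    results: pd.DataFrame  # hypothesis, window, replicate, <params>, loss, mape
    truth: Dict[str, float]
    n_reps: int

    def cell(self, hypothesis: str, window: int) -> pd.DataFrame:
        m = (self.results["hypothesis"] == hypothesis) & (
            self.results["window"] == window
        )
        return self.results[m]

    def rel_errors(self, hypothesis: str, window: int, param: str) -> np.ndarray:
        """|relative error| of one parameter in one cell, ordered by replicate."""
        df = self.cell(hypothesis, window).sort_values("replicate")
        est = df[param].to_numpy(dtype=float)
        true = self.truth[param]
        return np.abs(est - true) / abs(true)


def run_cell(
    cell: ExperimentCell,
    dataset: SyntheticDataset,
    *,
    n_starts: int = 16,
    optimizer_seed: int = 0,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    replicates: Optional[Sequence[int]] = None,
    projection_horizon: int = PROJECTION_HORIZON,
    mape_epsilon: float = MAPE_EPSILON,
) -> pd.DataFrame:
    """Calibrate and project every replicate under one experimental cell.

    For each replicate: truncate to the cell's window -> fit -> project
    ``projection_horizon`` days ahead -> score cumulative MAPE against the
    replicate's own stochastic future.  Per-replicate failures are recorded
    in the ``error`` column; the cell as a whole fails (RuntimeError) if
    more than 10% of replicates fail.
    """
    if cell.window + projection_horizon > dataset.horizon:
        raise ParameterError(
            "corpus horizon too short for window + projection horizon"
        )
    spec_kwargs: dict = dict(n_starts=n_starts, optimizer_seed=optimizer_seed)
    if bounds is not None:
        full = dict(CalibrationSpec().bounds)
        full.update(bounds)
        spec_kwargs["bounds"] = full
    spec = cell.spec(**spec_kwargs)
    rep_ids = list(replicates) if replicates is not None else list(range(dataset.n_reps))

    rows = []
    n_failed = 0
    for rid in rep_ids:
        obs = window(dataset, DataWindow(rid, cell.window, cell.channels))
        row = {
            "hypothesis": cell.hypothesis,
            "window": cell.window,
            "replicate": rid,
            "seed": dataset.seeds[rid],
        }
        try:
            res = fit(spec, obs, dataset.ground_truth)
            proj = project(
                res.estimates,
                spec,
                dataset.ground_truth,
                t_start=cell.window,
                horizon=projection_horizon,
            )
            future = dataset.replicates[rid].daily_deaths[
                cell.window + 1 : cell.window + projection_horizon + 1
            ]
            row.update(res.estimates)
            row["loss"] = res.loss
            row["converged"] = res.converged
            row["mape"] = mape_cumulative(proj, future, epsilon=mape_epsilon)
            row["error"] = ""
        except Exception as exc:  # recorded, not fatal
            n_failed += 1
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    if n_failed > 0.1 * len(rep_ids):
        raise RuntimeError(
            f"cell {cell.hypothesis}/{cell.window}d: {n_failed}/{len(rep_ids)} "
            "replicates failed"
        )
    return pd.DataFrame(rows)


def run_grid(
    dataset: SyntheticDataset,
    hypotheses: Iterable[str] = ("H1", "H2", "H3"),
    windows: Iterable[int] = (60, 120, 365),
    **cell_kwargs,
) -> ExperimentReport:
    """Run every requested cell over the corpus and collect a long table."""
    frames = []
    rep_sel = cell_kwargs.get("replicates")
    for h in hypotheses:
        for w in windows:
            frames.append(run_cell(ExperimentCell(h, w), dataset, **cell_kwargs))
    results = pd.concat(frames, ignore_index=True)
    truth = {
        "beta0": dataset.ground_truth.disease.beta0,
        "alpha": dataset.ground_truth.behavior.alpha,
        "lambda_p": dataset.ground_truth.behavior.lambda_p,
    }
    n_reps = len(rep_sel) if rep_sel is not None else dataset.n_reps
    return ExperimentReport(results=results, truth=truth, n_reps=n_reps)


def _paired_tests(err_a: np.ndarray, err_b: np.ndarray) -> Dict[str, float]:
    """Paired Wilcoxon signed-rank plus unpaired Mann-Whitney U on
    |relative error| vectors; identical vectors are flagged, not tested."""
    out: Dict[str, float] = {}
    if np.allclose(err_a, err_b):
        out["wilcoxon_p"] = np.nan
        out["mannwhitney_p"] = np.nan
        out["note"] = "identical"
        return out
    try:
        out["wilcoxon_p"] = float(sps.wilcoxon(err_a, err_b).pvalue)
    except ValueError:
        out["wilcoxon_p"] = np.nan
    out["mannwhitney_p"] = float(sps.mannwhitneyu(err_a, err_b).pvalue)
    out["note"] = ""
    return out


def estimate_error_stats(report: ExperimentReport) -> pd.DataFrame:
    """Stage-wise comparison of |relative error| per hypothesis x parameter.

    For every pair of stages within a hypothesis: paired two-sided Wilcoxon
    signed-rank (pairing by replicate — the same stochastic datasets underlie
    every cell) with Mann-Whitney U as an unpaired fallback, plus medians and
    the effect direction.
    """
    rows = []
    windows = sorted(report.results["window"].unique())
    for h in sorted(report.results["hypothesis"].unique()):
        params = [
            p
            for p in ("beta0", "alpha", "lambda_p")
            if p in report.cell(h, windows[0]).columns
            and report.cell(h, windows[0])[p].notna().all()
        ]
        for p in params:
            for i, wa in enumerate(windows):
                for wb in windows[i + 1 :]:
                    ea = report.rel_errors(h, wa, p)
                    eb = report.rel_errors(h, wb, p)
                    t = _paired_tests(ea, eb)
                    rows.append(
                        {
                            "hypothesis": h,
                            "parameter": p,
                            "window_a": wa,
                            "window_b": wb,
                            "median_err_a": float(np.median(ea)),
                            "median_err_b": float(np.median(eb)),
                            "direction": (
                                "a>b" if np.median(ea) > np.median(eb) else "a<=b"
                            ),
                            **t,
                        }
                    )
    return pd.DataFrame(rows)


def compare_conditions(
    report: ExperimentReport,
    param: str,
    window: int,
    hypothesis_a: str = "H3",
    hypothesis_b: str = "H1",
) -> Dict[str, float]:
    """Paired comparison of one parameter's |relative error| between two
    hypotheses at the same stage (e.g. does contact data help early?)."""
    ea = report.rel_errors(hypothesis_a, window, param)
    eb = report.rel_errors(hypothesis_b, window, param)
    out = _paired_tests(ea, eb)
    out["median_err_a"] = float(np.median(ea))
    out["median_err_b"] = float(np.median(eb))
    return out


def normalized_error_change(
    report: ExperimentReport,
    baseline: Tuple[str, int] = ("H1", 60),
    statistic: str = "mean",
) -> pd.DataFrame:
    """Per-cell % change of projection MAPE vs the early-SEIRb baseline.

    100 * (cell MAPE - baseline MAPE) / baseline MAPE, using the arithmetic
    mean of per-replicate cumulative MAPE (median via ``statistic``).  The
    baseline cell maps to 0% by construction.
    """
    agg = np.mean if statistic == "mean" else np.median
    base_df = report.cell(*baseline)
    if base_df.empty:
        raise ParameterError(f"baseline cell {baseline} missing from report")
    base = float(agg(base_df["mape"].to_numpy(dtype=float)))
    if base == 0:
        raise ZeroDivisionError("baseline projection error is zero; change undefined")
    rows = []
    for (h, w), df in report.results.groupby(["hypothesis", "window"]):
        m = float(agg(df["mape"].to_numpy(dtype=float)))
        rows.append(
            {
                "hypothesis": h,
                "window": w,
                "mean_mape": m,
                "change_pct": 100.0 * (m - base) / base,
            }
        )
    return pd.DataFrame(rows).sort_values(["hypothesis", "window"]).reset_index(
        drop=True
    )


def summarize_distributions(report: ExperimentReport) -> pd.DataFrame:
    """Bias/variance summary per cell x parameter, plot-ready long format.

    median estimate, IQR (dispersion around the median), and median relative
    bias (median estimate - truth, over truth).
    """
    rows = []
    for (h, w), df in report.results.groupby(["hypothesis", "window"]):
        for p in ("beta0", "alpha", "lambda_p"):
            if p not in df.columns or df[p].isna().any():
                continue
            est = df[p].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(est, [25, 50, 75])
            true = report.truth[p]
            rows.append(
                {
                    "hypothesis": h,
                    "window": w,
                    "parameter": p,
                    "median": med,
                    "iqr": q3 - q1,
                    "truth": true,
                    "median_rel_bias": (med - true) / true,
                }
            )
    return pd.DataFrame(rows)
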