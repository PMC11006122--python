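"""Least-squares calibration of SEIRb/SEIR models from windowed synthetic
observations, forward projection, and projection-error scoring.

Calibration mimics the situation of a modeler at day L of an outbreak:
only the first L days of (deaths, optionally contact-rate) data exist, the
masked parameters are unknown, and everything else is assumed known.  The
estimator minimizes a scale-free sum of squared residuals with a seeded
multi-start strategy (space-filling starts + bounded local refinement),
which guards against the multimodality the behavioral feedback induces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model_core import (
    BehaviorParams,
    DiseaseParams,
    ParameterError,
    ParameterSet,
    SimulationError,
    simulate,
)
from .synthetic_data import ObservedWindow

__all__ = [
    "CalibrationSpec",
    "CalibrationResult",
    "DEFAULT_BOUNDS",
    "loss",
    "fit",
    "project",
    "mape_cumulative",
]

# Generous, physically interpretable default search bounds.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "beta0": (0.05, 2.0),            # 1/day; R0 in [0.5, 20] at 10-day infectious period
    "alpha": (0.0, 1000.0),          # per (daily deaths per million)
    "lambda_p": (1.0, 365.0),        # days
    "incubation_period": (1.0, 20.0),
    "infectious_period": (1.0, 30.0),
    "ifr": (0.001, 0.1),
    "death_delay": (1.0, 30.0),
}

_DISEASE_FIELDS = set(DiseaseParams.__dataclass_fields__)
_BEHAVIOR_FIELDS = {"alpha", "lambda_p"}

# Residual value substituted when a candidate simulation blows up; acts as
# a finite +inf so the optimizer backs away.
_PENALTY = 1.0e6

# MAPE floor, deaths/day: keeps the percentage error defined on near-zero
# early-outbreak days.
MAPE_EPSILON = 0.5


@dataclass(frozen=True)
class CalibrationSpec:
    """What to estimate, from what, and how hard to search.

    model : 'SEIRb' (behavioral feedback active) or 'SEIR' (feedback off).
    free_params : names of masked parameters to estimate.  SEIR admits
        disease parameters only (canonically just beta0).
    bounds : per-parameter closed search intervals.
    n_starts : number of Latin-hypercube multi-start points.
    optimizer_seed : seed controlling start placement (full determinism).
    """

    model: str = "SEIRb"
    free_params: Tuple[str, ...] = ("beta0", "alpha", "lambda_p")
    bounds: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    n_starts: int = 16
    optimizer_seed: int = 0
    dt: float = 0.25

    def __post_init__(self):
        if self.model not in ("SEIRb", "SEIR"):
            raise ParameterError("model must be 'SEIRb' or 'SEIR'")
        if not self.free_params:
            raise ParameterError("free_params must be non-empty")
        for p in self.free_params:
            if p not in _DISEASE_FIELDS | _BEHAVIOR_FIELDS:
                raise ParameterError(f"unknown free parameter {p!r}")
            if self.model == "SEIR" and p in _BEHAVIOR_FIELDS:
                raise ParameterError("SEIR has no behavior parameters to estimate")
            lo, hi = self.bounds[p]
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ParameterError(f"bounds for {p!r} must be finite with hi > lo")
        if self.n_starts < 1:
            raise ParameterError("n_starts must be >= 1")


@dataclass
class CalibrationResult:
    """Best estimates for one replicate x one experimental condition."""

    estimates: Dict[str, float]
    loss: float
    converged: bool
    starts_tried: int
    best_start_seed: int

    def __post_init__(self):
        if self.loss < 0:
            raise ValueError("loss must be >= 0")


def _candidate_params(
    candidate: Mapping[str, float], spec: CalibrationSpec, fixed: ParameterSet
) -> Tuple[DiseaseParams, BehaviorParams]:
    """Overlay candidate values for the free parameters on the fixed truth."""
    dis_over = {k: v for k, v in candidate.items() if k in _DISEASE_FIELDS}
    beh_over = {k: v for k, v in candidate.items() if k in _BEHAVIOR_FIELDS}
    disease = replace(fixed.disease, **dis_over)
    if spec.model == "SEIR":
        behavior = BehaviorParams(alpha=0.0, lambda_p=1.0)
    else:
        behavior = replace(fixed.behavior, **beh_over)
    return disease, behavior


def _residuals(
    candidate: Mapping[str, float],
    spec: CalibrationSpec,
    observed: ObservedWindow,
    fixed: ParameterSet,
) -> np.ndarray:
    """Concatenated per-channel residual vector.

    Each channel's residuals are divided by the root-mean-square of its
    observed values, so the summed squared loss is scale-free and channels
    contribute on equal footing.
    """
    n_res = (0 if observed.deaths is None else len(observed.deaths)) + (
        0 if observed.contacts is None else len(observed.contacts)
    )
    disease, behavior = _candidate_params(candidate, spec, fixed)
    try:
        tr = simulate(disease, behavior, noise=None, horizon=observed.length, dt=spec.dt)
    except SimulationError:
        return np.full(n_res, _PENALTY)
    parts = []
    if observed.deaths is not None:
        model = tr.daily_deaths[1 : observed.length + 1]
        scale = np.sqrt(np.mean(observed.deaths**2))
        if scale == 0:
            scale = 1.0
        parts.append((model - observed.deaths) / scale)
    if observed.contacts is not None:
        model = tr.contact_multiplier[observed.contact_days]
        scale = np.sqrt(np.mean(observed.contacts**2))
        if scale == 0:
            scale = 1.0
        parts.append((model - observed.contacts) / scale)
    res = np.concatenate(parts)
    if not np.all(np.isfinite(res)):
        return np.full(n_res, _PENALTY)
    return res


def loss(
    candidate: Mapping[str, float],
    spec: CalibrationSpec,
    observed: ObservedWindow,
    fixed: ParameterSet,
) -> float:
    """Scale-free sum of squared residuals for an in-bounds candidate.

    Per channel: SSE divided by the mean square of the observed values,
    summed over channels.  Finite for any in-bounds candidate (numerical
    blow-ups are mapped to a large penalty).
    """
    if observed.deaths is None and observed.contacts is None:
        raise ParameterError("observed window is empty")
    r = _residuals(candidate, spec, observed, fixed)
    return float(np.sum(r**2))


def fit(
    spec: CalibrationSpec,
    observed: ObservedWindow,
    fixed: ParameterSet,
) -> CalibrationResult:
    """Seeded multi-start bounded least squares.

    Latin-hypercube start points in the unit cube are mapped to the bounds,
    each refined with trust-region-reflective least squares; the lowest
    loss wins.  Fully deterministic given ``spec.optimizer_seed``.
    """
    names = list(spec.free_params)
    lo = np.array([spec.bounds[p][0] for p in names])
    hi = np.array([spec.bounds[p][1] for p in names])
    span = hi - lo

    def unscale(x):
        return lo + span * x

    def fun(x):
        cand = dict(zip(names, unscale(np.clip(x, 0.0, 1.0))))
        return _residuals(cand, spec, observed, fixed)

    sampler = qmc.LatinHypercube(d=len(names), seed=spec.optimizer_seed)
    starts = sampler.random(spec.n_starts)

    best = None
    best_idx = -1
    any_converged = False
    for i, x0 in enumerate(starts):
        try:
            sol = least_squares(
                fun,
                x0,
                bounds=(0.0, 1.0),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=200 * len(names),
            )
        except Exception:
            continue
        if not np.isfinite(sol.cost):
            continue
        any_converged = any_converged or bool(sol.status > 0)
        if best is None or sol.cost < best.cost:
            best, best_idx = sol, i
    if best is None:
        raise RuntimeError(
            f"calibration failed: all {spec.n_starts} starts produced "
            "non-finite losses"
        )
    est = dict(zip(names, map(float, unscale(best.x))))
    return CalibrationResult(
        estimates=est,
        loss=float(2.0 * best.cost),  # least_squares cost is 0.5 * SSE
        converged=any_converged,
        starts_tried=spec.n_starts,
        best_start_seed=best_idx,
    )


def project(
    estimates: Mapping[str, float],
    spec: CalibrationSpec,
    fixed: ParameterSet,
    t_start: int,
    horizon: int = 365,
) -> np.ndarray:
    """Deterministic 365-day-ahead daily-deaths projection.

    Re-simulates from day 0 with the estimated (plus fixed) parameters and
    returns deaths for days t_start+1 .. t_start+horizon.
    """
    disease, behavior = _candidate_params(estimates, spec, fixed)
    tr = simulate(disease, behavior, noise=None, horizon=t_start + horizon, dt=spec.dt)
    return tr.daily_deaths[t_start + 1 : t_start + horizon + 1].copy()


def mape_cumulative(
    projected: np.ndarray, actual: np.ndarray, epsilon: float = MAPE_EPSILON
) -> float:
    """Daily mean absolute percentage error over the projection horizon, %.

    mean over days of |projected - actual| / max(actual, epsilon) * 100.
    The epsilon floor (deaths/day) keeps the metric finite on days with
    essentially zero actual deaths.
    """
    projected = np.asarray(projected, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if projected.shape != actual.shape:
        raise ValueError("projected and actual must have equal length")
    denom = np.maximum(actual, epsilon)
    return float(np.mean(np.abs(projected - actual) / denom) * 100.0)
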