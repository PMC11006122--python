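"""Core SEIRb dynamics: compartmental flows, endogenous risk response, and
autocorrelated exposure noise.

The SEIRb model extends the classical SEIR structure with a balancing
feedback loop: recorded deaths raise perceived risk, perceived risk lowers
the effective contact rate, and lower contacts suppress transmission.  The
loop is what lets a single fixed parameterization produce multiple epidemic
waves.  Two observable channels are emitted — daily recorded deaths and the
contact-rate multiplier — matching the data a modeler could plausibly obtain
(mortality surveillance and mobility-style behavior data).

State variables
---------------
S, E, I, R : susceptible / exposed / infectious / removed-recovered persons
D_pending  : persons who will die but whose deaths are not yet recorded
             (first-order recording delay of ``death_delay`` days)
D_cum      : cumulative recorded deaths
perceived_death_rate : exponentially smoothed recorded daily deaths per
             million persons; the input to the risk response

Flows (explicit Euler, step ``dt`` days)::

    exposure   = beta0 * c(perceived) * noise(t) * S * I / N
    E -> I     at rate 1/incubation_period
    I -> exit  at rate 1/infectious_period, split ifr : (1 - ifr)
               into D_pending and R
    D_pending -> D_cum at rate 1/death_delay
    d(perceived)/dt = (recorded deaths per million per day - perceived) / lambda_p

with the risk-response multiplier ``c`` either ``1/(1 + alpha*perceived)``
(default) or ``exp(-alpha*perceived)``.  ``alpha = 0`` recovers plain SEIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "DiseaseParams",
    "BehaviorParams",
    "NoiseParams",
    "ParameterSet",
    "ModelState",
    "Trajectory",
    "ParameterError",
    "StateError",
    "SimulationError",
    "pink_noise",
    "fit_correlation_time",
    "risk_response_multiplier",
    "step",
    "simulate",
    "simulate_seir",
]

# Default integration step, days. 1/dt must be an integer so that outputs
# can be sampled on exact day boundaries.
DEFAULT_DT = 0.25

RESPONSE_INVERSE_LINEAR = 0
RESPONSE_EXPONENTIAL = 1
_RESPONSE_CODES = {
    "inverse_linear": RESPONSE_INVERSE_LINEAR,
    "exponential": RESPONSE_EXPONENTIAL,
}


class ParameterError(ValueError):
    """An invalid parameter value."""


class StateError(ValueError):
    """An invalid model state (e.g. negative compartment)."""


class SimulationError(RuntimeError):
    """Numerical failure during integration; the message names the day."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseParams:
    """Disease-side parameters of the SEIRb/SEIR model.

    beta0 : baseline infectivity rate (contacts x infection probability),
        1/day.  R0 = beta0 * infectious_period.
    incubation_period : mean E->I residence time, days.
    infectious_period : mean I residence time, days.
    ifr : infection fatality ratio, fraction in (0, 1).
    death_delay : mean delay from leaving I to the death being recorded, days.
    population : total population, persons.
    initial_exposed : persons in E at day 0 (everyone else susceptible).
    """

    beta0: float = 0.25
    incubation_period: float = 4.0
    infectious_period: float = 10.0
    ifr: float = 0.01
    death_delay: float = 10.0
    population: float = 1.0e7
    initial_exposed: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "beta0",
            "incubation_period",
            "infectious_period",
            "ifr",
            "death_delay",
            "population",
            "initial_exposed",
        ):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ParameterError(f"{name} must be finite and non-negative")
        if not (0.0 < self.ifr < 1.0):
            raise ParameterError("ifr must lie in (0, 1)")
        for name in ("incubation_period", "infectious_period", "death_delay", "population"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.initial_exposed >= self.population:
            raise ParameterError("initial_exposed must be smaller than population")

    @property
    def r0(self) -> float:
        return self.beta0 * self.infectious_period


@dataclass(frozen=True)
class BehaviorParams:
    """Behavior-side parameters of the endogenous risk response.

    alpha : sensitivity to risk, per (daily deaths per million).  alpha = 0
        disables the feedback, reducing SEIRb to SEIR.
    lambda_p : time to perceive risk, days; the time constant of the
        first-order smoother that turns recorded daily deaths into
        perceived risk.
    response_form : 'inverse_linear' (default) or 'exponential'.
    """

    alpha: float = 2.0
    lambda_p: float = 60.0
    response_form: str = "inverse_linear"

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ParameterError("alpha must be finite and >= 0")
        if not np.isfinite(self.lambda_p) or self.lambda_p <= 0:
            raise ParameterError("lambda_p must be finite and > 0")
        if self.response_form not in _RESPONSE_CODES:
            raise ParameterError(
                f"response_form must be one of {sorted(_RESPONSE_CODES)}"
            )


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative autocorrelated (pink) noise on the exposure rate.

    The process is first-order exponential smoothing of i.i.d. Gaussian
    white noise with time constant ``correlation_time``; the white-noise
    standard deviation is inflated so the smoothed output has stationary
    standard deviation ``sd``.
    """

    mean: float = 1.0
    sd: float = 0.3
    correlation_time: float = 15.0
    seed: int = 0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("noise sd must be >= 0")
        if self.correlation_time <= 0:
            raise ParameterError("correlation_time must be > 0")

    def disabled(self) -> "NoiseParams":
        return replace(self, enabled=False)


@dataclass(frozen=True)
class ParameterSet:
    """A full model parameterization: disease + behavior + noise."""

    disease: DiseaseParams = field(default_factory=DiseaseParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    noise: NoiseParams = field(default_factory=NoiseParams)

    def to_dict(self) -> dict:
        d = {}
        d.update(asdict(self.disease))
        d.update(asdict(self.behavior))
        d.update({f"noise_{k}": v for k, v in asdict(self.noise).items()})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        noise_kwargs = {
            k[len("noise_"):]: d.pop(k) for k in list(d) if k.startswith("noise_")
        }
        dis_fields = {f for f in DiseaseParams.__dataclass_fields__}
        beh_fields = {f for f in BehaviorParams.__dataclass_fields__}
        dis = {k: d.pop(k) for k in list(d) if k in dis_fields}
        beh = {k: d.pop(k) for k in list(d) if k in beh_fields}
        if d:
            raise ParameterError(f"unknown parameter keys: {sorted(d)}")
        return cls(
            disease=DiseaseParams(**dis),
            behavior=BehaviorParams(**beh),
            noise=NoiseParams(**noise_kwargs),
        )


@dataclass
class ModelState:
    """Instantaneous model state (persons, except perceived risk)."""

    S: float
    E: float
    I: float
    R: float
    D_pending: float = 0.0
    D_cum: float = 0.0
    perceived_death_rate: float = 0.0  # daily deaths per million

    def total(self) -> float:
        return self.S + self.E + self.I + self.R + self.D_pending + self.D_cum

    def validate(self) -> None:
        for name in ("S", "E", "I", "R", "D_pending", "D_cum", "perceived_death_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise StateError(f"state component {name} is negative or non-finite")


@dataclass
class Trajectory:
    """Daily-sampled simulation output.

    All arrays have length ``horizon + 1`` and are indexed by day 0..horizon.
    ``daily_deaths[d]`` is the recorded deaths during day d (zero at d=0).
    ``noise`` is the exposure-noise value sampled at each day boundary.
    """

    t: np.ndarray
    daily_deaths: np.ndarray
    contact_multiplier: np.ndarray
    S: np.ndarray
    E: np.ndarray
    I: np.ndarray
    R: np.ndarray
    D_cum: np.ndarray
    noise: np.ndarray

    @property
    def horizon(self) -> int:
        return int(self.t[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.t,
                "daily_deaths": self.daily_deaths,
                "contact_multiplier": self.contact_multiplier,
                "S": self.S,
                "E": self.E,
                "I": self.I,
                "R": self.R,
                "D_cum": self.D_cum,
                "noise": self.noise,
            }
        )

    @classmethod
    def from_frame(cls, df) -> "Trajectory":
        return cls(
            t=df["day"].to_numpy(dtype=np.int64),
            daily_deaths=df["daily_deaths"].to_numpy(dtype=float),
            contact_multiplier=df["contact_multiplier"].to_numpy(dtype=float),
            S=df["S"].to_numpy(dtype=float),
            E=df["E"].to_numpy(dtype=float),
            I=df["I"].to_numpy(dtype=float),
            R=df["R"].to_numpy(dtype=float),
            D_cum=df["D_cum"].to_numpy(dtype=float),
            noise=df["noise"].to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# Pink noise
# ---------------------------------------------------------------------------


def pink_noise(
    params: NoiseParams, horizon: float, dt: float = DEFAULT_DT
) -> np.ndarray:
    """Autocorrelated multiplicative noise series, one value per Euler step.

    First-order exponential smoothing of Gaussian white noise with time
    constant ``correlation_time``:  v <- v + (dt/T) * (w - v).  The white
    noise is drawn with sd ``params.sd * sqrt(2T/dt - 1)`` so the smoothed
    output has stationary sd ~= ``params.sd``; the series starts at the
    stationary mean.

    Returns an array of length ``round(horizon/dt) + 1`` (one value per step
    boundary, including t=0).
    """
    if horizon < 1:
        raise ParameterError("horizon must be >= 1 day")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if params.correlation_time <= 0:
        raise ParameterError("correlation_time must be > 0")
    n_steps = int(round(horizon / dt))
    if not params.enabled or params.sd == 0:
        return np.full(n_steps + 1, params.mean, dtype=float)
    a = dt / params.correlation_time
    if a >= 2:
        raise ParameterError("dt must be smaller than 2*correlation_time")
    input_sd = params.sd * np.sqrt(2.0 * params.correlation_time / dt - 1.0)
    rng = np.random.default_rng(params.seed)
    w = rng.normal(params.mean, input_sd, size=n_steps)
    # recursion v[k+1] = v[k] + a*(w[k] - v[k]) as an IIR filter
    from scipy.signal import lfilter

    v = np.empty(n_steps + 1, dtype=float)
    v[0] = params.mean
    v[1:] = params.mean + lfilter([a], [1.0, -(1.0 - a)], w - params.mean, zi=[0.0])[0]
    return v


def fit_correlation_time(series: np.ndarray, max_lag: int = 15) -> tuple:
    """Estimate the exponential decay constant of a series' autocorrelation.

    Log-linear least squares of the empirical autocorrelation over lags
    1..max_lag (about one time constant, where the estimate is precise).
    Returns (time_constant_days, r_squared).
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    ac = np.array([np.dot(x[:-k], x[k:]) / denom for k in range(1, max_lag + 1)])
    if np.any(ac <= 0):
        raise ValueError("autocorrelation non-positive within the fit range")
    lags = np.arange(1, max_lag + 1, dtype=float)
    y = np.log(ac)
    slope, intercept = np.polyfit(lags, y, 1)
    pred = slope * lags + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return -1.0 / slope, r2


# ---------------------------------------------------------------------------
# Risk response
# ---------------------------------------------------------------------------


def risk_response_multiplier(
    perceived_death_rate: float, behavior: BehaviorParams
) -> float:
    """Contact-rate multiplier in (0, 1] as a function of perceived risk.

    inverse_linear: 1 / (1 + alpha * perceived);  exponential:
    exp(-alpha * perceived).  Both equal 1 at zero perceived risk and are
    strictly decreasing when alpha > 0.
    """
    if perceived_death_rate < 0:
        raise ParameterError("perceived_death_rate must be >= 0")
    if behavior.response_form == "exponential":
        return float(np.exp(-behavior.alpha * perceived_death_rate))
    return 1.0 / (1.0 + behavior.alpha * perceived_death_rate)


# ---------------------------------------------------------------------------
# Integration kernel
# ---------------------------------------------------------------------------
# The kernel carries hooks for the structural sensitivity variants
# (seasonality, waning immunity, variant emergence).  With amplitude 0,
# waning rate 0 and beta multiplier 1 the extra terms are exact identities,
# so the base model is reproduced bit-for-bit.


@njit(cache=True)
def _integrate(
    n_days,
    steps_per_day,
    dt,
    beta0,
    incubation,
    infectious,
    ifr,
    death_delay,
    population,
    alpha,
    lambda_p,
    response_code,
    noise,  # per-step array, length n_days*steps_per_day + 1
    S0,
    E0,
    I0,
    season_amp,
    season_period,
    waning_rate,
    variant_day,
    variant_mult,
):
    n_out = n_days + 1
    S_out = np.empty(n_out)
    E_out = np.empty(n_out)
    I_out = np.empty(n_out)
    R_out = np.empty(n_out)
    D_out = np.empty(n_out)
    P_out = np.empty(n_out)
    c_out = np.empty(n_out)
    noise_out = np.empty(n_out)
    perc_out = np.empty(n_out)

    S = S0
    E = E0
    I = I0
    R = 0.0
    P = 0.0
    D = 0.0
    perc = 0.0

    S_out[0] = S
    E_out[0] = E
    I_out[0] = I
    R_out[0] = R
    D_out[0] = D
    P_out[0] = P
    c_out[0] = 1.0
    noise_out[0] = noise[0]
    perc_out[0] = 0.0

    failed_day = -1
    for d in range(n_days):
        for s in range(steps_per_day):
            k = d * steps_per_day + s
            t = k * dt
            if response_code == 1:
                c = np.exp(-alpha * perc)
            else:
                c = 1.0 / (1.0 + alpha * perc)
            beta = beta0
            if t >= variant_day:
                beta = beta * variant_mult
            season = 1.0 + season_amp * np.sin(2.0 * np.pi * t / season_period)
            exposure = beta * season * c * noise[k] * S * I / population
            e_out_flow = E / incubation
            i_out_flow = I / infectious
            record_rate = P / death_delay
            waning_flow = waning_rate * R

            S += dt * (-exposure + waning_flow)
            E += dt * (exposure - e_out_flow)
            I += dt * (e_out_flow - i_out_flow)
            P += dt * (ifr * i_out_flow - record_rate)
            R += dt * ((1.0 - ifr) * i_out_flow - waning_flow)
            D += dt * record_rate
            perc += dt * ((record_rate / population * 1.0e6) - perc) / lambda_p

            if S < 0.0:
                S = 0.0
            if E < 0.0:
                E = 0.0
            if I < 0.0:
                I = 0.0
            if P < 0.0:
                P = 0.0
            if perc < 0.0:
                perc = 0.0
            if not (
                np.isfinite(S)
                and np.isfinite(E)
                and np.isfinite(I)
                and np.isfinite(R)
                and np.isfinite(P)
                and np.isfinite(D)
                and np.isfinite(perc)
            ):
                failed_day = d + 1
                break
        if failed_day >= 0:
            break
        idx = (d + 1) * steps_per_day
        if response_code == 1:
            c_now = np.exp(-alpha * perc)
        else:
            c_now = 1.0 / (1.0 + alpha * perc)
        S_out[d + 1] = S
        E_out[d + 1] = E
        I_out[d + 1] = I
        R_out[d + 1] = R
        D_out[d + 1] = D
        P_out[d + 1] = P
        c_out[d + 1] = c_now
        noise_out[d + 1] = noise[idx]
        perc_out[d + 1] = perc

    return (
        S_out,
        E_out,
        I_out,
        R_out,
        D_out,
        P_out,
        c_out,
        noise_out,
        perc_out,
        failed_day,
    )


def step(
    state: ModelState,
    disease: DiseaseParams,
    behavior: BehaviorParams,
    noise_value: float = 1.0,
    dt: float = DEFAULT_DT,
) -> ModelState:
    """One explicit-Euler step of the SEIRb flow equations.

    Pure-Python reference used for unit-level checks; `simulate` runs the
    same arithmetic in a compiled loop.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    state.validate()
    N = disease.population
    c = risk_response_multiplier(state.perceived_death_rate, behavior)
    exposure = disease.beta0 * c * noise_value * state.S * state.I / N
    e_out = state.E / disease.incubation_period
    i_out = state.I / disease.infectious_period
    record_rate = state.D_pending / disease.death_delay
    new = ModelState(
        S=state.S + dt * (-exposure),
        E=state.E + dt * (exposure - e_out),
        I=state.I + dt * (e_out - i_out),
        R=state.R + dt * (1.0 - disease.ifr) * i_out,
        D_pending=state.D_pending + dt * (disease.ifr * i_out - record_rate),
        D_cum=state.D_cum + dt * record_rate,
        perceived_death_rate=state.perceived_death_rate
        + dt
        * ((record_rate / N * 1.0e6) - state.perceived_death_rate)
        / behavior.lambda_p,
    )
    for name in ("S", "E", "I", "D_pending", "perceived_death_rate"):
        if getattr(new, name) < 0:
            setattr(new, name, 0.0)
    return new


def _steps_per_day(dt: float) -> int:
    spd = 1.0 / dt
    if abs(spd - round(spd)) > 1e-9:
        raise ParameterError("1/dt must be an integer so days can be sampled")
    return int(round(spd))


def simulate(
    disease: DiseaseParams,
    behavior: BehaviorParams,
    noise: Optional[NoiseParams] = None,
    horizon: int = 730,
    dt: float = DEFAULT_DT,
    *,
    _variant=None,
) -> Trajectory:
    """Integrate the SEIRb model and return a daily-sampled Trajectory.

    With ``noise=None`` or noise disabled the run is the deterministic
    SEIRb used during calibration.  Raises SimulationError naming the
    day if the state becomes non-finite.
    """
    if horizon < 1:
        raise ParameterError("horizon must be >= 1 day")
    spd = _steps_per_day(dt)
    n_days = int(horizon)
    if noise is None:
        noise = NoiseParams(enabled=False, sd=0.0)
    noise_series = pink_noise(noise, n_days, dt)

    if _variant is None:
        season_amp, season_period = 0.0, 365.0
        waning_rate = 0.0
        variant_day, variant_mult = float(n_days + 1), 1.0
    else:
        season_amp, season_period, waning_rate, variant_day, variant_mult = _variant

    (S, E, I, R, D, P, c, nz, perc, failed_day) = _integrate(
        n_days,
        spd,
        dt,
        disease.beta0,
        disease.incubation_period,
        disease.infectious_period,
        disease.ifr,
        disease.death_delay,
        disease.population,
        behavior.alpha,
        behavior.lambda_p,
        _RESPONSE_CODES[behavior.response_form],
        noise_series,
        disease.population - disease.initial_exposed,
        disease.initial_exposed,
        0.0,
        season_amp,
        season_period,
        waning_rate,
        variant_day,
        variant_mult,
    )
    if failed_day >= 0:
        raise SimulationError(f"non-finite state on day {failed_day}")
    daily_deaths = np.empty(n_days + 1)
    daily_deaths[0] = 0.0
    daily_deaths[1:] = np.diff(D)
    np.maximum(daily_deaths, 0.0, out=daily_deaths)
    return Trajectory(
        t=np.arange(n_days + 1, dtype=np.int64),
        daily_deaths=daily_deaths,
        contact_multiplier=c,
        S=S,
        E=E,
        I=I,
        R=R + P,  # pending deaths counted with removed for conservation display
        D_cum=D,
        noise=nz,
    )


def simulate_seir(
    disease: DiseaseParams,
    horizon: int = 730,
    dt: float = DEFAULT_DT,
    noise: Optional[NoiseParams] = None,
) -> Trajectory:
    """Plain SEIR run: the behavioral feedback switched off (alpha = 0)."""
    return simulate(
        disease,
        BehaviorParams(alpha=0.0, lambda_p=1.0),
        noise=noise,
        horizon=horizon,
        dt=dt,
    )
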