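"""Ground-truth corpus generation: replicated stochastic SEIRb runs and
windowed views of their observable channels.

The study design calls for a corpus of stochastic realizations of the same
ground-truth parameterization (default: 100 replicates over 730 days, noise
differing only by seed), from which calibration experiments draw truncated
"observation windows" of the two observable channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import (
    NoiseParams,
    ParameterError,
    ParameterSet,
    SimulationError,
    Trajectory,
    simulate,
)

__all__ = [
    "SyntheticDataset",
    "DataWindow",
    "ObservedWindow",
    "generate",
    "window",
    "subsample_contacts",
]

CHANNELS = ("daily_deaths", "contact_multiplier")
STANDARD_WINDOWS = (60, 120, 365)


@dataclass(frozen=True)
class DataWindow:
    """A windowed view request: which replicate, which channels, how long."""

    replicate_id: int
    length: int
    channels: tuple = CHANNELS

    def __post_init__(self):
        if not self.channels:
            raise ParameterError("channels must be non-empty")
        for c in self.channels:
            if c not in CHANNELS:
                raise KeyError(f"unknown channel {c!r}")
        if self.length < 1:
            raise ParameterError("window length must be >= 1 day")


@dataclass
class ObservedWindow:
    """Observed series handed to the calibrator.

    ``deaths[i]`` / ``contacts[i]`` are the observations for day i+1
    (day 0 carries no recorded deaths).  ``contact_days`` holds the day
    numbers of the contact observations; for a dense window it is simply
    1..length, for a subsampled one a sorted subset.
    """

    length: int
    deaths: Optional[np.ndarray] = None
    contacts: Optional[np.ndarray] = None
    contact_days: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.deaths is None and self.contacts is None:
            raise ParameterError("observed window has no channels")
        if self.contacts is not None and self.contact_days is None:
            self.contact_days = np.arange(1, len(self.contacts) + 1)


@dataclass
class SyntheticDataset:
    """The ground-truth corpus: replicate trajectories plus provenance."""

    replicates: list  # list[Trajectory]
    seeds: list
    ground_truth: ParameterSet
    horizon: int

    def __post_init__(self):
        if len(self.replicates) != len(self.seeds):
            raise ParameterError("replicates and seeds must align")

    @property
    def n_reps(self) -> int:
        return len(self.replicates)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "ground_truth": self.ground_truth.to_dict(),
            "seeds": list(map(int, self.seeds)),
            "horizon": int(self.horizon),
            "n_reps": self.n_reps,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for i, tr in enumerate(self.replicates):
            tr.to_frame().to_csv(out / f"replicate_{i:03d}.csv", index=False)

    @classmethod
    def load(cls, in_dir) -> "SyntheticDataset":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        reps = [
            Trajectory.from_frame(pd.read_csv(src / f"replicate_{i:03d}.csv"))
            for i in range(manifest["n_reps"])
        ]
        return cls(
            replicates=reps,
            seeds=manifest["seeds"],
            ground_truth=ParameterSet.from_dict(manifest["ground_truth"]),
            horizon=manifest["horizon"],
        )


def generate(
    ground_truth: Optional[ParameterSet] = None,
    n_reps: int = 100,
    horizon: int = 730,
    base_seed: int = 0,
    dt: float = 0.25,
) -> SyntheticDataset:
    """Simulate ``n_reps`` stochastic SEIRb replicates.

    Replicate i uses noise seed ``base_seed + i``; everything else is shared,
    so the corpus is fully reproducible from (ground_truth, base_seed).
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    gt = ground_truth if ground_truth is not None else ParameterSet()
    reps, seeds = [], []
    for i in range(n_reps):
        seed = int(base_seed) + i
        noise = replace(gt.noise, seed=seed)
        try:
            tr = simulate(gt.disease, gt.behavior, noise, horizon=horizon, dt=dt)
        except SimulationError as exc:
            raise SimulationError(f"replicate {i} (seed {seed}): {exc}") from exc
        reps.append(tr)
        seeds.append(seed)
    return SyntheticDataset(
        replicates=reps,
        seeds=seeds,
        ground_truth=gt,
        horizon=int(horizon),
    )


def window(dataset: SyntheticDataset, spec: DataWindow) -> ObservedWindow:
    """Truncate the requested channels to the first ``spec.length`` days.

    Day d observations are ``channel[d]`` for d = 1..length; the corpus is
    not mutated.
    """
    if not (0 <= spec.replicate_id < dataset.n_reps):
        raise KeyError(f"unknown replicate {spec.replicate_id}")
    if spec.length > dataset.horizon:
        raise ParameterError("window length exceeds corpus horizon")
    tr = dataset.replicates[spec.replicate_id]
    deaths = contacts = None
    if "daily_deaths" in spec.channels:
        deaths = tr.daily_deaths[1 : spec.length + 1].copy()
    if "contact_multiplier" in spec.channels:
        contacts = tr.contact_multiplier[1 : spec.length + 1].copy()
    return ObservedWindow(length=spec.length, deaths=deaths, contacts=contacts)


def subsample_contacts(
    obs: ObservedWindow, n_obs: int, seed: int
) -> ObservedWindow:
    """Thin the contact channel to ``n_obs`` days drawn uniformly without
    replacement (sorted by day); the deaths channel is left untouched.

    ``n_obs = 0`` removes the contact channel entirely (deaths-only window).
    """
    if obs.contacts is None:
        raise ParameterError("window has no contact channel to subsample")
    total = len(obs.contacts)
    if not (0 <= n_obs <= total):
        raise ParameterError(f"n_obs must be in [0, {total}]")
    if n_obs == total:
        return obs
    if n_obs == 0:
        if obs.deaths is None:
            raise ParameterError("removing contacts would leave an empty window")
        return ObservedWindow(length=obs.length, deaths=obs.deaths)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(total, size=n_obs, replace=False))
    return ObservedWindow(
        length=obs.length,
        deaths=obs.deaths,
        contacts=obs.contacts[keep],
        contact_days=obs.contact_days[keep],
    )
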