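"""Synthetic fluorometry data with controlled noise.

Replaces the wet-lab measurements with seeded generators for the two data
shapes the pipeline consumes:

* replicate fluorescence time courses over 0–15 min following a polynomial
  or two-component-linear dynamics model, with additive Gaussian noise
  (default sigma = 5 relative units, n = 4 replicates), and
* C-1193 concentration–response tables following the Hill inhibition law
  F = Fmax / (1 + (C/Ki)^n) over 0.001–100 uM, with multiplicative
  Gaussian noise (default CV 5%, n = 7 replicates).

A single integer seed governs all randomness; per-replicate substreams are
spawned deterministically from it, so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import LinearModel, PolyModel, Trajectory
from .hfpn import T_MAX, logger

ADDITIVE = "additive_gaussian"
MULTIPLICATIVE = "multiplicative_gaussian"

#: default inhibitor concentrations, molar (0.001–100 uM in decade steps)
DEFAULT_CONCENTRATIONS_M = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)
#: default time-series noise, relative fluorescence units (x1000)
DEFAULT_SIGMA = 5.0
#: default dose-response noise, coefficient of variation
DEFAULT_CV = 0.05
#: default replicate counts
DEFAULT_N_TIMESERIES = 4
DEFAULT_N_DOSERESPONSE = 7


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = ADDITIVE
    sigma: float = DEFAULT_SIGMA  # units for additive, CV for multiplicative
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (ADDITIVE, MULTIPLICATIVE):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class HillLaw:
    """Ideal concentration-response law F(C) = Fmax / (1 + (C/Ki)^n)."""

    fmax: float = 1000.0
    ki: float = 5.5e-9    # molar
    n: float = 1.0

    def __call__(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.fmax / (1.0 + (conc / self.ki) ** self.n)


ModelLike = "PolyModel | tuple[LinearModel, LinearModel] | HillLaw"


@dataclass(frozen=True)
class GenSpec:
    """What to generate: model, grid, replicate count, labels."""

    model: object  # PolyModel, (early, late) LinearModel pair, or HillLaw
    time_grid: np.ndarray | None = None            # minutes, for time series
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_M  # molar
    n_replicates: int = DEFAULT_N_TIMESERIES
    observable: str = "obs"
    condition: str = "control"
    #: clamp generated values at 0 (fluorescence amounts are physically
    #: non-negative); off by default so noiseless samples follow the model
    #: exactly, including fitted intercepts below zero
    clamp_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.time_grid is not None:
            g = np.asarray(self.time_grid, dtype=float)
            if len(g) and (g[0] < 0 or g[-1] > T_MAX):
                raise ValueError(f"time grid must lie within [0, {T_MAX}] min")
            object.__setattr__(self, "time_grid", g)


def _eval_model(model, t: np.ndarray) -> np.ndarray:
    if isinstance(model, tuple):  # two-component linearization
        early, late = model
        bp = early.interval[1]
        return np.where(t <= bp, early(t), late(t))
    return np.asarray(model(t), dtype=float)


def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _apply_noise(values: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.sigma == 0:
        return values.copy()
    eps = rng.normal(size=values.shape)
    if noise.kind == ADDITIVE:
        return values + noise.sigma * eps
    return values * (1.0 + noise.sigma * eps)


def gen_timeseries(spec: GenSpec, noise: NoiseSpec) -> list[Trajectory]:
    """Generate ``n_replicates`` noisy trajectories of the spec's model."""
    if spec.time_grid is None:
        raise ValueError("GenSpec.time_grid is required for time series")
    clean = _eval_model(spec.model, spec.time_grid)
    out: list[Trajectory] = []
    for i, rng in enumerate(_replicate_rngs(noise.seed, spec.n_replicates)):
        vals = _apply_noise(clean, noise, rng)
        if spec.clamp_at_zero:
            n_clamped = int((vals < 0).sum())
            if n_clamped:
                logger.info("replicate %d: clamped %d sample(s) at 0", i, n_clamped)
            vals = np.maximum(vals, 0.0)
        out.append(Trajectory(observable=spec.observable, condition=spec.condition,
                              times=spec.time_grid, values=vals, replicate=i))
    return out


def gen_doseresponse(spec: GenSpec, noise: NoiseSpec) -> pd.DataFrame:
    """Generate a dose-response table (columns concentration_M, F, replicate).

    Each replicate gets a zero-inhibitor row carrying its Fmax reference,
    followed by one noisy row per concentration. The Fmax row is the
    normalization reference of the Hill transform and is recorded
    noise-free; the measurement noise applies to the responses at the
    inhibitor concentrations.
    """
    law = spec.model
    if not isinstance(law, HillLaw):
        raise ValueError("GenSpec.model must be a HillLaw for dose-response generation")
    conc = np.asarray(spec.concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if law.fmax <= 0:
        raise ValueError("Fmax must be positive")
    rows = []
    for i, rng in enumerate(_replicate_rngs(noise.seed, spec.n_replicates)):
        vals = np.concatenate([[law.fmax], _apply_noise(law(conc), noise, rng)])
        for c, f in zip(np.concatenate([[0.0], conc]), vals):
            rows.append({"concentration_M": c, "F": float(f), "replicate": i})
    return pd.DataFrame(rows, columns=["concentration_M", "F", "replicate"])
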