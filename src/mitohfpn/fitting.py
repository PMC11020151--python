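"""Least-squares fitting of fluorescence trajectories.

Implements the model forms used throughout the pipeline: single polynomials
of degree 1–4, the two-component linearization around a 2.5-min breakpoint,
analytic differentiation, replicate aggregation (mean ± SE), and extraction
of initial velocities (V0) from the fitted models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import polynomial as npoly


@dataclass(frozen=True)
class PolyModel:
    """Polynomial dynamics model F(t) = c0 + c1*t + ... + cd*t**d.

    Coefficients are in ascending order; t in minutes; F in relative
    fluorescence units (x1000), or mV for the electric potential.
    ``r_squared`` is present only on models produced by fitting.
    """

    coefficients: tuple[float, ...]
    r_squared: float | None = None
    valid_interval: tuple[float, float] = (0.0, 15.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t):
        return npoly.polyval(np.asarray(t, dtype=float), self.coefficients)

    def derivative(self) -> "PolyModel":
        d = npoly.polyder(self.coefficients)
        if len(d) == 0:
            d = np.zeros(1)
        return PolyModel(coefficients=tuple(d), valid_interval=self.valid_interval)

    def antiderivative(self, constant: float = 0.0) -> "PolyModel":
        return PolyModel(coefficients=tuple(npoly.polyint(self.coefficients, k=constant)),
                         valid_interval=self.valid_interval)


@dataclass(frozen=True)
class LinearModel:
    """A fitted line on a time subinterval."""

    slope: float
    intercept: float
    interval: tuple[float, float] = (0.0, 15.0)
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not self.interval[0] < self.interval[1]:
            raise ValueError(f"interval {self.interval} must have t_lo < t_hi")

    def __call__(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.intercept


@dataclass(frozen=True)
class Trajectory:
    """One observable's sampled time course for one condition/replicate."""

    observable: str
    condition: str
    times: np.ndarray
    values: np.ndarray
    replicate: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if len(t) and (t[0] < 0 or t[-1] > 15.0):
            raise ValueError("times must lie within [0, 15] min")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    # residuals at round-off scale (constant or exactly-reproduced data)
    # count as a perfect fit; the ratio below is meaningless there
    if ss_res <= 1e-28 * (1.0 + float(np.sum(y * y))):
        return 1.0
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_polynomial(traj: Trajectory, degree: int) -> PolyModel:
    """Ordinary least-squares polynomial fit of the requested degree."""
    if not 1 <= degree <= 4:
        raise ValueError(f"degree must be in 1..4, got {degree}")
    needed = degree + 2
    if len(traj) < needed:
        raise ValueError(
            f"degree-{degree} fit needs at least {needed} samples, got {len(traj)}")
    coeffs = npoly.polyfit(traj.times, traj.values, degree)
    model = PolyModel(coefficients=tuple(coeffs),
                      valid_interval=(float(traj.times[0]), float(traj.times[-1])))
    return replace(model, r_squared=_r_squared(traj.values, model(traj.times)))


def differentiate(model: PolyModel) -> PolyModel:
    """Analytic derivative (the transition's activation speed)."""
    if model.degree < 1:
        return PolyModel(coefficients=(0.0,), valid_interval=model.valid_interval)
    return model.derivative()


def _fit_line(t: np.ndarray, v: np.ndarray, interval: tuple[float, float]) -> LinearModel:
    c = npoly.polyfit(t, v, 1)
    model = LinearModel(slope=float(c[1]), intercept=float(c[0]), interval=interval)
    return replace(model, r_squared=_r_squared(v, model(t)))


def two_component_fit(traj: Trajectory, breakpoint: float = 2.5) -> tuple[LinearModel, LinearModel]:
    """Independent least-squares lines on t <= breakpoint and t > breakpoint.

    The breakpoint sample belongs to the early interval; no continuity is
    imposed at the breakpoint (the two components are fitted separately).
    """
    early = traj.times <= breakpoint
    late = ~early
    for mask, name in ((early, f"[{traj.times[0] if len(traj) else 0}, {breakpoint}]"),
                       (late, f"({breakpoint}, {traj.times[-1] if len(traj) else 15}]")):
        if int(mask.sum()) < 3:
            raise ValueError(f"two-component fit needs >= 3 samples in interval {name}, "
                             f"got {int(mask.sum())}")
    lo = float(traj.times[0])
    hi = float(traj.times[-1])
    return (
        _fit_line(traj.times[early], traj.values[early], (lo, breakpoint)),
        _fit_line(traj.times[late], traj.values[late], (breakpoint, hi)),
    )


@dataclass(frozen=True)
class VelocityReport:
    """Initial velocities of NO synthesis, Ca2+ accumulation and energization.

    V0_NO is the slope of the NO (DAF-FM) linear model; V0_Ca the slope of
    the early-interval (0–2.5 min) Fluo-4 component; V0_EP the derivative of
    the EP polynomial at t = 0. The three quantities are reported side by
    side, descriptively; no arithmetic identity among them is asserted.
    """

    condition: str
    V0_NO: float
    V0_Ca: float
    V0_EP: float
    provenance: dict[str, str]


def initial_velocities(
    condition: str,
    no_model: LinearModel | None,
    ca_early_model: LinearModel | None,
    ep_model: PolyModel | None,
) -> VelocityReport:
    """Extract the three initial velocities from fitted models."""
    missing = [name for name, m in
               (("NO linear model", no_model),
                ("early-interval Ca linear model", ca_early_model),
                ("EP polynomial", ep_model)) if m is None]
    if missing:
        raise ValueError("missing fitted model(s): " + ", ".join(missing))
    return VelocityReport(
        condition=condition,
        V0_NO=no_model.slope,
        V0_Ca=ca_early_model.slope,
        V0_EP=float(differentiate(ep_model)(0.0)),
        provenance={
            "V0_NO": f"slope of NO_DAFFM line on [{no_model.interval[0]}, {no_model.interval[1]}] min",
            "V0_Ca": f"slope of early Fluo-4 component on [{ca_early_model.interval[0]}, {ca_early_model.interval[1]}] min",
            "V0_EP": "derivative of the EP polynomial at t = 0",
        },
    )


def aggregate_replicates(trajs: list[Trajectory]) -> tuple[Trajectory, np.ndarray]:
    """Pointwise mean trajectory and standard error across replicates.

    All replicates must share the same time grid; SE = sd / sqrt(n) with the
    n−1 (sample) variance convention.
    """
    if len(trajs) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    grid = trajs[0].times
    for tr in trajs[1:]:
        if len(tr.times) != len(grid) or not np.allclose(tr.times, grid):
            raise ValueError(
                f"replicate {tr.replicate!r} time grid does not match replicate "
                f"{trajs[0].replicate!r}")
    stack = np.vstack([tr.values for tr in trajs])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    out = Trajectory(observable=trajs[0].observable, condition=trajs[0].condition,
                     times=grid, values=mean, replicate=None)
    return out, se
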