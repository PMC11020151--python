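"""Hill-coordinate estimation of the apparent inhibition constant (Ki).

For an ideal inhibition law F = Fmax / (1 + (C/Ki)^n), the transform

    y = -log10((Fmax - F) / F),   x = -log10(C)

linearizes the dose-response to y = n*x + n*log10(Ki): the slope is the
Hill coefficient and the x-intercept is -log10(Ki) (the half-maximal
point), so Ki = 10**(-x_intercept). Replicate fits with R^2 <= 0.9 are
discarded; the surviving Ki values are aggregated as mean ± SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .hfpn import logger

R2_FILTER = 0.9

#: dose-response table columns: concentration in molar, fluorescence in
#: relative units, integer replicate id; the concentration == 0 row of each
#: replicate carries that replicate's Fmax measurement
DOSE_COLUMNS = ("concentration_M", "F", "replicate")


def hill_transform(F, Fmax, conc):
    """Map one measurement to Hill coordinates (x, y).

    Requires 0 < F < Fmax and conc > 0; violations raise (batch handling
    with row rejection lives in :func:`estimate_ki`).
    """
    F = np.asarray(F, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentration must be positive")
    if np.any(F <= 0) or np.any(F >= Fmax):
        raise ValueError("F must lie strictly between 0 and Fmax")
    y = -np.log10((Fmax - F) / F)
    x = -np.log10(conc)
    if np.ndim(F) == 0 and np.ndim(conc) == 0:
        return float(x), float(y)
    return x, y


@dataclass(frozen=True)
class ReplicateFit:
    replicate: int
    ki: float           # molar
    hill_slope: float
    r_squared: float
    n_points: int
    accepted: bool


@dataclass(frozen=True)
class KiEstimate:
    """Aggregated apparent inhibition constant across replicates."""

    ki: float            # molar, mean over accepted replicates
    ki_se: float         # molar
    hill_slope: float    # mean over accepted replicates
    r_squared: float     # mean over accepted replicates
    n_replicates: int    # accepted count
    per_replicate: tuple[ReplicateFit, ...]

    @property
    def ki_nM(self) -> float:
        return self.ki * 1e9

    @property
    def ki_se_nM(self) -> float:
        return self.ki_se * 1e9


def _replicate_fmax(group: pd.DataFrame, replicate) -> float:
    zero = group[group["concentration_M"] == 0.0]
    if len(zero):
        return float(zero["F"].iloc[0])
    raise ValueError(f"replicate {replicate!r} has no zero-inhibitor (Fmax) row")


def estimate_ki(data: pd.DataFrame) -> KiEstimate:
    """Estimate Ki from a dose-response table (columns ``DOSE_COLUMNS``).

    Per replicate: Fmax is taken from that replicate's zero-inhibitor row;
    rows with F outside (0, Fmax) are dropped with a logged count (the
    transform is undefined there, and truncating would bias the fit); the
    remaining points are fitted by least squares in Hill coordinates. At
    least 3 transformable rows per replicate are required. Replicates with
    R^2 <= 0.9 are excluded from the aggregate; if none survive, an error
    lists the per-replicate R^2 values.
    """
    missing = [c for c in DOSE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"dose-response table lacks column(s): {missing}")

    fits: list[ReplicateFit] = []
    for rep, group in data.groupby("replicate", sort=True):
        fmax = _replicate_fmax(group, rep)
        rows = group[group["concentration_M"] > 0.0]
        ok = (rows["F"] > 0.0) & (rows["F"] < fmax)
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("replicate %r: dropped %d row(s) with F outside (0, Fmax)",
                        rep, n_dropped)
        rows = rows[ok]
        if len(rows) < 3:
            raise ValueError(
                f"replicate {rep!r} has {len(rows)} transformable rows; need >= 3")
        x, y = hill_transform(rows["F"].to_numpy(), fmax, rows["concentration_M"].to_numpy())
        b, a = npoly.polyfit(x, y, 1)  # y = a*x + b
        yhat = a * x + b
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot else 1.0
        # x-intercept -b/a is -log10(Ki)
        ki = float(10.0 ** (b / a))
        fits.append(ReplicateFit(replicate=int(rep), ki=ki, hill_slope=float(a),
                                 r_squared=r2, n_points=len(rows),
                                 accepted=r2 > R2_FILTER))

    accepted = [f for f in fits if f.accepted]
    if not accepted:
        detail = ", ".join(f"replicate {f.replicate}: R^2={f.r_squared:.3f}" for f in fits)
        raise ValueError(f"all replicates failed the R^2 > {R2_FILTER} filter ({detail})")
    kis = np.array([f.ki for f in accepted])
    se = float(kis.std(ddof=1) / np.sqrt(len(kis))) if len(kis) > 1 else 0.0
    return KiEstimate(
        ki=float(kis.mean()),
        ki_se=se,
        hill_slope=float(np.mean([f.hill_slope for f in accepted])),
        r_squared=float(np.mean([f.r_squared for f in accepted])),
        n_replicates=len(accepted),
        per_replicate=tuple(fits),
    )
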