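"""Ensemble-level scaling fits.

Compact aggregates obey R_g ~ N^nu and, because the graph diameter grows
linearly with spatial extent, the shifted power law (D + 1) ~ N^nu.  The
reference exponents bracketing compact folding in 3D are nu_SF = 1/3
(space filling) and nu_RW = 3/5 (self-avoiding random walk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScalingFit",
    "LinearFit",
    "fit_power_law",
    "fit_diameter_scaling",
    "fit_diameter_vs_rg",
    "NU_SPACE_FILLING",
    "NU_SELF_AVOIDING",
]

#: Space-filling (maximally dense) aggregate exponent in 3D.
NU_SPACE_FILLING = 1.0 / 3.0
#: Self-avoiding random walk exponent in 3D.
NU_SELF_AVOIDING = 3.0 / 5.0


@dataclass
class ScalingFit:
    """Power-law fit y ~ prefactor * N^exponent from log-log OLS."""

    exponent: float
    prefactor: float
    stderr_exponent: float
    n_points: int
    nu_space_filling: float = NU_SPACE_FILLING
    nu_self_avoiding: float = NU_SELF_AVOIDING


@dataclass
class LinearFit:
    """Ordinary least-squares line y = slope * x + intercept."""

    slope: float
    intercept: float
    stderr_slope: float
    n_points: int


def fit_power_law(N_values, y_values) -> ScalingFit:
    """OLS of log y on log N; the slope is the scaling exponent.

    Raises
    ------
    ValueError
        On nonpositive y values or fewer than 3 distinct N.
    """
    n = np.asarray(N_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if n.shape != y.shape:
        raise ValueError("N_values and y_values must have equal length")
    if np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive y values")
    if np.any(n <= 0):
        raise ValueError("power-law fit requires strictly positive N values")
    if np.unique(n).size < 3:
        raise ValueError("need at least 3 distinct N values")
    res = stats.linregress(np.log(n), np.log(y))
    return ScalingFit(
        exponent=float(res.slope),
        prefactor=float(np.exp(res.intercept)),
        stderr_exponent=float(res.stderr),
        n_points=int(n.size),
    )


def fit_diameter_scaling(ensemble: pd.DataFrame) -> ScalingFit:
    """Fit (D + 1) ~ N^nu to realization-averaged diameters.

    ``ensemble`` needs columns ``N`` and ``diameter`` (one row per run);
    diameters are averaged across realizations per chain length *before*
    the log-log fit.  The +1 shift handles the shortest chains (N = 2 has
    D = 1) and is the form under which the scaling is algebraic.
    """
    if not {"N", "diameter"}.issubset(ensemble.columns):
        raise ValueError("ensemble table needs columns 'N' and 'diameter'")
    per_n = ensemble.groupby("N")["diameter"].mean()
    return fit_power_law(per_n.index.to_numpy(), per_n.to_numpy() + 1.0)


def fit_diameter_vs_rg(D_values, Rg_values, unit_scale: float = 1.0) -> LinearFit:
    """Least-squares slope of (D + 1) against R_g, in inverse length units.

    ``Rg_values`` are multiplied by ``unit_scale`` first; pass the mean
    PRN link length in Å (≈ 5.066) to convert model units to Å so the
    slope is comparable with protein data (Å⁻¹).

    Raises
    ------
    ValueError
        On length mismatch or an all-equal R_g input (degenerate fit).
    """
    d = np.asarray(D_values, dtype=float)
    rg = np.asarray(Rg_values, dtype=float) * float(unit_scale)
    if d.shape != rg.shape:
        raise ValueError("D_values and Rg_values must have equal length")
    if d.size < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if np.ptp(rg) == 0:
        raise ValueError("degenerate fit: all R_g values are equal")
    res = stats.linregress(rg, d + 1.0)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=float(res.stderr),
        n_points=int(d.size),
    )
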