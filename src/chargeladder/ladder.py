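"""Ladder regression: migration times → mobilities → net charge Z.

The effective electrophoretic mobility of an analyte, measured against a
neutral EOF marker, is

    mu = (L_d * L_t / V) * (1/t - 1/t_eof)        [cm^2 kV^-1 min^-1]

Under the ladder model mu_N = c (Z + N dZ_Ac) the ordinary-least-squares
line of mu on acetylation number N has x-intercept -Z/dZ_Ac, so

    Z = dZ_Ac * intercept / slope = -x_intercept * dZ_Ac.

The unknown hydrodynamic coefficient c cancels in the intercept/slope
ratio — the ladder is its own calibration. Each replicate electropherogram
is fit independently (its own EOF marker removes any need for run-to-run
alignment) and per-replicate Z values are aggregated as mean ± sample sd.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic import CapillaryConfig

__all__ = [
    "MobilityLadder",
    "LadderFit",
    "NetChargeEstimate",
    "effective_mobility",
    "fit_ladder",
    "net_charge_from_fit",
    "aggregate_replicates",
]


class DegenerateLadderError(ValueError):
    """Ladder has no usable slope (all rungs at the same mobility)."""


@dataclass(frozen=True)
class MobilityLadder:
    """Per-replicate (N, mu) pairs, the regression input."""

    entries: tuple[tuple[int, float], ...]
    replicate_id: int | str | None = None
    pH: float | None = None
    redox_state: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple((int(n), float(m)) for n, m in self.entries))
        ns = [n for n, _ in self.entries]
        if len(set(ns)) != len(ns):
            raise ValueError("duplicate acetylation numbers in ladder")


@dataclass(frozen=True)
class LadderFit:
    slope: float
    intercept: float
    x_intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class NetChargeEstimate:
    """Replicate-aggregated net charge, Z_mean ± Z_sd (sample sd, n−1)."""

    z_mean: float
    z_sd: float
    n_replicates: int
    pH: float | None = None
    redox_state: str | None = None

    def __post_init__(self) -> None:
        if self.z_sd < 0:
            raise ValueError("z_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


def effective_mobility(t_min: float, t_eof_min: float, cap: CapillaryConfig) -> float:
    """Effective mobility from migration time and EOF-marker time.

    Negative for analytes eluting after the marker (anions under normal
    polarity); zero exactly at t = t_eof.
    """
    if t_min <= 0 or t_eof_min <= 0:
        raise ValueError("migration times must be positive")
    return cap.mobility_factor * (1.0 / t_min - 1.0 / t_eof_min)


def fit_ladder(ladder: MobilityLadder, max_rungs: int = 6) -> LadderFit:
    """OLS of mu on N over the first ``max_rungs`` rungs (N < max_rungs).

    The emulated experiments used the first five to six rungs; later rungs
    are noisier (lower abundance, wall adsorption) and are excluded.
    """
    used = [(n, mu) for n, mu in ladder.entries if n < max_rungs]
    if len(used) < 3:
        raise ValueError(f"need at least 3 rungs to fit, got {len(used)}")
    n_arr = np.array([n for n, _ in used], dtype=float)
    mu = np.array([m for _, m in used], dtype=float)
    slope, intercept = np.polyfit(n_arr, mu, 1)
    if abs(slope) <= 1e-12 * max(1.0, abs(intercept)):
        raise DegenerateLadderError("zero slope: rung mobilities do not change with N")
    resid = mu - (slope * n_arr + intercept)
    ss_tot = float(np.sum((mu - mu.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return LadderFit(
        slope=float(slope),
        intercept=float(intercept),
        x_intercept=float(-intercept / slope),
        r_squared=r2,
        n_points=len(used),
    )


def net_charge_from_fit(fit: LadderFit, delta_z_ac: float) -> float:
    """Z = dZ_Ac * (intercept / slope); invariant to rescaling all mobilities."""
    if delta_z_ac == 0:
        raise ValueError("delta_z_ac must be nonzero")
    if fit.slope == 0:
        raise DegenerateLadderError("zero slope")
    return delta_z_ac * fit.intercept / fit.slope


def aggregate_replicates(
    z_values: Iterable[float],
    pH: float | None = None,
    redox_state: str | None = None,
) -> NetChargeEstimate:
    """Mean and sample standard deviation (ddof=1; sd = 0 for a single value)."""
    vals = np.asarray(list(z_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values to aggregate")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return NetChargeEstimate(
        z_mean=float(np.mean(vals)),
        z_sd=sd,
        n_replicates=int(vals.size),
        pH=pH,
        redox_state=redox_state,
    )
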