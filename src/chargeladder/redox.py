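"""Redox comparison: ΔZ upon reduction, charge regulation, ET/PCET/2PCET.

Comparing the net charge of the oxidized and reduced forms gives the charge
change of the redox event, ΔZ = Z_red − Z_ox (so a protein that becomes
more negative upon reduction has ΔZ < 0). For an event transferring
``n_electrons`` electrons, ΔZ per electron reports the proton coupling:

    ΔZ/e = −1   uncoupled ET        (0 protons per electron)
    ΔZ/e =  0   PCET                (1 proton per electron)
    ΔZ/e = +1   2PCET               (2 protons per electron)

Percent charge regulation per electron, 100·(1 − min(|ΔZ/e|, 1)), measures
how completely the protein's ionizable groups absorb the added electron's
charge: 100 % means Z is unchanged by reduction. Uncertainties combine in
quadrature; per-electron uncertainty is the quadrature ΔZ sd divided by the
electron count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .ladder import NetChargeEstimate

__all__ = [
    "RedoxComparison",
    "compare_redox",
    "redox_stats",
    "classify_coupling",
    "report",
]

#: Labels by nearest integer proton count per electron.
_LABELS = {0: "ET", 1: "PCET", 2: "2PCET"}


@dataclass(frozen=True)
class RedoxComparison:
    """Oxidized/reduced charge comparison with propagated uncertainties."""

    z_ox: NetChargeEstimate
    z_red: NetChargeEstimate
    n_electrons: int
    delta_z: float
    delta_z_sd: float
    delta_z_per_e: float
    delta_z_per_e_sd: float
    cr_percent: float
    cr_percent_sd: float
    n_protons_est: float
    coupling_label: str

    @property
    def pH(self) -> float | None:
        return self.z_ox.pH


def classify_coupling(delta_z_per_e: float, tol: float = 0.25) -> tuple[float, str]:
    """Estimate protons transferred per electron and label the coupling.

    n_H/e = ΔZ/e + 1; the label is ET/PCET/2PCET when n_H/e lies within
    ``tol`` of 0/1/2, otherwise "fractional".
    """
    if not 0 < tol < 0.5:
        raise ValueError("tol must be in (0, 0.5)")
    n_protons_est = delta_z_per_e + 1.0
    for k, label in _LABELS.items():
        if abs(n_protons_est - k) <= tol:
            return n_protons_est, label
    return n_protons_est, "fractional"


def redox_stats(
    delta_z: float,
    delta_z_sd: float,
    n_electrons: int,
    tol: float = 0.25,
) -> dict:
    """Per-electron charge change, charge regulation and coupling from ΔZ.

    Entry point for precomputed ΔZ values (e.g. literature numbers); the
    same arithmetic backs :func:`compare_redox`.
    """
    if n_electrons < 1:
        raise ValueError("n_electrons must be at least 1")
    per_e = delta_z / n_electrons
    per_e_sd = delta_z_sd / n_electrons
    if abs(per_e) > 1.0 + 1e-3:  # slack: estimates at the ET/2PCET boundary
        warnings.warn(
            f"|dZ per electron| = {abs(per_e):.3g} > 1 lies outside the "
            "0-2 proton coupling framework",
            stacklevel=2,
        )
    cr = 100.0 * (1.0 - min(abs(per_e), 1.0))
    cr_sd = 100.0 * per_e_sd
    n_protons_est, label = classify_coupling(per_e, tol)
    return {
        "delta_z": delta_z,
        "delta_z_sd": delta_z_sd,
        "delta_z_per_e": per_e,
        "delta_z_per_e_sd": per_e_sd,
        "cr_percent": cr,
        "cr_percent_sd": cr_sd,
        "n_protons_est": n_protons_est,
        "coupling_label": label,
    }


def compare_redox(
    ox: NetChargeEstimate,
    red: NetChargeEstimate,
    n_electrons: int,
    tol: float = 0.25,
) -> RedoxComparison:
    """Compare oxidized and reduced estimates measured at the same pH."""
    if ox.pH is not None and red.pH is not None and ox.pH != red.pH:
        raise ValueError(f"pH mismatch: oxidized {ox.pH} vs reduced {red.pH}")
    delta_z = red.z_mean - ox.z_mean
    delta_z_sd = float(np.hypot(ox.z_sd, red.z_sd))
    stats = redox_stats(delta_z, delta_z_sd, n_electrons, tol)
    return RedoxComparison(z_ox=ox, z_red=red, n_electrons=n_electrons, **stats)


def report(
    comparisons: Sequence[RedoxComparison],
    extra_proteins: Sequence[tuple[str, float, float]] = (),
) -> pd.DataFrame:
    """Summary table: one oxidized and one reduced row per condition.

    Charges are rounded to 2 decimals and percent charge regulation to an
    integer, ties away from zero, at this reporting layer only. Note: the
    per-electron sd column is the quadrature ΔZ sd divided by the electron
    count, the same scaled value that backs the percent-regulation sd.
    ``extra_proteins`` optionally appends user-supplied (name, Z_ox, ΔZ_ET)
    survey rows for cross-protein comparison.
    """
    if not comparisons:
        raise ValueError("no comparisons to report")
    rows = []
    ordered = sorted(comparisons, key=lambda c: (c.pH is None, c.pH))
    for c in ordered:
        rows.append(
            {
                "redox_state": "oxidized",
                "pH": c.pH,
                "Z": round_half_away(c.z_ox.z_mean, 2),
                "Z_sd": round_half_away(c.z_ox.z_sd, 2),
                "delta_z": round_half_away(c.delta_z, 2),
                "delta_z_sd": round_half_away(c.delta_z_sd, 2),
                "delta_z_per_e": round_half_away(c.delta_z_per_e, 2),
                "delta_z_per_e_sd": round_half_away(c.delta_z_per_e_sd, 2),
                "cr_percent": round_half_away(c.cr_percent, 0),
                "cr_percent_sd": round_half_away(c.cr_percent_sd, 0),
                "coupling": c.coupling_label,
            }
        )
        rows.append(
            {
                "redox_state": "reduced",
                "pH": c.pH,
                "Z": round_half_away(c.z_red.z_mean, 2),
                "Z_sd": round_half_away(c.z_red.z_sd, 2),
            }
        )
    df = pd.DataFrame(rows)
    for name, z_ox, dz in extra_proteins:
        df = pd.concat(
            [df, pd.DataFrame([{"redox_state": "oxidized", "protein": name,
                                "Z": z_ox, "delta_z": dz}])],
            ignore_index=True,
        )
    return df
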