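"""Henderson–Hasselbalch net-charge model of a metalloprotein.

A protein's net charge Z at a given pH is modelled as the sum of
fractional charges of its ionizable groups (bases contribute
``+count / (1 + 10**(pH - pKa))``, acids ``-count / (1 + 10**(pKa - pH))``),
the formal charges of its metal sites in the current redox state, and an
integer number of lysine acetylations each shifting Z by ``delta_z_per_acetylation``
(negative: acetylation neutralises a positive lysine).

The same module holds the proton-coupling arithmetic: a redox event that
transfers ``n_electrons`` electrons and ``n_protons`` protons changes Z by
``n_protons - n_electrons``, so per electron uncoupled ET gives -1, PCET
(one proton per electron) gives 0 and 2PCET gives +1.

A radial residue-counting utility over PDB structures supports questions of
which ionizable residues surround a metal site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "RedoxState",
    "IonizableGroup",
    "MetalSite",
    "ProteinChargeModel",
    "ProtonationScenario",
    "DEFAULT_PKA",
    "IONIZABLE_RESIDUES",
    "net_charge",
    "predict_delta_z",
    "ionizable_within_radius",
    "metal_coordinates",
]


class RedoxState(str, Enum):
    OXIDIZED = "oxidized"
    REDUCED = "reduced"


#: Default intrinsic pKa values for ionizable groups. The literature offers
#: several such consensus tables; these are typical textbook values and are
#: overridable in any model or config file.
DEFAULT_PKA: dict[str, float] = {
    "Asp": 3.7,
    "Glu": 4.2,
    "His": 6.4,
    "Cys": 8.5,
    "Tyr": 10.1,
    "Lys": 10.5,
    "Arg": 12.5,
    "N-term": 8.0,
    "C-term": 3.2,
}

#: Which of DEFAULT_PKA's side chains are acids vs. bases.
_ACIDIC = {"Asp", "Glu", "Cys", "Tyr", "C-term"}
_BASIC = {"His", "Lys", "Arg", "N-term"}

#: Residues counted as ionizable in structural shell queries.
IONIZABLE_RESIDUES = frozenset({"ASP", "GLU", "HIS", "LYS", "ARG"})

_STANDARD_RESIDUES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


@dataclass(frozen=True)
class IonizableGroup:
    """One class of titratable group (e.g. all Lys side chains, or His71)."""

    label: str
    kind: str  # "acid" or "base"
    pKa: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise ValueError(f"kind must be 'acid' or 'base', got {self.kind!r}")
        if not np.isfinite(self.pKa):
            raise ValueError("pKa must be finite")
        if self.count < 0:
            raise ValueError("count must be non-negative")

    def fractional_charge(self, pH: float) -> float:
        """Henderson–Hasselbalch mean charge of this group class at ``pH``."""
        if self.kind == "base":
            return self.count / (1.0 + 10.0 ** (pH - self.pKa))
        return -self.count / (1.0 + 10.0 ** (self.pKa - pH))

    @classmethod
    def from_residue(cls, residue: str, count: int = 1, pKa: float | None = None) -> "IonizableGroup":
        """Build a group from a residue name in :data:`DEFAULT_PKA`."""
        if residue not in DEFAULT_PKA:
            raise KeyError(f"no default pKa for {residue!r}")
        kind = "acid" if residue in _ACIDIC else "base"
        return cls(residue, kind, DEFAULT_PKA[residue] if pKa is None else pKa, count)


@dataclass(frozen=True)
class MetalSite:
    """A redox-active metal site with formal charges per redox state."""

    site_id: str
    charge_by_state: Mapping[str, int] = field(
        default_factory=lambda: {"oxidized": 2, "reduced": 1}
    )
    protons_coupled_per_electron: int = 0

    def __post_init__(self) -> None:
        for state, q in self.charge_by_state.items():
            if int(q) != q:
                raise ValueError(f"metal charge for {state!r} must be integer, got {q}")
        if self.protons_coupled_per_electron < 0:
            raise ValueError("protons_coupled_per_electron must be non-negative")

    def charge(self, redox_state: RedoxState | str) -> int:
        state = RedoxState(redox_state).value
        if state not in self.charge_by_state:
            raise KeyError(f"site {self.site_id!r} has no charge for state {state!r}")
        return int(self.charge_by_state[state])


@dataclass(frozen=True)
class ProteinChargeModel:
    """Ground-truth charge model: groups per subunit, metal sites per assembly.

    ``groups`` are counted per subunit and scaled by ``n_subunits``;
    ``sites`` are enumerated explicitly for the whole assembly (the SOD1
    dimer studied here has four Cu sites). ``delta_z_per_acetylation``
    (ΔZ_Ac) is the — negative, sub-unit-magnitude — change in net charge per
    lysine acetylation; its magnitude is below 1 because of charge
    regulation.
    """

    groups: tuple[IonizableGroup, ...] = ()
    sites: tuple[MetalSite, ...] = ()
    n_subunits: int = 1
    delta_z_per_acetylation: float = -0.9

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be positive")
        if not self.delta_z_per_acetylation < 0:
            raise ValueError("delta_z_per_acetylation must be negative")

    @property
    def total_lysines(self) -> int:
        per_subunit = sum(g.count for g in self.groups if g.label.lower().startswith("lys"))
        return per_subunit * self.n_subunits

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "groups": [
                {"label": g.label, "kind": g.kind, "pKa": g.pKa, "count": g.count}
                for g in self.groups
            ],
            "sites": [
                {
                    "site_id": s.site_id,
                    "charge_by_state": dict(s.charge_by_state),
                    "protons_coupled_per_electron": s.protons_coupled_per_electron,
                }
                for s in self.sites
            ],
            "n_subunits": self.n_subunits,
            "delta_z_per_acetylation": self.delta_z_per_acetylation,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProteinChargeModel":
        return cls(
            groups=tuple(IonizableGroup(**g) for g in d.get("groups", ())),
            sites=tuple(MetalSite(**s) for s in d.get("sites", ())),
            n_subunits=int(d.get("n_subunits", 1)),
            delta_z_per_acetylation=float(d.get("delta_z_per_acetylation", -0.9)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ProteinChargeModel":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class ProtonationScenario:
    """Proton/electron stoichiometry of one redox event (totals, not per site)."""

    n_electrons: int
    n_protons: int = 0

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be positive")
        if self.n_protons < 0:
            raise ValueError("n_protons must be non-negative")


def net_charge(
    model: ProteinChargeModel,
    pH: float,
    redox_state: RedoxState | str = RedoxState.OXIDIZED,
    n_acetyl: int = 0,
) -> float:
    """Net charge Z of the assembly at ``pH`` with ``n_acetyl`` acetylations.

    Z = n_subunits * Σ_groups q_HH(pH) + Σ_sites q(redox_state)
        + n_acetyl * ΔZ_Ac
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    if n_acetyl < 0:
        raise ValueError("n_acetyl must be non-negative")
    total_lys = model.total_lysines
    if total_lys and n_acetyl > total_lys:
        raise ValueError(f"n_acetyl={n_acetyl} exceeds total lysine count {total_lys}")
    state = RedoxState(redox_state)
    z = model.n_subunits * sum(g.fractional_charge(pH) for g in model.groups)
    z += sum(site.charge(state) for site in model.sites)
    z += n_acetyl * model.delta_z_per_acetylation
    return z


def predict_delta_z(scenario: ProtonationScenario) -> int:
    """Net-charge change of a redox event: ΔZ = n_protons − n_electrons.

    Per transferred electron this is −1 for uncoupled ET, 0 for PCET and
    +1 for 2PCET.
    """
    return scenario.n_protons - scenario.n_electrons


def scenario_for_model(model: ProteinChargeModel) -> ProtonationScenario:
    """Full-reduction scenario implied by a model's metal sites."""
    n_e = sum(
        s.charge("oxidized") - s.charge("reduced") for s in model.sites
    )
    if n_e < 1:
        raise ValueError("model's sites imply no electron transfer")
    n_h = sum(
        (s.charge("oxidized") - s.charge("reduced")) * s.protons_coupled_per_electron
        for s in model.sites
    )
    return ProtonationScenario(n_electrons=n_e, n_protons=n_h)


# -- structural shell counting -------------------------------------------


def _residues(structure) -> list:
    """Flatten a Bio.PDB entity (or accept an iterable of residues)."""
    if hasattr(structure, "get_residues"):
        return list(structure.get_residues())
    return list(structure)


def ionizable_within_radius(
    structure,
    center: Sequence[float],
    radius: float,
    residue_classes: Iterable[str] = IONIZABLE_RESIDUES,
) -> int:
    """Count residues of the given classes with any atom within ``radius`` Å.

    ``structure`` is a Bio.PDB entity (Structure/Model/Chain) or an iterable
    of Bio.PDB residues; ``center`` is a 3-vector in Å (typically a metal ion
    coordinate). The shell is closed: distance ≤ radius counts.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    classes = {c.upper() for c in residue_classes}
    unknown = classes - _STANDARD_RESIDUES
    if unknown:
        raise ValueError(f"unknown residue class names: {sorted(unknown)}")
    residues = _residues(structure)
    if not residues:
        raise ValueError("empty structure")
    c = np.asarray(center, dtype=float)
    n = 0
    for res in residues:
        if res.get_resname().upper() not in classes:
            continue
        coords = np.array([atom.coord for atom in res.get_atoms()], dtype=float)
        if coords.size and np.min(np.linalg.norm(coords - c, axis=1)) <= radius:
            n += 1
    return n


def metal_coordinates(structure, element: str) -> list[np.ndarray]:
    """Coordinates of all atoms of a metal ``element`` (e.g. "ZN", "CU")."""
    elem = element.upper()
    out = []
    for res in _residues(structure):
        for atom in res.get_atoms():
            if (atom.element or "").upper() == elem:
                out.append(np.asarray(atom.coord, dtype=float))
    return out
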