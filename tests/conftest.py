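import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from chargeladder import CapillaryConfig, SyntheticTruth
from chargeladder.synthetic import NoiseSpec


@pytest.fixture
def cap():
    return CapillaryConfig()


@pytest.fixture
def truth():
    """Default ground truth: dimer Z_ox = -6.35 -> Z_red = -6.44 (dZ = -0.09)."""
    return SyntheticTruth()


@pytest.fixture
def noiseless():
    return NoiseSpec.noiseless()


def gaussian_trace(centers, heights, sigma=0.05, t_max=12.0, dt=1 / 240, baseline=0.0):
    """Sum-of-Gaussians trace on a uniform grid (test helper)."""
    from chargeladder import Trace

    time = np.arange(0.0, t_max + dt / 2, dt)
    signal = np.full_like(time, baseline, dtype=float)
    for c, h in zip(centers, heights):
        signal += h * np.exp(-0.5 * ((time - c) / sigma) ** 2)
    return Trace(time, signal)


def build_structure(residue_specs):
    """Synthetic Bio.PDB structure from [(resname, [(atom, xyz), ...]), ...]."""
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("synthetic")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for i, (resname, atoms) in enumerate(residue_specs, start=1):
        sb.init_residue(resname, " ", i, " ")
        for j, (atom_name, xyz) in enumerate(atoms):
            sb.init_atom(
                atom_name,
                np.array(xyz, dtype=float),
                0.0,
                1.0,
                " ",
                atom_name,
                serial_number=i * 100 + j,
                element=atom_name[0],
            )
    return sb.get_structure()
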