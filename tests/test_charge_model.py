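"""Henderson–Hasselbalch charge model, coupling arithmetic, shell counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chargeladder import (
    IonizableGroup,
    MetalSite,
    ProteinChargeModel,
    ProtonationScenario,
    RedoxState,
    ionizable_within_radius,
    net_charge,
    predict_delta_z,
)
from chargeladder.charge_model import scenario_for_model

from conftest import build_structure


def simple_model(**kwargs):
    defaults = dict(
        groups=[
            IonizableGroup.from_residue("Asp", count=2),
            IonizableGroup.from_residue("Lys", count=3),
            IonizableGroup.from_residue("His", count=1),
        ],
        n_subunits=1,
    )
    defaults.update(kwargs)
    return ProteinChargeModel(**defaults)


class TestNetCharge:
    def test_half_titration_of_single_base(self):
        m = ProteinChargeModel(groups=[IonizableGroup("B", "base", 7.0, 1)])
        assert net_charge(m, pH=7.0) == pytest.approx(0.5)

    def test_two_group_model_at_neutral_ph(self):
        # one acid (pKa 4, count 2) fully deprotonated, one base (pKa 10)
        # fully protonated: -2/(1+1e-3) + 1/(1+1e-3) = -0.999001
        m = ProteinChargeModel(
            groups=[IonizableGroup("acid", "acid", 4.0, 2), IonizableGroup("base", "base", 10.0, 1)]
        )
        assert net_charge(m, pH=7.0) == pytest.approx(-0.999000999, abs=1e-9)

    def test_more_negative_at_higher_ph(self):
        m = simple_model(sites=[MetalSite("Cu1"), MetalSite("Cu2")])
        z = [net_charge(m, pH) for pH in (5.6, 7.4, 8.3)]
        assert z[0] > z[1] > z[2]

    def test_metal_site_charges_by_state(self):
        m = ProteinChargeModel(
            groups=[IonizableGroup("B", "base", 7.0, 1)],
            sites=[MetalSite("Cu_Zn"), MetalSite("Cu_Cu")],
        )
        z_ox = net_charge(m, 7.0, RedoxState.OXIDIZED)
        z_red = net_charge(m, 7.0, RedoxState.REDUCED)
        assert z_ox - z_red == pytest.approx(2.0)  # two sites, one electron each

    def test_acetylation_shifts_by_delta_z_ac(self):
        m = simple_model(delta_z_per_acetylation=-0.85)
        for k in (1, 2, 3):
            dz = net_charge(m, 7.4, n_acetyl=k) - net_charge(m, 7.4, n_acetyl=k - 1)
            assert dz == pytest.approx(-0.85, abs=1e-12)

    def test_subunit_scaling(self):
        mono = simple_model(n_subunits=1)
        dimer = simple_model(n_subunits=2)
        assert net_charge(dimer, 7.0) == pytest.approx(2 * net_charge(mono, 7.0))

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(redox_state="half-baked"), "half-baked"),
            (dict(n_acetyl=-1), "non-negative"),
            (dict(n_acetyl=99), "lysine"),
            (dict(pH=15.0), "pH"),
        ],
    )
    def test_input_validation(self, kwargs, match):
        with pytest.raises((ValueError, KeyError), match=match):
            net_charge(simple_model(), **{"pH": 7.0, **kwargs})

    @given(
        ph_lo=st.floats(0.5, 13.0),
        dph=st.floats(0.01, 1.0),
        pka=st.floats(2.0, 12.0),
        n_base=st.integers(0, 5),
        n_acid=st.integers(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_ph(self, ph_lo, dph, pka, n_base, n_acid):
        groups = [IonizableGroup("a", "acid", pka, n_acid + 1), IonizableGroup("b", "base", 14 - pka, n_base)]
        m = ProteinChargeModel(groups=groups)
        assert net_charge(m, ph_lo) > net_charge(m, min(ph_lo + dph, 14.0))


class TestCouplingArithmetic:
    @pytest.mark.parametrize(
        "n_e, n_h, expected",
        [(1, 0, -1), (1, 1, 0), (1, 2, 1), (4, 4, 0), (4, 0, -4), (4, 8, 4)],
    )
    def test_delta_z_is_protons_minus_electrons(self, n_e, n_h, expected):
        assert predict_delta_z(ProtonationScenario(n_e, n_h)) == expected

    def test_full_dimer_pcet_gives_zero_net_change(self):
        # four Cu(II)->Cu(I) sites, one proton per electron: complete regulation
        sites = [MetalSite(f"Cu{i}", protons_coupled_per_electron=1) for i in range(4)]
        m = ProteinChargeModel(groups=[IonizableGroup("B", "base", 7, 1)], sites=sites)
        s = scenario_for_model(m)
        assert (s.n_electrons, s.n_protons) == (4, 4)
        assert predict_delta_z(s) == 0

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            ProtonationScenario(0, 1)
        with pytest.raises(ValueError):
            ProtonationScenario(1, -1)


class TestModelSerialization:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_roundtrip(self, tmp_path, suffix):
        m = simple_model(
            sites=[MetalSite("Cu_Zn", protons_coupled_per_electron=1)],
            n_subunits=2,
            delta_z_per_acetylation=-0.9,
        )
        path = tmp_path / f"model{suffix}"
        m.save(path)
        assert ProteinChargeModel.load(path) == m


def brute_force_count(residue_specs, center, radius, classes):
    """All-pairs distance oracle, independent of the implementation."""
    c = np.asarray(center, dtype=float)
    n = 0
    for resname, atoms in residue_specs:
        if resname.upper() not in {x.upper() for x in classes}:
            continue
        if any(np.linalg.norm(np.asarray(xyz) - c) <= radius for _, xyz in atoms):
            n += 1
    return n


class TestRadialCounting:
    CLASSES = ("ASP", "GLU", "HIS", "LYS", "ARG")

    def test_three_residue_example(self):
        specs = [
            ("ASP", [("CA", (5.0, 0, 0))]),
            ("LYS", [("CA", (15.0, 0, 0))]),
            ("ALA", [("CA", (2.0, 0, 0))]),
        ]
        s = build_structure(specs)
        assert ionizable_within_radius(s, (0, 0, 0), 10.0, self.CLASSES) == 1

    def test_radius_zero(self):
        s = build_structure([("ASP", [("CA", (1.0, 0, 0))])])
        assert ionizable_within_radius(s, (0, 0, 0), 0.0, self.CLASSES) == 0

    def test_closed_shell_boundary(self):
        s = build_structure([("LYS", [("NZ", (10.0, 0, 0))])])
        assert ionizable_within_radius(s, (0, 0, 0), 10.0, self.CLASSES) == 1

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_and_is_monotone(self, data):
        names = ["ASP", "GLU", "HIS", "LYS", "ARG", "ALA", "GLY", "SER"]
        n_res = data.draw(st.integers(1, 12))
        specs = []
        for i in range(n_res):
            name = data.draw(st.sampled_from(names))
            n_atoms = data.draw(st.integers(1, 4))
            atoms = [
                (f"C{j}", tuple(data.draw(st.floats(-20, 20)) for _ in range(3)))
                for j in range(n_atoms)
            ]
            specs.append((name, atoms))
        s = build_structure(specs)
        r1 = data.draw(st.floats(0, 15))
        r2 = data.draw(st.floats(0, 15))
        counts = {
            r: ionizable_within_radius(s, (0, 0, 0), r, self.CLASSES) for r in (r1, r2)
        }
        for r in (r1, r2):
            assert counts[r] == brute_force_count(specs, (0, 0, 0), r, self.CLASSES)
        assert counts[max(r1, r2)] >= counts[min(r1, r2)]

    def test_unknown_class_rejected(self):
        s = build_structure([("ASP", [("CA", (1, 0, 0))])])
        with pytest.raises(ValueError, match="unknown residue class"):
            ionizable_within_radius(s, (0, 0, 0), 5.0, ["ASP", "XYZ"])

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ionizable_within_radius([], (0, 0, 0), 5.0, self.CLASSES)
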