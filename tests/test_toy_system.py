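"""Reduced binding-site model: construction, energies, restraint geometry."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pumpsel import (
    COULOMB,
    IonParameters,
    RestraintSpec,
    build_binding_site,
    default_ion_parameters,
    restraint_energy,
    total_energy,
)
from pumpsel.toy_system import (
    BindingSiteModel,
    LigandSpec,
    SiteState,
    energy_terms,
    initial_site_state,
    model_from_json,
    model_to_json,
    restraint_geometry,
    rotate_model,
    wrap_degrees,
)


class TestConstruction:
    def test_net_charge_counts_deprotonated_ligands(self):
        m = build_binding_site({"n_ligands": 6, "charged": ["L1", "L2"]})
        assert m.ligand_net_charge == pytest.approx(-2.0)

    def test_protonation_neutralises_one_charge(self):
        m = build_binding_site({"n_ligands": 6, "charged": ["L1", "L2"],
                                "protonated": ["L1"]})
        assert m.ligand_net_charge == pytest.approx(-1.0)

    def test_identical_configs_serialize_identically(self):
        cfg = {"n_ligands": 5, "charged": ["L2"], "mutated": ["L3"],
               "temperature": 310.0}
        assert model_to_json(build_binding_site(cfg)) == \
            model_to_json(build_binding_site(cfg))

    def test_serialization_round_trip_is_lossless(self, restrained_site):
        text = model_to_json(restrained_site)
        assert model_from_json(text) == restrained_site
        assert model_to_json(model_from_json(text)) == text

    def test_unknown_flag_ids_rejected(self):
        with pytest.raises(ValueError, match="unknown ligands"):
            build_binding_site({"n_ligands": 3, "charged": ["L9"]})

    def test_overlapping_anchors_rejected(self):
        lig = LigandSpec(ligand_id="a", anchor=(4.0, 0, 0))
        with pytest.raises(ValueError, match="overlapping"):
            BindingSiteModel(
                ligands=(lig, replace(lig, ligand_id="b")),
                ion=default_ion_parameters("Na"))

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_binding_site({"n_ligands": 2, "anchor_radius": -1.0})
        with pytest.raises(ValueError):
            IonParameters(species="Na", epsilon=-0.1, rmin_half=1.4)


class TestEnergy:
    def test_single_ligand_coulomb_matches_hand_computation(self):
        """Ion–charge Coulomb term equals q1·q2·332.0716/r exactly."""
        lig = LigandSpec(ligand_id="L1", anchor=(4.0, 0.0, 0.0),
                         dipole_q=0.45,
                         torsion=())
        m = BindingSiteModel(ligands=(lig,), ion=default_ion_parameters("Na"),
                             wall_k=0.0, confinement_radius=10.0)
        state = SiteState(ion_pos=np.array([0.0, 0.0, 0.0]),
                          chi=np.array([30.0]))
        tip = lig.tip_position(30.0)
        inner = lig.inner_position(30.0)
        expected = (COULOMB * 1.0 * lig.tip_charge / np.linalg.norm(tip)
                    + COULOMB * 1.0 * lig.inner_charge / np.linalg.norm(inner))
        terms = energy_terms(m, state)
        assert terms["coulomb_ion"] == pytest.approx(expected, rel=1e-12)

    def test_nonbonded_terms_vanish_at_large_separation(self):
        lig = LigandSpec(ligand_id="L1", anchor=(4.0, 0.0, 0.0), torsion=())
        m = BindingSiteModel(ligands=(lig,), ion=default_ion_parameters("Na"),
                             wall_k=0.0, confinement_radius=1e9)
        far = SiteState(ion_pos=np.array([1e8, 0.0, 0.0]), chi=np.array([0.0]))
        terms = energy_terms(m, far)
        assert abs(terms["coulomb_ion"]) < 1e-5
        assert abs(terms["lj_ion"]) < 1e-30

    def test_identical_states_identical_energy(self, small_site):
        s = initial_site_state(small_site)
        assert total_energy(small_site, s) == total_energy(small_site, s.copy())

    def test_torsion_periodicity(self, small_site):
        s = initial_site_state(small_site)
        s.chi[:] = 17.0
        e1 = total_energy(small_site, s)
        s2 = s.copy()
        s2.chi[:] = wrap_degrees(17.0 + 360.0)
        assert total_energy(small_site, s2) == pytest.approx(e1, abs=1e-10)

    def test_protonation_changes_coulomb_only(self):
        cfg = {"n_ligands": 4, "charged": ["L1", "L2"]}
        m1 = build_binding_site(cfg)
        m2 = build_binding_site({**cfg, "protonated": ["L1"]})
        s = initial_site_state(m1)
        t1, t2 = energy_terms(m1, s), energy_terms(m2, s)
        assert t1["lj_ion"] == t2["lj_ion"]
        assert t1["torsion"] == t2["torsion"]
        assert t1["coulomb_ion"] != t2["coulomb_ion"]

    def test_mutation_changes_lj_and_charge(self):
        cfg = {"n_ligands": 4, "charged": ["L1"]}
        m1 = build_binding_site(cfg)
        m2 = build_binding_site({**cfg, "mutated": ["L1"]})
        s = initial_site_state(m1)
        t1, t2 = energy_terms(m1, s), energy_terms(m2, s)
        assert t1["lj_ion"] != t2["lj_ion"]
        assert m2.ligand_net_charge == 0.0

    def test_rigid_rotation_invariance(self, restrained_site, rng):
        """Rotating the whole system (anchors, frames, restraint points,
        ion) leaves the energy unchanged: geometry is purely internal."""
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [31.0, -57.0, 12.0], degrees=True).as_matrix()
        rotated = rotate_model(restrained_site, R)
        s = initial_site_state(restrained_site, rng)
        s_rot = SiteState(ion_pos=R @ s.ion_pos, chi=s.chi.copy())
        assert total_energy(rotated, s_rot) == pytest.approx(
            total_energy(restrained_site, s), rel=1e-10)

    def test_nbfix_override_takes_precedence(self):
        na = default_ion_parameters("Na")
        with_fix = IonParameters(species="Na", epsilon=na.epsilon,
                                 rmin_half=na.rmin_half,
                                 nbfix=(("O_carbonyl", 0.2, 3.0),))
        lig = LigandSpec(ligand_id="L1", anchor=(4.0, 0, 0))
        assert with_fix.pair_lj("O_carbonyl", lig.tip_epsilon,
                                lig.tip_rmin_half) == (0.2, 3.0)
        assert with_fix.pair_lj("other", 0.12, 1.7) == \
            na.pair_lj("other", 0.12, 1.7)


class TestRestraint:
    anchors = ((6.0, 0.0, 0.0), (0.0, 6.0, 0.0), (0.0, 0.0, 6.0))

    def equilibrium_spec(self):
        r, th, ps = restraint_geometry((0.5, 0.5, 0.5), self.anchors)
        return RestraintSpec(r0=r, theta0=th, psi0=ps)

    def test_zero_at_equilibrium(self):
        spec = self.equilibrium_spec()
        assert restraint_energy((0.5, 0.5, 0.5), spec, self.anchors) == \
            pytest.approx(0.0, abs=1e-12)

    def test_unit_distance_offset_costs_half_k(self):
        """k_r = 10 kcal/mol/Å² and a 1 Å stretch give ½·10·1² = 5."""
        p1 = np.array(self.anchors[0])
        ion = np.array([0.5, 0.5, 0.5])
        spec = self.equilibrium_spec()
        v = ion - p1
        stretched = p1 + v * (1.0 + 1.0 / np.linalg.norm(v))
        e = restraint_energy(stretched, replace(spec,
                                                theta0=restraint_geometry(stretched, self.anchors)[1],
                                                psi0=restraint_geometry(stretched, self.anchors)[2]),
                             self.anchors)
        assert e == pytest.approx(5.0, abs=1e-9)

    def test_psi_antipode_costs_half_k_pi_squared(self):
        """ψ off by 180° with k_ψ = 200 → ½·200·π² ≈ 987.0 kcal/mol."""
        ion = np.array([0.5, 0.5, 0.5])
        r, th, ps = restraint_geometry(ion, self.anchors)
        spec = RestraintSpec(r0=r, theta0=th,
                             psi0=wrap_degrees(ps + 180.0).item())
        e = restraint_energy(ion, spec, self.anchors)
        assert e == pytest.approx(0.5 * 200.0 * math.pi ** 2, rel=1e-9)

    def test_ion_at_p1_is_undefined(self):
        spec = self.equilibrium_spec()
        with pytest.raises(ValueError, match="coincides"):
            restraint_energy(self.anchors[0], spec, self.anchors)

    def test_angle_wrap_before_squaring(self):
        ion = np.array([0.5, 0.5, 0.5])
        r, th, ps = restraint_geometry(ion, self.anchors)
        spec_plus = RestraintSpec(r0=r, theta0=th, psi0=wrap_degrees(ps + 350.0).item())
        spec_minus = RestraintSpec(r0=r, theta0=th, psi0=wrap_degrees(ps - 10.0).item())
        assert restraint_energy(ion, spec_plus, self.anchors) == pytest.approx(
            restraint_energy(ion, spec_minus, self.anchors), rel=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            RestraintSpec(r0=5.0, theta0=0.0, psi0=0.0)
        with pytest.raises(ValueError):
            RestraintSpec(r0=5.0, theta0=90.0, psi0=0.0, k_r=-1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(chi=st.floats(-1e4, 1e4, allow_nan=False))
def test_wrap_degrees_stays_in_range(chi):
    w = float(wrap_degrees(chi))
    assert -180.0 <= w < 180.0
    assert abs((chi - w) % 360.0) < 1e-6 or abs((chi - w) % 360.0 - 360.0) < 1e-6
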