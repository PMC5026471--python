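"""Alchemical legs: interpolation, three-point swaps, decoupling, deprotonation."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.special import logsumexp

from pumpsel import (
    IonParameters,
    LambdaSchedule,
    decouple_restraint_leg,
    default_schedule,
    deprotonation_leg,
    interpolate_ion_params,
    run_mc,
    three_point_alchemy,
)
from pumpsel.alchemy import CrossEnergyMatrix
from pumpsel.constants import KB, T_DEFAULT
from pumpsel.estimators import wham_multistate
from pumpsel._energy import site_evaluator
from pumpsel.toy_system import RestraintSpec, build_binding_site, restraint_geometry

BETA = 1.0 / (KB * T_DEFAULT)


class TestSchedules:
    def test_default_window_counts(self):
        assert len(default_schedule("site_ion_swap")) == 16
        assert len(default_schedule("bulk_ion_swap")) == 11
        assert len(default_schedule("deprot_site")) == 24
        assert len(default_schedule("deprot_bulk")) == 10

    def test_endpoints_required(self):
        with pytest.raises(ValueError):
            LambdaSchedule(label="x", lambdas=(0.1, 0.5, 1.0))
        with pytest.raises(ValueError):
            LambdaSchedule(label="x", lambdas=(0.0, 0.5, 0.5, 1.0))

    def test_unknown_leg_label(self):
        with pytest.raises(ValueError):
            default_schedule("nonsense")


class TestInterpolation:
    def test_endpoints_exact(self, na_params, k_params):
        assert interpolate_ion_params(na_params, k_params, 0.0) == na_params
        assert interpolate_ion_params(na_params, k_params, 1.0) == k_params

    def test_midpoint_is_arithmetic_mean(self, na_params, k_params):
        mid = interpolate_ion_params(na_params, k_params, 0.5)
        assert mid.epsilon == pytest.approx(
            0.5 * (na_params.epsilon + k_params.epsilon))
        assert mid.rmin_half == pytest.approx(
            0.5 * (na_params.rmin_half + k_params.rmin_half))
        assert mid.charge == 1.0

    def test_pair_overrides_interpolate(self):
        na = IonParameters(species="Na", epsilon=0.05, rmin_half=1.4,
                           nbfix=(("O_carbonyl", 0.10, 3.0),))
        k = IonParameters(species="K", epsilon=0.09, rmin_half=1.8,
                          nbfix=(("O_carbonyl", 0.20, 3.4),))
        mid = interpolate_ion_params(na, k, 0.5)
        assert mid.nbfix == (("O_carbonyl", pytest.approx(0.15),
                              pytest.approx(3.2)),)

    def test_mismatched_override_lists_rejected(self):
        na = IonParameters(species="Na", epsilon=0.05, rmin_half=1.4,
                           nbfix=(("O_carbonyl", 0.1, 3.0),))
        k = IonParameters(species="K", epsilon=0.09, rmin_half=1.8)
        with pytest.raises(ValueError, match="override"):
            interpolate_ion_params(na, k, 0.5)

    def test_interpolated_endpoint_energies_match_pure_species(
            self, small_site, na_params, k_params):
        """λ=0/1 hybrid energies equal pure-species energies exactly."""
        from pumpsel.toy_system import initial_site_state, total_energy
        s = initial_site_state(small_site)
        for lam, pure in ((0.0, na_params), (1.0, k_params)):
            hyb = interpolate_ion_params(na_params, k_params, lam)
            assert total_energy(small_site, s, ion=hyb) == \
                total_energy(small_site, s, ion=pure)


class TestThreePoint:
    def test_identical_species_null(self, small_site, na_params):
        na_copy = IonParameters(species="K", epsilon=na_params.epsilon,
                                rmin_half=na_params.rmin_half)
        res = three_point_alchemy(small_site, seed=3, na=na_params, k=na_copy,
                                  n_steps=800, thin=4)
        assert res.dg == pytest.approx(0.0, abs=1e-9)

    def test_direction_reversal_flips_sign(self, small_site, na_params,
                                           close_k_params):
        fwd = three_point_alchemy(small_site, seed=21, na=na_params,
                                  k=close_k_params, n_steps=3000, thin=5)
        rev = three_point_alchemy(small_site, seed=22, na=na_params,
                                  k=close_k_params, n_steps=3000, thin=5,
                                  reverse=True)
        tol = 3 * np.hypot(fwd.error, rev.error) + 0.05
        assert abs(fwd.dg + rev.dg) < tol

    def test_cycle_closure_against_two_state_estimate(self, small_site,
                                                      na_params, close_k_params):
        """f_K − f_Na from the three-state WHAM equals the direct
        two-state estimate using only the endpoint samplings."""
        res = three_point_alchemy(small_site, seed=5, na=na_params,
                                  k=close_k_params, n_steps=4000, thin=5)
        # rebuild the endpoint-only matrix from fresh endpoint runs
        ev = site_evaluator(small_site)
        rows = []
        for ion, seed in ((na_params, 101), (close_k_params, 102)):
            series = run_mc(small_site.with_ion(ion), 4000, seed, thin=5)
            rows.append(np.stack(
                [ev.batch_energy(series.ion_pos, series.chi, ion=i)
                 for i in (na_params, close_k_params)], axis=1))
        two_state = CrossEnergyMatrix(
            energies=np.vstack(rows),
            origin=np.concatenate([np.zeros(len(rows[0]), int),
                                   np.ones(len(rows[1]), int)]))
        direct = wham_multistate(two_state, T_DEFAULT)
        tol = 3 * res.error + 0.1
        assert abs(res.dg - float(direct.f[1])) < tol

    def test_agrees_with_zwanzig_exponential_averaging(self, small_site,
                                                       na_params, close_k_params):
        """Independent oracle: two-sided exponential averaging on long
        endpoint runs brackets the WHAM estimate."""
        ev = site_evaluator(small_site)
        res = three_point_alchemy(small_site, seed=7, na=na_params,
                                  k=close_k_params, n_steps=5000, thin=5)
        dgs = {}
        for label, ion, other, seed in (("fwd", na_params, close_k_params, 201),
                                        ("rev", close_k_params, na_params, 202)):
            series = run_mc(small_site.with_ion(ion), 8000, seed, thin=4)
            du = (ev.batch_energy(series.ion_pos, series.chi, ion=other)
                  - ev.batch_energy(series.ion_pos, series.chi, ion=ion))
            dgs[label] = -(logsumexp(-BETA * du) - np.log(len(du))) / BETA
        # forward and reverse Zwanzig estimates bound the true value
        lo, hi = sorted((dgs["fwd"], -dgs["rev"]))
        assert lo - 3 * res.error - 0.1 < res.dg < hi + 3 * res.error + 0.1

    def test_overlap_warning_on_disjoint_states(self, small_site, na_params):
        fat = IonParameters(species="K", epsilon=0.087, rmin_half=2.6)
        with pytest.warns(RuntimeWarning, match="overlap"):
            three_point_alchemy(small_site, seed=9, na=na_params, k=fat,
                                n_steps=600, thin=4)


class TestRestraintDecoupling:
    def test_unrestrained_model_rejected(self, small_site):
        with pytest.raises(ValueError, match="restraint"):
            decouple_restraint_leg(small_site, seed=1)

    def test_zero_force_constants_give_zero(self, small_site):
        m = replace(small_site,
                    restraint=RestraintSpec(r0=6.0, theta0=75.0, psi0=0.0,
                                            k_r=0.0, k_theta=0.0, k_psi=0.0))
        res = decouple_restraint_leg(m, seed=2, n_steps=400, thin=4,
                                     schedule=default_schedule("trans_decouple_Na", 3))
        assert res.dg == pytest.approx(0.0, abs=1e-9)

    def test_species_symmetric_model_gives_equal_legs(self, restrained_site,
                                                      na_params):
        """With identical ion parameters the Na and K legs coincide
        within error (here: exactly, same seeds and parameters)."""
        same = IonParameters(species="K", epsilon=na_params.epsilon,
                             rmin_half=na_params.rmin_half)
        sched = default_schedule("trans_decouple_Na", 4)
        res_na = decouple_restraint_leg(restrained_site.with_ion(na_params),
                                        seed=3, schedule=sched, n_steps=800,
                                        thin=4)
        res_k = decouple_restraint_leg(restrained_site.with_ion(same), seed=3,
                                       schedule=sched, n_steps=800, thin=4)
        assert res_na.dg == pytest.approx(res_k.dg, abs=1e-9)

    def test_stiff_restraint_on_near_flat_landscape_matches_quadrature(self):
        """A fully decoupled ligand (zero charges, zero LJ) leaves the
        confined ion on a flat landscape; ΔG of switching the stiff
        distance restraint on then matches the ratio of configurational
        integrals computed by quadrature."""
        from pumpsel.toy_system import BindingSiteModel, LigandSpec
        from pumpsel import default_ion_parameters
        ghost = LigandSpec(ligand_id="L1", anchor=(3.5, 0.0, 0.0),
                           dipole_q=0.0, tip_epsilon=0.0)
        model = BindingSiteModel(
            ligands=(ghost,), ion=default_ion_parameters("Na"),
            confinement_radius=4.0, wall_k=1000.0, scenario_id="flat")
        r0, th0, ps0 = restraint_geometry((1e-9, 0, 0), model.anchors_p)
        # distance-only restraint to keep the oracle a 1-D radial integral
        spec = RestraintSpec(r0=r0, theta0=th0, psi0=ps0, k_r=25.0,
                             k_theta=0.0, k_psi=0.0)
        m = replace(model, restraint=spec)
        res = decouple_restraint_leg(
            m, seed=11, n_steps=9000, thin=3,
            schedule=default_schedule("trans_decouple_Na", 6))

        p1 = np.array(model.anchors_p[0])
        kt = KB * T_DEFAULT

        def boltz(x, y, z, restrained):
            r = np.sqrt(x * x + y * y + z * z)
            u = 0.5 * 1000.0 * np.maximum(0.0, r - 4.0) ** 2
            if restrained:
                d = np.sqrt((x - p1[0]) ** 2 + (y - p1[1]) ** 2 + (z - p1[2]) ** 2)
                u = u + 0.5 * 25.0 * (d - r0) ** 2
            return np.exp(-u / kt)

        # the ghost ligand is exactly decoupled, so the ion integral is 3-D
        grid = np.linspace(-4.6, 4.6, 161)
        X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
        z_free = boltz(X, Y, Z, False).sum()
        z_rest = boltz(X, Y, Z, True).sum()
        oracle = -kt * np.log(z_rest / z_free)
        assert res.dg == pytest.approx(oracle, abs=3 * res.error + 0.15)


class TestDeprotonation:
    def test_non_protonatable_ligand_rejected(self, small_site):
        with pytest.raises(ValueError, match="protonatable"):
            deprotonation_leg(small_site, "L3", seed=1)

    def test_frozen_geometry_matches_energy_difference(self):
        """On an effectively frozen model a linear charge perturbation
        has ΔG equal to the potential-energy difference (zero entropy),
        the linear-response limit of charging in a fixed field."""
        model = build_binding_site({
            "n_ligands": 3, "charged": ["L1"],
            "torsion": [[60.0, 1, 180.0]],     # very stiff arms, minimum at χ=0
            "wall_k": 2000.0, "confinement_radius": 0.05,
            "scenario_id": "frozen"})
        from pumpsel.toy_system import initial_site_state
        res = deprotonation_leg(model, "L1", seed=4, n_steps=2500, thin=5,
                                schedule=default_schedule("deprot_bulk", 5))
        ev0 = site_evaluator(_deprot_variant(model, "L1", 0.0))
        ev1 = site_evaluator(_deprot_variant(model, "L1", 1.0))
        s = initial_site_state(model)
        # relax torsions to the stiff-arm minimum (χ = 0 by construction)
        du = (ev1.energy(s.ion_pos, s.chi) - ev0.energy(s.ion_pos, s.chi))
        assert res.dg == pytest.approx(du, abs=3 * res.error + 0.6)

    def test_identical_environments_give_identical_legs(self):
        cfg = {"n_ligands": 4, "charged": ["L1"], "scenario_id": "env"}
        m = build_binding_site(cfg)
        sched = default_schedule("deprot_bulk", 4)
        a = deprotonation_leg(m, "L1", seed=6, schedule=sched, n_steps=800,
                              thin=4)
        b = deprotonation_leg(m, "L1", seed=6, schedule=sched, n_steps=800,
                              thin=4)
        assert a.dg == b.dg

    def test_negative_site_environment_raises_deprotonation_cost(self):
        """Charged neighbours make deprotonation less favourable: the
        site leg exceeds the neighbour-free reference leg, the pKa
        shifts up (proton retained)."""
        charged_cfg = {"n_ligands": 5, "charged": ["L1", "L2", "L3"],
                       "scenario_id": "neg_site"}
        plain_cfg = {"n_ligands": 5, "charged": ["L1"],
                     "scenario_id": "plain_site"}
        sched = default_schedule("deprot_bulk", 5)
        site = deprotonation_leg(build_binding_site(charged_cfg), "L1", seed=8,
                                 schedule=sched, n_steps=2000, thin=5)
        bulk = deprotonation_leg(build_binding_site(plain_cfg), "L1", seed=9,
                                 schedule=sched, n_steps=2000, thin=5)
        assert site.dg > bulk.dg + 3 * np.hypot(site.error, bulk.error)


def _deprot_variant(model, ligand_id, lam):
    idx = model.ligand_index(ligand_id)
    lig = model.ligands[idx]
    new = replace(lig, ionizable_q=lam * max(lig.ionizable_q, 1.0),
                  protonated=lam == 0.0)
    ligands = list(model.ligands)
    ligands[idx] = new
    return replace(model, ligands=tuple(ligands))
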