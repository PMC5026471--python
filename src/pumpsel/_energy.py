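"""Vectorised energy evaluators for the toy Hamiltonians.

One evaluator is built per (hashable) model and cached; it precomputes
static geometry/parameter arrays so that per-step Monte Carlo energy
calls and batched cross-energy evaluations over stored frames stay
cheap.  The public entry points remain ``toy_system.total_energy`` /
``energy_terms`` / ``droplet_energy``, which delegate here.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .constants import COULOMB


def _lj_arr(eps, rmin, r):
    x6 = (rmin / r) ** 6
    return eps * (x6 * x6 - 2.0 * x6)


class SiteEvaluator:
    """Precomputed-energy machine for one BindingSiteModel."""

    def __init__(self, model):
        self.model = model
        nl = len(model.ligands)
        self.nl = nl
        self.anchors = np.array([l.anchor for l in model.ligands], dtype=float)
        frames = [l.frame() for l in model.ligands]
        self.u = np.array([f[0] for f in frames])
        self.v = np.array([f[1] for f in frames])
        self.w = np.array([f[2] for f in frames])
        self.arm = np.array([l.arm_length for l in model.ligands])
        from .toy_system import _CONE_DEG, _INNER_FRAC
        cone = math.radians(_CONE_DEG)
        self.cos_cone, self.sin_cone = math.cos(cone), math.sin(cone)
        self.inner_frac = _INNER_FRAC
        self.tip_q = np.array([l.tip_charge for l in model.ligands])
        self.inner_q = np.array([l.inner_charge for l in model.ligands])
        self.tip_eps = np.array([l.tip_epsilon for l in model.ligands])
        self.tip_rh = np.array([l.effective_rmin_half for l in model.ligands])
        # intrinsic torsion terms, padded to a rectangular array
        nt = max(len(l.torsion) for l in model.ligands)
        self.t_k = np.zeros((nl, nt))
        self.t_n = np.zeros((nl, nt))
        self.t_d = np.zeros((nl, nt))
        for i, l in enumerate(model.ligands):
            for j, term in enumerate(l.torsion):
                self.t_k[i, j] = term.k
                self.t_n[i, j] = term.n
                self.t_d[i, j] = math.radians(term.delta)
        # boosting terms per ligand index
        self.boosts = []
        for b in model.boosts:
            idx = model.ligand_index(b.ligand_id)
            n_arr = np.arange(1, len(b.k) + 1, dtype=float)
            self.boosts.append((idx, b.strength, np.asarray(b.k, dtype=float),
                                np.radians(np.asarray(b.chi0, dtype=float)), n_arr))
        # ligand–ligand static pair tables (i < j)
        iu, ju = np.triu_indices(nl, k=1)
        self.pair_i, self.pair_j = iu, ju
        self.ll_eps = np.sqrt(self.tip_eps[iu] * self.tip_eps[ju])
        self.ll_rmin = self.tip_rh[iu] + self.tip_rh[ju]
        self.ion_lj_table = self._ion_lj(model.ion)

    def _ion_lj(self, ion):
        eps = np.empty(self.nl)
        rmin = np.empty(self.nl)
        for i, l in enumerate(self.model.ligands):
            eps[i], rmin[i] = ion.pair_lj(l.atom_class, l.tip_epsilon,
                                          l.effective_rmin_half)
        return eps, rmin

    # -- geometry ---------------------------------------------------------

    def positions(self, chi_deg):
        """Tip and inner charge-site positions; chi_deg shape (..., nl)."""
        chi = np.radians(np.asarray(chi_deg, dtype=float))
        cc = np.cos(chi)[..., None]
        sc = np.sin(chi)[..., None]
        direction = (self.cos_cone * self.w
                     + self.sin_cone * (cc * self.u + sc * self.v))
        tips = self.anchors + self.arm[:, None] * direction
        inners = self.anchors + self.inner_frac * (tips - self.anchors)
        return tips, inners

    # -- single-state energy ---------------------------------------------

    def terms(self, ion_pos, chi_deg, ion=None):
        m = self.model
        ion_pos = np.asarray(ion_pos, dtype=float)
        chi = np.asarray(chi_deg, dtype=float)
        if chi.shape != (self.nl,):
            raise ValueError("state torsion vector does not match the model")
        if not (np.all(np.isfinite(ion_pos)) and np.all(np.isfinite(chi))):
            raise ValueError("non-finite coordinates")
        tips, inners = self.positions(chi)
        d_tip = np.linalg.norm(tips - ion_pos, axis=-1)
        d_inn = np.linalg.norm(inners - ion_pos, axis=-1)
        if np.any(d_tip < 1e-9) or np.any(d_inn < 1e-9):
            raise ValueError("ion overlaps a ligand charge site")
        ion_obj = ion if ion is not None else m.ion
        charge = ion_obj.charge
        e_coul = COULOMB * charge * (np.sum(self.tip_q / d_tip)
                                     + np.sum(self.inner_q / d_inn))
        eps, rmin = (self.ion_lj_table if ion is None or ion is m.ion
                     else self._ion_lj(ion))
        e_lj = float(np.sum(_lj_arr(eps, rmin, d_tip)))

        iu, ju = self.pair_i, self.pair_j
        e_ll = 0.0
        if iu.size:
            for pa, qa in ((tips, self.tip_q), (inners, self.inner_q)):
                for pb, qb in ((tips, self.tip_q), (inners, self.inner_q)):
                    d = np.linalg.norm(pa[iu] - pb[ju], axis=-1)
                    e_ll += float(np.sum(qa[iu] * qb[ju] / d))
            e_ll *= COULOMB
            d_tt = np.linalg.norm(tips[iu] - tips[ju], axis=-1)
            e_ll += float(np.sum(_lj_arr(self.ll_eps, self.ll_rmin, d_tt)))

        chi_r = np.radians(chi)
        e_tors = float(np.sum(self.t_k * (1.0 + np.cos(self.t_n * chi_r[:, None]
                                                       - self.t_d))))
        e_boost = 0.0
        for idx, s, k, c0, n_arr in self.boosts:
            e_boost -= s * float(np.sum(k * (1.0 + np.cos(n_arr * (chi_r[idx] - c0)))))

        d0 = float(np.linalg.norm(ion_pos))
        e_wall = 0.5 * m.wall_k * max(0.0, d0 - m.confinement_radius) ** 2

        e_rest = 0.0
        if m.restraint is not None:
            from .toy_system import restraint_energy
            e_rest = restraint_energy(ion_pos, m.restraint, m.anchors_p)

        return {
            "coulomb_ion": float(e_coul),
            "lj_ion": e_lj,
            "ligand_ligand": e_ll,
            "torsion": e_tors,
            "boost": e_boost,
            "wall": e_wall,
            "restraint": e_rest,
        }

    def energy(self, ion_pos, chi_deg, ion=None):
        return float(sum(self.terms(ion_pos, chi_deg, ion=ion).values()))

    # -- batched cross-energies ------------------------------------------

    def batch_energy(self, ion_pos_arr, chi_arr, ion=None, restraint_factor=1.0):
        """Total energies for frames; ion_pos_arr (n,3), chi_arr (n,nl).

        ``ion`` swaps the ion parameter set (the alchemical cross-
        evaluation path); ``restraint_factor`` scales the restraint term
        (the decoupling path).  Boost terms are *excluded*: estimation
        always runs on zero-boost frames.
        """
        m = self.model
        ion_pos_arr = np.asarray(ion_pos_arr, dtype=float)
        chi_arr = np.asarray(chi_arr, dtype=float)
        n = len(ion_pos_arr)
        tips, inners = self.positions(chi_arr)          # (n, nl, 3)
        d_tip = np.linalg.norm(tips - ion_pos_arr[:, None, :], axis=-1)
        d_inn = np.linalg.norm(inners - ion_pos_arr[:, None, :], axis=-1)
        ion_obj = ion if ion is not None else m.ion
        e = COULOMB * ion_obj.charge * (np.sum(self.tip_q / d_tip, axis=1)
                                        + np.sum(self.inner_q / d_inn, axis=1))
        eps, rmin = (self.ion_lj_table if ion is None or ion is m.ion
                     else self._ion_lj(ion))
        e += np.sum(_lj_arr(eps, rmin, d_tip), axis=1)

        iu, ju = self.pair_i, self.pair_j
        if iu.size:
            ll = np.zeros(n)
            for pa, qa in ((tips, self.tip_q), (inners, self.inner_q)):
                for pb, qb in ((tips, self.tip_q), (inners, self.inner_q)):
                    d = np.linalg.norm(pa[:, iu] - pb[:, ju], axis=-1)
                    ll += np.sum(qa[iu] * qb[ju] / d, axis=1)
            e += COULOMB * ll
            d_tt = np.linalg.norm(tips[:, iu] - tips[:, ju], axis=-1)
            e += np.sum(_lj_arr(self.ll_eps, self.ll_rmin, d_tt), axis=1)

        chi_r = np.radians(chi_arr)
        e += np.sum(self.t_k * (1.0 + np.cos(self.t_n * chi_r[..., None] - self.t_d)),
                    axis=(1, 2))
        d0 = np.linalg.norm(ion_pos_arr, axis=1)
        e += 0.5 * m.wall_k * np.maximum(0.0, d0 - m.confinement_radius) ** 2
        if m.restraint is not None and restraint_factor != 0.0:
            from .toy_system import restraint_energy
            spec = m.restraint
            e += restraint_factor * np.array(
                [restraint_energy(p, spec, m.anchors_p) for p in ion_pos_arr])
        return e


class DropletEvaluator:
    """Precomputed-energy machine for one BulkDropletModel."""

    def __init__(self, model):
        self.model = model
        self.ion_lj = model.ion.pair_lj("O_solvent", model.solvent_epsilon,
                                        model.solvent_rmin_half)
        m = model.n_solvent
        self.pair_i, self.pair_j = np.triu_indices(m, k=1)

    def _ion_pair(self, ion):
        if ion is None or ion is self.model.ion:
            return self.ion_lj
        return ion.pair_lj("O_solvent", self.model.solvent_epsilon,
                           self.model.solvent_rmin_half)

    def energy(self, ion_pos, o_pos, o_dir, ion=None):
        m = self.model
        ion_obj = ion if ion is not None else m.ion
        h_pos = o_pos + m.dipole_length * o_dir
        d_o = np.linalg.norm(o_pos - ion_pos, axis=-1)
        d_h = np.linalg.norm(h_pos - ion_pos, axis=-1)
        e = COULOMB * ion_obj.charge * m.solvent_q * (np.sum(1.0 / d_h)
                                                      - np.sum(1.0 / d_o))
        eps, rmin = self._ion_pair(ion)
        e += float(np.sum(_lj_arr(eps, rmin, d_o)))
        iu, ju = self.pair_i, self.pair_j
        if iu.size:
            q = m.solvent_q
            for pa, qa in ((o_pos, -q), (h_pos, q)):
                for pb, qb in ((o_pos, -q), (h_pos, q)):
                    d = np.linalg.norm(pa[iu] - pb[ju], axis=-1)
                    e += COULOMB * qa * qb * float(np.sum(1.0 / d))
            d_oo = np.linalg.norm(o_pos[iu] - o_pos[ju], axis=-1)
            e += float(np.sum(_lj_arr(m.solvent_epsilon, 2 * m.solvent_rmin_half, d_oo)))
        # boundary wall on ion and solvent O sites
        d_all = np.concatenate(([np.linalg.norm(ion_pos)],
                                np.linalg.norm(o_pos, axis=-1)))
        e += 0.5 * m.wall_k * float(np.sum(np.maximum(0.0, d_all - m.radius) ** 2))
        return float(e)

    def batch_energy(self, ion_pos_arr, o_pos_arr, o_dir_arr, ion=None):
        """Frame-wise total energies under a (possibly swapped) ion."""
        return np.array([self.energy(ion_pos_arr[t], o_pos_arr[t], o_dir_arr[t],
                                     ion=ion)
                         for t in range(len(ion_pos_arr))])


@lru_cache(maxsize=256)
def _site_evaluator_cached(model):
    return SiteEvaluator(model)


@lru_cache(maxsize=256)
def _droplet_evaluator_cached(model):
    return DropletEvaluator(model)


def site_evaluator(model) -> SiteEvaluator:
    try:
        return _site_evaluator_cached(model)
    except TypeError:  # unhashable (shouldn't happen for frozen specs)
        return SiteEvaluator(model)


def droplet_evaluator(model) -> DropletEvaluator:
    try:
        return _droplet_evaluator_cached(model)
    except TypeError:
        return DropletEvaluator(model)
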