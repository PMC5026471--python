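"""Reduced binding-site and bulk-droplet models.

This module defines the desk-scale Hamiltonians used throughout the
package: a confined mobile ion coordinated by a small number of flexible
dipolar ligands ("arms" anchored on a rigid shell, each with one periodic
side-chain-like torsion χ), and a separate droplet of solvent dipoles
standing in for the bulk phase.  The two ion species differ only in their
nonbonded (Lennard-Jones, optionally pair-specific) parameters, which is
what makes alchemical Na⁺↔K⁺ transformations meaningful.

Energy terms: Coulomb (constant 332.0716 kcal·Å/mol/e²), Lennard-Jones in
the ε/r_min convention with pair-specific overrides, intrinsic torsion
cosine series, a half-harmonic spherical confinement wall replacing an
implicit-boundary treatment, and an optional ion translational restraint
u_trans = ½[k_r(r−r0)² + k_θ(θ−θ0)² + k_ψ(ψ−ψ0)²] defined against three
fixed anchor points p1, p2, p3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

from .constants import T_DEFAULT

__all__ = [
    "IonParameters",
    "CosineTerm",
    "TorsionBoost",
    "LigandSpec",
    "RestraintSpec",
    "BindingSiteModel",
    "BulkDropletModel",
    "SiteState",
    "DropletState",
    "build_binding_site",
    "build_bulk_droplet",
    "default_ion_parameters",
    "initial_site_state",
    "initial_droplet_state",
    "total_energy",
    "energy_terms",
    "droplet_energy",
    "rotate_model",
    "restraint_energy",
    "restraint_geometry",
    "model_to_json",
    "model_from_json",
    "wrap_degrees",
]

# Default tip-atom (coordinating oxygen-like) LJ parameters
_TIP_EPS = 0.12        # kcal/mol
_TIP_RMIN_HALF = 1.70  # Å

# Ligand-arm geometry: the arm swings on a cone whose axis is the inward
# anchor direction tilted sideways, so χ genuinely modulates the tip–ion
# distance (a purely radial cone axis would decouple χ from coordination).
_CONE_DEG = 55.0
_TILT_DEG = 25.0
_INNER_FRAC = 0.40     # position of the + partial charge along the arm

_MUTATION_RADIUS_INCREMENT = 0.2  # Å added to the tip r_min on D→N-style mutation


def wrap_degrees(x):
    """Wrap angle(s) in degrees to [-180, 180)."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def _wrap_radians(x):
    """Wrap angle(s) in radians to (-π, π]."""
    return -((math.pi - np.asarray(x, dtype=float)) % (2.0 * math.pi) - math.pi)


# ---------------------------------------------------------------------------
# Ion parameters


@dataclass(frozen=True)
class IonParameters:
    """Nonbonded parameters of one monovalent cation.

    ``epsilon``/``rmin_half`` follow the ε, R_min/2 convention; the
    combined minimum-distance for a pair is the sum of the two halves and
    the combined well depth the geometric mean, unless a pair-specific
    override for a ligand atom class is present in ``nbfix`` (mapping
    atom class → (ε_ij, r_min_ij), already combined).
    """

    species: str
    epsilon: float
    rmin_half: float
    charge: float = 1.0
    nbfix: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.rmin_half <= 0:
            raise ValueError(f"rmin_half must be > 0, got {self.rmin_half}")

    def pair_lj(self, atom_class: str, eps_other: float, rmin_half_other: float) -> tuple[float, float]:
        """Combined (ε_ij, r_min_ij) against a ligand atom class."""
        for cls, eps, rmin in self.nbfix:
            if cls == atom_class:
                return eps, rmin
        return math.sqrt(self.epsilon * eps_other), self.rmin_half + rmin_half_other


# Published fixed-charge monovalent-ion LJ parameters (ε kcal/mol, R_min/2 Å)
_DEFAULT_IONS = {
    "Na": (0.0469, 1.41075),
    "K": (0.0870, 1.76375),
}


def default_ion_parameters(species: str) -> IonParameters:
    """Packaged default parameters for Na⁺ or K⁺."""
    try:
        eps, rh = _DEFAULT_IONS[species]
    except KeyError:
        raise ValueError(f"no default parameters for species {species!r}") from None
    return IonParameters(species=species, epsilon=eps, rmin_half=rh)


# ---------------------------------------------------------------------------
# Ligands, restraints, models


@dataclass(frozen=True)
class CosineTerm:
    """One term k·(1 + cos(n·χ − δ)) of a periodic torsion potential."""

    k: float       # kcal/mol
    n: int         # multiplicity
    delta: float   # phase, degrees

    def energy(self, chi_deg):
        return self.k * (1.0 + np.cos(np.radians(self.n * np.asarray(chi_deg) - self.delta)))


@dataclass(frozen=True)
class TorsionBoost:
    """A scaled, sign-reversed boosting potential attached to one torsion.

    Contributes −strength·Σ_n k_n{1 + cos[n(χ − χ0_n)]} to the total
    energy, flattening the rotamer barriers of that torsion.
    """

    ligand_id: str
    k: tuple[float, ...]          # kcal/mol, term n has multiplicity n
    chi0: tuple[float, ...]       # degrees
    strength: float = 1.0

    def energy(self, chi_deg):
        chi = np.asarray(chi_deg, dtype=float)
        u = np.zeros_like(chi)
        for n, (kn, c0) in enumerate(zip(self.k, self.chi0), start=1):
            u = u + kn * (1.0 + np.cos(np.radians(n * (chi - c0))))
        return -self.strength * u


@dataclass(frozen=True)
class LigandSpec:
    """One flexible dipolar coordinating arm.

    The arm pivots about a fixed anchor; its single torsion χ moves the
    tip (the coordinating, oxygen-like atom carrying the − partial
    charge) on a tilted cone.  ``ionizable_q`` is the magnitude of the
    dissociable charge carried at the tip when the ligand is acidic and
    deprotonated; ``protonated`` neutralises it (charges only — the LJ
    surface is untouched), while ``mutated`` neutralises it *and* bulks
    up the tip radius, emulating a charge-neutralising D→N substitution.
    """

    ligand_id: str
    anchor: tuple[float, float, float]
    arm_length: float = 2.2
    dipole_q: float = 0.45
    ionizable_q: float = 0.0
    protonated: bool = False
    mutated: bool = False
    atom_class: str = "O_carbonyl"
    tip_epsilon: float = _TIP_EPS
    tip_rmin_half: float = _TIP_RMIN_HALF
    torsion: tuple[CosineTerm, ...] = (CosineTerm(1.5, 3, 0.0), CosineTerm(0.8, 1, 0.0))
    #: explicit cone frame (u, v, w) rows; None → derived from the anchor
    frame_axes: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self):
        if self.arm_length <= 0:
            raise ValueError("arm_length must be positive")
        a = np.asarray(self.anchor, dtype=float)
        if np.linalg.norm(a) < 1e-9:
            raise ValueError("ligand anchor must not sit at the origin")

    @property
    def tip_charge(self) -> float:
        q = -self.dipole_q
        if self.ionizable_q > 0 and not self.protonated and not self.mutated:
            q -= self.ionizable_q
        return q

    @property
    def inner_charge(self) -> float:
        return self.dipole_q

    @property
    def net_charge(self) -> float:
        return self.tip_charge + self.inner_charge

    @property
    def effective_rmin_half(self) -> float:
        if self.mutated:
            return self.tip_rmin_half + _MUTATION_RADIUS_INCREMENT
        return self.tip_rmin_half

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Deterministic orthonormal cone frame (u, v, w) for this anchor."""
        if self.frame_axes is not None:
            u, v, w = (np.asarray(x, dtype=float) for x in self.frame_axes)
            return u, v, w
        a = np.asarray(self.anchor, dtype=float)
        inward = -a / np.linalg.norm(a)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, inward)) > 0.95:
            ref = np.array([1.0, 0.0, 0.0])
        u0 = ref - np.dot(ref, inward) * inward
        u0 /= np.linalg.norm(u0)
        tilt = math.radians(_TILT_DEG)
        w = math.cos(tilt) * inward + math.sin(tilt) * u0
        w /= np.linalg.norm(w)
        u = np.cross(np.cross(w, u0), w)
        nu = np.linalg.norm(u)
        if nu < 1e-12:  # degenerate tilt
            u = np.cross(w, ref)
            nu = np.linalg.norm(u)
        u /= nu
        v = np.cross(w, u)
        return u, v, w

    def tip_position(self, chi_deg: float) -> np.ndarray:
        u, v, w = self.frame()
        a = np.asarray(self.anchor, dtype=float)
        cone = math.radians(_CONE_DEG)
        chi = math.radians(chi_deg)
        direction = math.cos(cone) * w + math.sin(cone) * (math.cos(chi) * u + math.sin(chi) * v)
        return a + self.arm_length * direction

    def inner_position(self, chi_deg: float) -> np.ndarray:
        a = np.asarray(self.anchor, dtype=float)
        return a + _INNER_FRAC * (self.tip_position(chi_deg) - a)

    def torsion_energy(self, chi_deg) -> float:
        return sum(t.energy(chi_deg) for t in self.torsion)


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic ion translational restraint against anchors p1, p2, p3.

    u_trans = ½[k_r(r−r0)² + k_θ(θ−θ0)² + k_ψ(ψ−ψ0)²], with r the
    ion–p1 distance, θ the ion–p1–p2 angle and ψ the ion–p1–p2–p3
    torsion.  Angle inputs/outputs in degrees, force constants in
    kcal/mol/Å² and kcal/mol/rad².
    """

    r0: float
    theta0: float
    psi0: float
    k_r: float = 10.0
    k_theta: float = 200.0
    k_psi: float = 200.0

    def __post_init__(self):
        if min(self.k_r, self.k_theta, self.k_psi) < 0:
            raise ValueError("restraint force constants must be >= 0")
        if not (0.0 < self.theta0 < 180.0):
            raise ValueError("theta0 must lie strictly between 0 and 180 degrees")

    def scaled(self, factor: float) -> "RestraintSpec":
        return replace(self, k_r=self.k_r * factor, k_theta=self.k_theta * factor,
                       k_psi=self.k_psi * factor)


@dataclass(frozen=True)
class BindingSiteModel:
    """The reduced, flexible binding site: ion + dipolar arms + walls."""

    ligands: tuple[LigandSpec, ...]
    ion: IonParameters
    confinement_radius: float = 3.5
    wall_k: float = 20.0
    temperature: float = T_DEFAULT
    restraint: RestraintSpec | None = None
    anchors_p: tuple[tuple[float, float, float], ...] = (
        (6.0, 0.0, 0.0), (0.0, 6.0, 0.0), (0.0, 0.0, 6.0))
    boosts: tuple[TorsionBoost, ...] = ()
    scenario_id: str = "site"

    def __post_init__(self):
        if self.confinement_radius <= 0 or self.wall_k < 0:
            raise ValueError("confinement geometry must be positive")
        p1, p2, p3 = (np.asarray(p, dtype=float) for p in self.anchors_p)
        if np.linalg.norm(np.cross(p2 - p1, p3 - p1)) < 1e-9:
            raise ValueError("anchor points p1, p2, p3 must be non-collinear")
        seen = set()
        for lig in self.ligands:
            key = tuple(np.round(lig.anchor, 6))
            if key in seen:
                raise ValueError("overlapping ligand anchors")
            seen.add(key)
            if np.linalg.norm(np.asarray(lig.anchor)) > self.confinement_radius + lig.arm_length + 3.0:
                raise ValueError("ligand anchor far outside the confinement region")

    @property
    def n_torsions(self) -> int:
        return len(self.ligands)

    @property
    def ligand_net_charge(self) -> float:
        return sum(l.net_charge for l in self.ligands)

    def with_ion(self, ion: IonParameters) -> "BindingSiteModel":
        return replace(self, ion=ion)

    def with_boosts(self, boosts: Sequence[TorsionBoost]) -> "BindingSiteModel":
        return replace(self, boosts=tuple(boosts))

    def ligand_index(self, ligand_id: str) -> int:
        for i, l in enumerate(self.ligands):
            if l.ligand_id == ligand_id:
                return i
        raise KeyError(f"no ligand {ligand_id!r} in model")


@dataclass
class SiteState:
    """Coordinates of a binding-site model: ion xyz (Å) + torsions (deg)."""

    ion_pos: np.ndarray
    chi: np.ndarray

    def copy(self) -> "SiteState":
        return SiteState(self.ion_pos.copy(), self.chi.copy())


@dataclass(frozen=True)
class BulkDropletModel:
    """An ion in a droplet of mobile solvent dipoles with a soft boundary.

    Each solvent particle is a rigid two-charge dipole (−q at its LJ-
    bearing, oxygen-like site, +q displaced by ``dipole_length`` along its
    orientation vector).  A half-harmonic wall at ``radius`` confines all
    particles, standing in for an implicit bulk boundary.
    """

    ion: IonParameters
    n_solvent: int = 8
    radius: float = 5.5
    wall_k: float = 10.0
    solvent_q: float = 0.60
    dipole_length: float = 0.9
    solvent_epsilon: float = 0.1521
    solvent_rmin_half: float = 1.7682
    temperature: float = T_DEFAULT
    scenario_id: str = "bulk"

    def __post_init__(self):
        if self.n_solvent <= 0:
            raise ValueError("droplet needs at least one solvent dipole")
        if self.radius <= 0:
            raise ValueError("droplet radius must be positive")

    def with_ion(self, ion: IonParameters) -> "BulkDropletModel":
        return replace(self, ion=ion)


@dataclass
class DropletState:
    """Coordinates of a droplet: ion xyz + solvent positions/orientations."""

    ion_pos: np.ndarray
    solvent_pos: np.ndarray     # (M, 3)
    solvent_dir: np.ndarray     # (M, 3), unit vectors

    def copy(self) -> "DropletState":
        return DropletState(self.ion_pos.copy(), self.solvent_pos.copy(),
                            self.solvent_dir.copy())


# ---------------------------------------------------------------------------
# Restraint geometry and energy


def restraint_geometry(ion_pos, anchors_p) -> tuple[float, float, float]:
    """(r, θ_deg, ψ_deg) of the ion against anchor points p1, p2, p3."""
    l1 = np.asarray(ion_pos, dtype=float)
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in anchors_p)
    v = l1 - p1
    r = float(np.linalg.norm(v))
    if r < 1e-9:
        raise ValueError("ion coincides with anchor p1; restraint geometry undefined")
    a = p2 - p1
    cos_t = np.dot(v, a) / (r * np.linalg.norm(a))
    theta = math.degrees(math.acos(min(1.0, max(-1.0, cos_t))))
    # dihedral l1-p1-p2-p3
    b1, b2, b3 = p1 - l1, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    psi = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    return r, theta, psi


def restraint_energy(ion_pos, spec: RestraintSpec, anchors_p) -> float:
    """u_trans of the ion: ½[k_r(r−r0)² + k_θ(θ−θ0)² + k_ψ(ψ−ψ0)²].

    Angles are converted to radians and angular differences wrapped to
    (−π, π] before squaring.
    """
    r, theta, psi = restraint_geometry(ion_pos, anchors_p)
    dr = r - spec.r0
    dth = _wrap_radians(math.radians(theta - spec.theta0))
    dps = _wrap_radians(math.radians(psi - spec.psi0))
    return 0.5 * (spec.k_r * dr * dr
                  + spec.k_theta * float(dth) ** 2
                  + spec.k_psi * float(dps) ** 2)


# ---------------------------------------------------------------------------
# Site energy


def energy_terms(model: BindingSiteModel, state: SiteState,
                 ion: IonParameters | None = None) -> dict[str, float]:
    """Energy decomposition of a binding-site configuration (kcal/mol).

    Terms: ion–ligand Coulomb, ion–tip Lennard-Jones (honouring pair
    overrides), ligand–ligand nonbonded, intrinsic torsions, boosting
    modifiers, confinement wall, translational restraint.  ``ion``
    overrides the model's ion parameters, which is how alchemical
    cross-energies are evaluated on stored frames.
    """
    from ._energy import site_evaluator
    return site_evaluator(model).terms(state.ion_pos, state.chi, ion=ion)


def total_energy(model: BindingSiteModel, state: SiteState,
                 ion: IonParameters | None = None) -> float:
    """Total potential energy of a binding-site configuration (kcal/mol)."""
    return float(sum(energy_terms(model, state, ion=ion).values()))


# ---------------------------------------------------------------------------
# Droplet energy


def droplet_energy(model: BulkDropletModel, state: DropletState,
                   ion: IonParameters | None = None) -> float:
    """Total potential energy of a droplet configuration (kcal/mol)."""
    from ._energy import droplet_evaluator
    return droplet_evaluator(model).energy(
        np.asarray(state.ion_pos, dtype=float),
        np.asarray(state.solvent_pos, dtype=float),
        np.asarray(state.solvent_dir, dtype=float),
        ion=ion)


# ---------------------------------------------------------------------------
# Builders


def _anchor_directions(n: int) -> np.ndarray:
    """Deterministic, well-spread unit vectors for n ligand anchors."""
    octa = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    if n <= 6:
        return octa[:n]
    # golden-spiral placement for larger sites
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def build_binding_site(config: dict) -> BindingSiteModel:
    """Construct a binding-site model from a scenario configuration.

    Recognised keys (all optional unless noted): ``n_ligands``,
    ``charged`` (ids carrying a dissociable −1), ``protonated``,
    ``mutated``, ``anchor_radius``, ``arm_length``, ``dipole_q``,
    ``confinement_radius``, ``wall_k``, ``temperature``, ``ion``
    (species name or parameter dict), ``restraint`` (RestraintSpec
    fields), ``scenario_id``, ``torsion`` (list of [k, n, delta]).
    Construction is deterministic: identical configs give identical
    serialised models.
    """
    n = int(config.get("n_ligands", 6))
    if n < 1:
        raise ValueError("need at least one ligand")
    anchor_radius = float(config.get("anchor_radius", 4.0))
    if anchor_radius <= 0:
        raise ValueError("anchor_radius must be positive")
    ids = [f"L{i+1}" for i in range(n)]
    charged = set(config.get("charged", ()))
    protonated = set(config.get("protonated", ()))
    mutated = set(config.get("mutated", ()))
    for label, group in (("charged", charged), ("protonated", protonated),
                         ("mutated", mutated)):
        unknown = group - set(ids)
        if unknown:
            raise ValueError(f"{label} flags reference unknown ligands: {sorted(unknown)}")
    torsion = tuple(CosineTerm(float(k), int(nn), float(d))
                    for k, nn, d in config.get(
                        "torsion", [[1.5, 3, 0.0], [0.8, 1, 0.0]]))
    dirs = _anchor_directions(n)
    ligands = tuple(
        LigandSpec(
            ligand_id=ids[i],
            anchor=tuple(anchor_radius * dirs[i]),
            arm_length=float(config.get("arm_length", 2.2)),
            dipole_q=float(config.get("dipole_q", 0.45)),
            ionizable_q=1.0 if ids[i] in charged else 0.0,
            protonated=ids[i] in protonated,
            mutated=ids[i] in mutated,
            torsion=torsion,
        )
        for i in range(n)
    )
    ion_cfg = config.get("ion", "Na")
    ion = (default_ion_parameters(ion_cfg) if isinstance(ion_cfg, str)
           else IonParameters(**ion_cfg))
    restraint = None
    if "restraint" in config and config["restraint"] is not None:
        restraint = RestraintSpec(**config["restraint"])
    return BindingSiteModel(
        ligands=ligands,
        ion=ion,
        confinement_radius=float(config.get("confinement_radius", 3.5)),
        wall_k=float(config.get("wall_k", 20.0)),
        temperature=float(config.get("temperature", T_DEFAULT)),
        restraint=restraint,
        scenario_id=str(config.get("scenario_id", "site")),
    )


def build_bulk_droplet(config: dict | None = None,
                       ion: IonParameters | None = None) -> BulkDropletModel:
    """Construct the bulk-droplet model (defaults emulate an ion-in-water sphere)."""
    config = dict(config or {})
    if ion is None:
        ion_cfg = config.pop("ion", "Na")
        ion = (default_ion_parameters(ion_cfg) if isinstance(ion_cfg, str)
               else IonParameters(**ion_cfg))
    else:
        config.pop("ion", None)
    return BulkDropletModel(ion=ion, **config)


def initial_site_state(model: BindingSiteModel, rng: np.random.Generator | None = None) -> SiteState:
    """Ion at the origin, torsions at 0° (or jittered if an rng is given)."""
    chi = np.zeros(model.n_torsions)
    ion = np.zeros(3)
    if rng is not None:
        chi = wrap_degrees(rng.uniform(-180.0, 180.0, model.n_torsions))
        ion = rng.normal(scale=0.3, size=3)
    return SiteState(ion_pos=ion, chi=chi)


def initial_droplet_state(model: BulkDropletModel,
                          rng: np.random.Generator | None = None) -> DropletState:
    """Ion at the centre, solvent on a deterministic shell (jittered with rng)."""
    dirs = _anchor_directions(model.n_solvent)
    pos = 0.6 * model.radius * dirs
    orient = -dirs  # negative end toward the ion
    if rng is not None:
        pos = pos + rng.normal(scale=0.2, size=pos.shape)
        raw = orient + rng.normal(scale=0.2, size=orient.shape)
        orient = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    return DropletState(ion_pos=np.zeros(3), solvent_pos=pos, solvent_dir=orient)


def rotate_model(model: BindingSiteModel, rotation: np.ndarray) -> BindingSiteModel:
    """Rigidly rotate a binding-site model (anchors, frames, restraint points).

    Together with rotating the ion position of a state, this leaves the
    total energy invariant: the restraint and the ligand geometry are
    purely internal.
    """
    R = np.asarray(rotation, dtype=float)
    ligands = []
    for lig in model.ligands:
        u, v, w = lig.frame()
        ligands.append(replace(
            lig,
            anchor=tuple(R @ np.asarray(lig.anchor)),
            frame_axes=(tuple(R @ u), tuple(R @ v), tuple(R @ w)),
        ))
    return replace(model, ligands=tuple(ligands),
                   anchors_p=tuple(tuple(R @ np.asarray(p)) for p in model.anchors_p))


# ---------------------------------------------------------------------------
# Serialization (lossless JSON round trip)


def model_to_json(model: BindingSiteModel | BulkDropletModel) -> str:
    kind = "site" if isinstance(model, BindingSiteModel) else "droplet"
    return json.dumps({"kind": kind, "model": asdict(model)}, sort_keys=True)


def _ion_from_dict(d: dict) -> IonParameters:
    d = dict(d)
    d["nbfix"] = tuple(tuple(x) for x in d.get("nbfix", ()))
    return IonParameters(**d)


def model_from_json(text: str) -> BindingSiteModel | BulkDropletModel:
    doc = json.loads(text)
    payload = doc["model"]
    payload["ion"] = _ion_from_dict(payload["ion"])
    if doc["kind"] == "droplet":
        return BulkDropletModel(**payload)
    ligands = []
    for ld in payload["ligands"]:
        ld = dict(ld)
        ld["anchor"] = tuple(ld["anchor"])
        ld["torsion"] = tuple(CosineTerm(**t) for t in ld["torsion"])
        if ld.get("frame_axes") is not None:
            ld["frame_axes"] = tuple(tuple(x) for x in ld["frame_axes"])
        ligands.append(LigandSpec(**ld))
    payload["ligands"] = tuple(ligands)
    payload["anchors_p"] = tuple(tuple(p) for p in payload["anchors_p"])
    if payload.get("restraint") is not None:
        payload["restraint"] = RestraintSpec(**payload["restraint"])
    boosts = []
    for bd in payload.get("boosts", ()):
        bd = dict(bd)
        bd["k"] = tuple(bd["k"])
        bd["chi0"] = tuple(bd["chi0"])
        boosts.append(TorsionBoost(**bd))
    payload["boosts"] = tuple(boosts)
    return BindingSiteModel(**payload)
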