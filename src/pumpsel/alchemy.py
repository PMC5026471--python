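"""λ-coupled alchemical transformations on the toy models.

Legs implemented:

* Na⁺↔K⁺ ion swap at a binding site or in the bulk droplet, via the
  three-point scheme: sample the two endpoints and the hybrid ion at the
  interpolation midpoint, cross-evaluate every frame under every
  parameter set, and solve the adjacent free-energy differences
  self-consistently with multistate WHAM; their sum is ΔG for the swap.
* gradual decoupling of the ion translational restraint (per species),
  with the restraint energy scaled linearly by λ.
* deprotonation of an acidic ligand, with the dissociable tip charge
  grown linearly in λ (charges only — no topology change), used by the
  pKa thermodynamic cycle.

All legs return the free-energy difference together with a 10-block
standard error and an overlap diagnostic (effective sample sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .constants import KB as KB_LOCAL

from ._energy import droplet_evaluator, site_evaluator
from .estimators import WHAMResult, wham_multistate
from .sampling import run_mc
from .toy_system import (
    BindingSiteModel,
    BulkDropletModel,
    IonParameters,
    default_ion_parameters,
)

__all__ = [
    "LambdaSchedule",
    "CrossEnergyMatrix",
    "AlchemyResult",
    "default_schedule",
    "interpolate_ion_params",
    "three_point_alchemy",
    "decouple_restraint_leg",
    "deprotonation_leg",
]

#: default λ-window counts per leg (site swap 16, bulk swap 11,
#: restraint decoupling mirrors the site setup, deprotonation 24/10)
DEFAULT_WINDOW_COUNTS = {
    "site_ion_swap": 16,
    "bulk_ion_swap": 11,
    "trans_decouple_Na": 16,
    "trans_decouple_K": 16,
    "deprot_site": 24,
    "deprot_bulk": 10,
}

#: warn when a state's effective cross-weight sample size drops below this
ESS_WARN_THRESHOLD = 50.0


@dataclass(frozen=True)
class LambdaSchedule:
    """Ascending λ values (0 and 1 included) for one alchemical leg."""

    label: str
    lambdas: tuple[float, ...]

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.size < 2 or lam[0] != 0.0 or lam[-1] != 1.0:
            raise ValueError("schedule must start at λ=0 and end at λ=1")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("λ values must be strictly ascending")
        if np.any((lam < 0) | (lam > 1)):
            raise ValueError("λ values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.lambdas)


def default_schedule(label: str, n_windows: int | None = None) -> LambdaSchedule:
    """Evenly spaced λ schedule with the leg's default window count."""
    if n_windows is None:
        try:
            n_windows = DEFAULT_WINDOW_COUNTS[label]
        except KeyError:
            raise ValueError(f"unknown leg label {label!r}") from None
    return LambdaSchedule(label=label,
                          lambdas=tuple(np.linspace(0.0, 1.0, n_windows)))


@dataclass
class CrossEnergyMatrix:
    """Frames × states energies with frame provenance."""

    energies: np.ndarray        # (n_frames, K), kcal/mol
    origin: np.ndarray          # (n_frames,), generating-state index
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.origin = np.asarray(self.origin, dtype=int)
        if self.energies.ndim != 2 or len(self.origin) != len(self.energies):
            raise ValueError("energies must be (n_frames, K) with one origin per frame")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite cross-energies")


@dataclass
class AlchemyResult:
    """One alchemical leg: ΔG with block error and WHAM diagnostics."""

    label: str
    dg: float                    # kcal/mol
    error: float                 # 10-block standard deviation
    wham: WHAMResult | None = None
    block_estimates: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ion-parameter interpolation


def interpolate_ion_params(na: IonParameters, k: IonParameters,
                           lam: float) -> IonParameters:
    """Linear LJ/pair-override interpolation between two ion parameter sets.

    λ=0 returns the first set exactly and λ=1 the second; the charge is
    left unchanged (both species are monovalent cations).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("λ must lie in [0, 1]")
    if na.charge != k.charge:
        raise ValueError("ion swap assumes equal charges")
    if lam == 0.0:
        return na
    if lam == 1.0:
        return k
    na_fix = {c: (e, r) for c, e, r in na.nbfix}
    k_fix = {c: (e, r) for c, e, r in k.nbfix}
    if set(na_fix) != set(k_fix):
        raise ValueError("pair-override (NBFIX) atom classes differ between species")
    nbfix = tuple(
        (c,
         (1 - lam) * na_fix[c][0] + lam * k_fix[c][0],
         (1 - lam) * na_fix[c][1] + lam * k_fix[c][1])
        for c in sorted(na_fix))
    return IonParameters(
        species=f"hybrid({lam:g})",
        epsilon=(1 - lam) * na.epsilon + lam * k.epsilon,
        rmin_half=(1 - lam) * na.rmin_half + lam * k.rmin_half,
        charge=na.charge,
        nbfix=nbfix,
    )


# ---------------------------------------------------------------------------
# Shared machinery


def _spawned_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _batch_fn(model):
    """(frames → energies under state k) evaluator factory for a model."""
    if isinstance(model, BindingSiteModel):
        ev = site_evaluator(model)

        def fn(series, **kw):
            return ev.batch_energy(series.ion_pos, series.chi, **kw)
        return fn
    if isinstance(model, BulkDropletModel):
        ev = droplet_evaluator(model)

        def fn(series, **kw):
            kw.pop("restraint_factor", None)
            return ev.batch_energy(series.ion_pos, series.aux["solvent_pos"],
                                   series.aux["solvent_dir"], **kw)
        return fn
    raise TypeError(f"unsupported model type {type(model).__name__}")


def _min_pairwise_ess(u_rows: list[np.ndarray], temperature: float) -> float:
    """Worst effective sample size of adjacent-state reweighting.

    For each adjacent pair, frames of one state are importance-weighted
    into the other; ESS = (Σw)²/Σw².  This is the overlap diagnostic —
    a state's own frames always look fine, so self-ESS is uninformative.
    """
    beta = 1.0 / (KB_LOCAL * temperature)
    worst = np.inf
    for k_ in range(len(u_rows) - 1):
        for src, dst in ((k_, k_ + 1), (k_ + 1, k_)):
            du = u_rows[src][:, dst] - u_rows[src][:, src]
            logw = -beta * (du - du.min())
            ess = np.exp(2 * logsumexp(logw) - logsumexp(2 * logw))
            worst = min(worst, float(ess))
    return worst


def _solve_with_blocks(u_rows: list[np.ndarray], temperature: float,
                       n_blocks: int, label: str) -> tuple[WHAMResult, float, float, np.ndarray]:
    """Full-data multistate WHAM + blocked re-estimates of ΔG = f_K − f_0.

    ``u_rows[k]`` is the (n_k, K) cross-energy block of frames generated
    by state k.  Blocks are contiguous, taken jointly across states.
    """
    energies = np.vstack(u_rows)
    origin = np.concatenate([np.full(len(r), k_) for k_, r in enumerate(u_rows)])
    matrix = CrossEnergyMatrix(energies=energies, origin=origin)
    full = wham_multistate(matrix, temperature)
    min_ess = _min_pairwise_ess(u_rows, temperature)
    if min_ess < ESS_WARN_THRESHOLD:
        warnings.warn(
            f"{label}: low cross-state overlap (min cross-weight ESS "
            f"{min_ess:.1f} < {ESS_WARN_THRESHOLD:g} frames)",
            RuntimeWarning, stacklevel=3)
    dg = float(full.f[-1] - full.f[0])

    estimates = []
    for b in range(n_blocks):
        rows = []
        ok = True
        for r in u_rows:
            bounds = np.linspace(0, len(r), n_blocks + 1).astype(int)
            seg = r[bounds[b]:bounds[b + 1]]
            if len(seg) == 0:
                ok = False
                break
            rows.append(seg)
        if not ok:
            continue
        sub = CrossEnergyMatrix(
            energies=np.vstack(rows),
            origin=np.concatenate([np.full(len(r), k_) for k_, r in enumerate(rows)]))
        fb = wham_multistate(sub, temperature).f
        estimates.append(float(fb[-1] - fb[0]))
    estimates = np.asarray(estimates)
    err = float(np.std(estimates, ddof=1)) if len(estimates) > 1 else 0.0
    return full, dg, err, estimates


# ---------------------------------------------------------------------------
# Legs


def three_point_alchemy(model, seed: int, *, na: IonParameters | None = None,
                        k: IonParameters | None = None, n_steps: int = 6000,
                        thin: int = 5, n_blocks: int = 10,
                        reverse: bool = False, **mc_kwargs) -> AlchemyResult:
    """ΔG of alchemically swapping the mobile ion (default Na⁺ → K⁺).

    Three samplings are run — the starting ion, the parameter-midpoint
    hybrid, and the target ion — every frame is cross-evaluated under
    all three parameter sets, and the two adjacent free-energy
    differences are solved self-consistently; their sum is returned.
    Works for both the binding-site model and the bulk droplet.
    """
    na = na if na is not None else default_ion_parameters("Na")
    k = k if k is not None else default_ion_parameters("K")
    if reverse:
        na, k = k, na
    ions = [na, interpolate_ion_params(na, k, 0.5), k]
    seeds = _spawned_seeds(seed, len(ions))
    batch = _batch_fn(model)
    u_rows = []
    for ion, s in zip(ions, seeds):
        series = run_mc(model.with_ion(ion), n_steps, s, thin=thin, **mc_kwargs)
        u_rows.append(np.stack([batch(series, ion=other) for other in ions],
                               axis=1))
    label = f"{na.species}->{k.species}@{model.scenario_id}"
    full, dg, err, est = _solve_with_blocks(u_rows, model.temperature,
                                            n_blocks, label)
    return AlchemyResult(label=label, dg=dg, error=err, wham=full,
                         block_estimates=est,
                         meta={"n_steps": n_steps, "thin": thin, "seed": seed})


def decouple_restraint_leg(model: BindingSiteModel, seed: int, *,
                           schedule: LambdaSchedule | None = None,
                           n_steps: int = 4000, n_blocks: int = 10,
                           exponent: float = 2.0,
                           **mc_kwargs) -> AlchemyResult:
    """ΔG of gradually switching the ion translational restraint on.

    The restraint energy is coupled as λ^exponent·u_trans (λ=0 off, λ=1
    the full restraint); the default quadratic coupling concentrates
    windows where the stiff restraint first takes hold.  The returned
    ΔG = G(restrained) − G(unrestrained) for the model's current ion
    species; release free energies are the negative.
    """
    if model.restraint is None:
        raise ValueError("model carries no translational restraint to decouple")
    if schedule is None:
        schedule = default_schedule(f"trans_decouple_{model.ion.species}"
                                    if model.ion.species in ("Na", "K")
                                    else "trans_decouple_Na")
    lambdas = np.asarray(schedule.lambdas)
    couplings = lambdas ** exponent
    seeds = _spawned_seeds(seed, len(lambdas))
    ev = site_evaluator(model)
    u_rows = []
    for g, s in zip(couplings, seeds):
        m_lam = replace(model, restraint=model.restraint.scaled(float(g)))
        series = run_mc(m_lam, n_steps, s, **mc_kwargs)
        u0 = ev.batch_energy(series.ion_pos, series.chi, restraint_factor=0.0)
        u1 = ev.batch_energy(series.ion_pos, series.chi, restraint_factor=1.0)
        u_rest = u1 - u0
        u_rows.append(u0[:, None] + couplings[None, :] * u_rest[:, None])
    label = f"trans_decouple_{model.ion.species}@{model.scenario_id}"
    full, dg, err, est = _solve_with_blocks(u_rows, model.temperature,
                                            n_blocks, label)
    return AlchemyResult(label=label, dg=dg, error=err, wham=full,
                         block_estimates=est, meta={"seed": seed})


def deprotonation_leg(model: BindingSiteModel, ligand_id: str, seed: int, *,
                      schedule: LambdaSchedule | None = None,
                      n_steps: int = 4000, n_blocks: int = 10,
                      **mc_kwargs) -> AlchemyResult:
    """ΔG of deprotonating one acidic ligand (charges grown linearly in λ).

    λ=0 is the protonated (neutral) ligand, λ=1 the fully deprotonated
    one; only Coulomb terms change, so cross-energies are exact linear
    combinations of the two endpoint evaluations.
    """
    idx = model.ligand_index(ligand_id)
    lig = model.ligands[idx]
    if lig.ionizable_q <= 0:
        raise ValueError(f"ligand {ligand_id!r} is not protonatable")
    if schedule is None:
        schedule = default_schedule("deprot_site")
    lambdas = np.asarray(schedule.lambdas)

    def model_at(lam: float) -> BindingSiteModel:
        new_lig = replace(lig, ionizable_q=float(lam) * lig.ionizable_q,
                          protonated=lam == 0.0, mutated=False)
        ligands = list(model.ligands)
        ligands[idx] = new_lig
        return replace(model, ligands=tuple(ligands))

    m0, m1 = model_at(0.0), model_at(1.0)
    ev0, ev1 = site_evaluator(m0), site_evaluator(m1)
    seeds = _spawned_seeds(seed, len(lambdas))
    u_rows = []
    for lam, s in zip(lambdas, seeds):
        series = run_mc(model_at(float(lam)), n_steps, s, **mc_kwargs)
        u0 = ev0.batch_energy(series.ion_pos, series.chi)
        v = ev1.batch_energy(series.ion_pos, series.chi) - u0
        u_rows.append(u0[:, None] + lambdas[None, :] * v[:, None])
    label = f"deprot_{ligand_id}@{model.scenario_id}"
    full, dg, err, est = _solve_with_blocks(u_rows, model.temperature,
                                            n_blocks, label)
    return AlchemyResult(label=label, dg=dg, error=err, wham=full,
                         block_estimates=est, meta={"seed": seed})
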