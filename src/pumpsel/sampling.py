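"""Metropolis Monte Carlo sampling of the toy models.

Only equilibrium averages feed the downstream free-energy estimators, so
a Metropolis sampler replaces dynamics entirely.  The move set pairs a
Gaussian ion displacement with single-torsion rotations (uniform within
±Δ); move sizes are tuned toward 30–50 % acceptance in a pre-run phase
and then frozen for production, so identical inputs give bit-identical
output series.

Umbrella sampling along one torsion follows the 72-window, 5°-spacing,
100 kcal/mol/rad² protocol by default; window bias differences are
wrapped to (−180°, 180°] before squaring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import KB
from .toy_system import (
    BindingSiteModel,
    BulkDropletModel,
    CosineTerm,
    SiteState,
    TorsionBoost,
    initial_droplet_state,
    initial_site_state,
    wrap_degrees,
)
from ._energy import droplet_evaluator, site_evaluator

__all__ = [
    "SampleSeries",
    "UmbrellaWindowSpec",
    "TorsionProfileModel",
    "Scalar1DModel",
    "run_mc",
    "umbrella_scan",
    "default_umbrella_windows",
    "umbrella_bias_energy",
]


@dataclass
class SampleSeries:
    """Tagged coordinate/energy time-series from one sampling run.

    ``energy`` holds the *unbiased* model energy per frame; any umbrella
    bias is recorded in ``meta['window']`` and re-applied by the
    estimators.  ``chi`` is (n_frames, n_torsions) in degrees (or
    (n_frames,) for single-coordinate models); ``ion_pos`` may be None
    for models without an ion.
    """

    scenario_id: str
    temperature: float
    seed: int
    thin: int
    energy: np.ndarray
    chi: np.ndarray | None = None
    ion_pos: np.ndarray | None = None
    acceptance: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.size == 0:
            raise ValueError("a sample series needs at least one frame")
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("non-finite energies in sample series")

    @property
    def n_frames(self) -> int:
        return len(self.energy)


@dataclass(frozen=True)
class UmbrellaWindowSpec:
    """One harmonic umbrella window on a periodic torsion."""

    center: float            # degrees
    k_bias: float = 100.0    # kcal/mol/rad²
    index: int = 0

    def __post_init__(self):
        if self.k_bias <= 0:
            raise ValueError("umbrella force constant must be positive")


def umbrella_bias_energy(spec: UmbrellaWindowSpec, chi_deg) -> np.ndarray:
    """½·k·Δχ² with Δχ wrapped to (−180°, 180°] and squared in radians."""
    d = np.radians(wrap_degrees(np.asarray(chi_deg, dtype=float) - spec.center))
    return 0.5 * spec.k_bias * d * d


def default_umbrella_windows(spacing: float = 5.0,
                             k_bias: float = 100.0) -> list[UmbrellaWindowSpec]:
    """Windows tiling the full period (default: 72 windows at 5°)."""
    n = 360.0 / spacing
    if abs(n - round(n)) > 1e-9:
        raise ValueError("window spacing must divide 360 degrees")
    n = int(round(n))
    return [UmbrellaWindowSpec(center=-180.0 + i * spacing, k_bias=k_bias, index=i)
            for i in range(n)]


# ---------------------------------------------------------------------------
# Single-coordinate models (the isolated-residue torsion scan analog, plus
# a plain 1-D test model for closed-form checks)


@dataclass(frozen=True)
class TorsionProfileModel:
    """One side-chain-like torsion on a stripped scaffold.

    This mirrors the protocol of scanning a residue's torsional free
    energy in isolation (helix stripped of other side chains) before
    fitting the boosting potential: the sampled coordinate is a single
    periodic χ with an intrinsic multi-well cosine potential.
    """

    torsion: tuple[CosineTerm, ...]
    temperature: float = 303.15
    scenario_id: str = "torsion_scan"
    boosts: tuple[TorsionBoost, ...] = ()

    def potential(self, chi_deg):
        chi = np.asarray(chi_deg, dtype=float)
        u = sum(t.energy(chi) for t in self.torsion)
        for b in self.boosts:
            u = u + b.energy(chi)
        return u


@dataclass(frozen=True)
class Scalar1DModel:
    """A non-periodic scalar coordinate under an arbitrary potential."""

    potential: Callable[[float], float]
    temperature: float = 303.15
    scenario_id: str = "scalar"
    move_scale: float = 0.5


# ---------------------------------------------------------------------------
# Metropolis driver


def _tune(scale: float, acc: float, lo: float = 0.30, hi: float = 0.50,
          factor: float = 1.35, bounds: tuple[float, float] = (1e-3, 90.0)) -> float:
    if acc > hi:
        scale *= factor
    elif acc < lo:
        scale /= factor
    return float(min(max(scale, bounds[0]), bounds[1]))


def run_mc(model, n_steps: int, seed: int, *, temperature: float | None = None,
           bias: Callable | None = None, thin: int = 10, n_equil: int | None = None,
           tune: bool = True, initial_state=None, sigma_ion: float = 0.25,
           delta_chi: float = 30.0) -> SampleSeries:
    """Sample a toy model with Metropolis Monte Carlo.

    ``bias`` is an optional extra potential-energy modifier evaluated on
    the sampled torsion coordinate(s) — for binding-site models it
    receives the full χ vector (degrees), for single-coordinate models
    the scalar coordinate.  Recorded energies exclude the bias.

    Identical (model, seed, settings) inputs give bit-identical series.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if thin <= 0 or thin > n_steps:
        raise ValueError("thin must lie in [1, n_steps]")
    rng = np.random.default_rng(seed)
    if n_equil is None:
        n_equil = max(200, n_steps // 5)

    if isinstance(model, BindingSiteModel):
        return _run_site(model, n_steps, n_equil, rng, seed, temperature, bias,
                         thin, tune, sigma_ion, delta_chi, initial_state)
    if isinstance(model, BulkDropletModel):
        return _run_droplet(model, n_steps, n_equil, rng, seed, temperature,
                            thin, tune, sigma_ion, initial_state)
    if isinstance(model, TorsionProfileModel):
        return _run_torsion(model, n_steps, n_equil, rng, seed, temperature,
                            bias, thin, tune, delta_chi, initial_state)
    if isinstance(model, Scalar1DModel):
        return _run_scalar(model, n_steps, n_equil, rng, seed, temperature,
                           bias, thin, tune, initial_state)
    raise TypeError(f"don't know how to sample {type(model).__name__}")


def _metropolis(rng, beta, d_e) -> bool:
    if not math.isfinite(d_e):
        if d_e > 0:
            return False
        raise ValueError("non-finite energy encountered during sampling")
    return d_e <= 0.0 or rng.random() < math.exp(-beta * d_e)


def _run_torsion(model, n_steps, n_equil, rng, seed, temperature, bias, thin,
                 tune, delta_chi, initial_state):
    T = temperature if temperature is not None else model.temperature
    beta = 1.0 / (KB * T)

    def u(chi):
        e = float(model.potential(chi))
        if bias is not None:
            e += float(bias(chi))
        return e

    chi = float(initial_state) if initial_state is not None else 0.0
    e_cur = u(chi)
    delta = delta_chi

    if tune:
        for _ in range(8):
            acc = 0
            for _ in range(100):
                prop = float(wrap_degrees(chi + rng.uniform(-delta, delta)))
                e_new = u(prop)
                if _metropolis(rng, beta, e_new - e_cur):
                    chi, e_cur = prop, e_new
                    acc += 1
            delta = _tune(delta, acc / 100.0, bounds=(0.5, 120.0))

    n_acc = 0
    for _ in range(n_equil):
        prop = float(wrap_degrees(chi + rng.uniform(-delta, delta)))
        e_new = u(prop)
        if _metropolis(rng, beta, e_new - e_cur):
            chi, e_cur = prop, e_new

    n_frames = n_steps // thin
    chis = np.empty(n_frames)
    energies = np.empty(n_frames)
    k = 0
    for step in range(n_frames * thin):
        prop = float(wrap_degrees(chi + rng.uniform(-delta, delta)))
        e_new = u(prop)
        if _metropolis(rng, beta, e_new - e_cur):
            chi, e_cur = prop, e_new
            n_acc += 1
        if (step + 1) % thin == 0:
            chis[k] = chi
            energies[k] = float(model.potential(chi))  # unbiased
            k += 1
    return SampleSeries(scenario_id=model.scenario_id, temperature=T, seed=seed,
                        thin=thin, energy=energies, chi=chis,
                        acceptance={"torsion": n_acc / (n_frames * thin)},
                        meta={"move_scale": delta})


def _run_scalar(model, n_steps, n_equil, rng, seed, temperature, bias, thin,
                tune, initial_state):
    T = temperature if temperature is not None else model.temperature
    beta = 1.0 / (KB * T)

    def u(x):
        e = float(model.potential(x))
        if bias is not None:
            e += float(bias(x))
        return e

    x = float(initial_state) if initial_state is not None else 0.0
    e_cur = u(x)
    delta = model.move_scale
    if tune:
        for _ in range(8):
            acc = 0
            for _ in range(100):
                prop = x + rng.uniform(-delta, delta)
                e_new = u(prop)
                if _metropolis(rng, beta, e_new - e_cur):
                    x, e_cur = prop, e_new
                    acc += 1
            delta = _tune(delta, acc / 100.0, bounds=(1e-4, 1e3))
    for _ in range(n_equil):
        prop = x + rng.uniform(-delta, delta)
        e_new = u(prop)
        if _metropolis(rng, beta, e_new - e_cur):
            x, e_cur = prop, e_new
    n_frames = n_steps // thin
    xs = np.empty(n_frames)
    energies = np.empty(n_frames)
    n_acc = 0
    k = 0
    for step in range(n_frames * thin):
        prop = x + rng.uniform(-delta, delta)
        e_new = u(prop)
        if _metropolis(rng, beta, e_new - e_cur):
            x, e_cur = prop, e_new
            n_acc += 1
        if (step + 1) % thin == 0:
            xs[k] = x
            energies[k] = float(model.potential(x))
            k += 1
    return SampleSeries(scenario_id=model.scenario_id, temperature=T, seed=seed,
                        thin=thin, energy=energies, chi=xs,
                        acceptance={"scalar": n_acc / (n_frames * thin)},
                        meta={"move_scale": delta})


def _run_site(model, n_steps, n_equil, rng, seed, temperature, bias, thin,
              tune, sigma_ion, delta_chi, initial_state):
    T = temperature if temperature is not None else model.temperature
    beta = 1.0 / (KB * T)
    ev = site_evaluator(model)
    nl = model.n_torsions

    state = (initial_state.copy() if initial_state is not None
             else initial_site_state(model))

    def u(s: SiteState):
        e = ev.energy(s.ion_pos, s.chi)
        if bias is not None:
            e += float(bias(s.chi))
        return e

    e_cur = u(state)
    sigma, delta = sigma_ion, delta_chi

    def sweep(n, record=False, frames=None):
        nonlocal state, e_cur
        acc = {"ion": 0, "torsion": 0}
        tries = {"ion": 0, "torsion": 0}
        k = 0
        for step in range(n):
            pick = rng.integers(0, nl + 1)
            if pick == 0:
                prop = state.copy()
                prop.ion_pos = prop.ion_pos + rng.normal(scale=sigma, size=3)
                kind = "ion"
            else:
                prop = state.copy()
                j = int(pick - 1)
                prop.chi[j] = wrap_degrees(prop.chi[j] + rng.uniform(-delta, delta))
                kind = "torsion"
            tries[kind] += 1
            e_new = u(prop)
            if _metropolis(rng, beta, e_new - e_cur):
                state, e_cur = prop, e_new
                acc[kind] += 1
            if record and (step + 1) % thin == 0:
                frames["ion"][k] = state.ion_pos
                frames["chi"][k] = state.chi
                frames["e"][k] = ev.energy(state.ion_pos, state.chi)
                k += 1
        return acc, tries

    if tune:
        for _ in range(8):
            acc, tries = sweep(150)
            if tries["ion"]:
                sigma = _tune(sigma, acc["ion"] / tries["ion"], bounds=(1e-3, 3.0))
            if tries["torsion"]:
                delta = _tune(delta, acc["torsion"] / tries["torsion"],
                              bounds=(0.5, 120.0))
    sweep(n_equil)
    n_frames = n_steps // thin
    frames = {"ion": np.empty((n_frames, 3)), "chi": np.empty((n_frames, nl)),
              "e": np.empty(n_frames)}
    acc, tries = sweep(n_frames * thin, record=True, frames=frames)
    acceptance = {k: acc[k] / tries[k] if tries[k] else 0.0 for k in acc}
    return SampleSeries(scenario_id=model.scenario_id, temperature=T, seed=seed,
                        thin=thin, energy=frames["e"], chi=frames["chi"],
                        ion_pos=frames["ion"], acceptance=acceptance,
                        meta={"sigma_ion": sigma, "delta_chi": delta})


def _run_droplet(model, n_steps, n_equil, rng, seed, temperature, thin, tune,
                 sigma_ion, initial_state):
    T = temperature if temperature is not None else model.temperature
    beta = 1.0 / (KB * T)
    ev = droplet_evaluator(model)
    m = model.n_solvent

    state = (initial_state.copy() if initial_state is not None
             else initial_droplet_state(model, rng))
    e_cur = ev.energy(state.ion_pos, state.solvent_pos, state.solvent_dir)
    sigma, sig_rot = sigma_ion, 0.35

    def propose():
        pick = rng.integers(0, 2 * m + 1)
        prop = state.copy()
        if pick == 0:
            prop.ion_pos = prop.ion_pos + rng.normal(scale=sigma, size=3)
            return prop, "ion"
        j = int((pick - 1) % m)
        if pick <= m:
            prop.solvent_pos[j] += rng.normal(scale=sigma, size=3)
            return prop, "trans"
        d = prop.solvent_dir[j] + rng.normal(scale=sig_rot, size=3)
        prop.solvent_dir[j] = d / np.linalg.norm(d)
        return prop, "rot"

    def sweep(n, record=False, frames=None):
        nonlocal state, e_cur
        acc = {"ion": 0, "trans": 0, "rot": 0}
        tries = {"ion": 0, "trans": 0, "rot": 0}
        k = 0
        for step in range(n):
            prop, kind = propose()
            tries[kind] += 1
            e_new = ev.energy(prop.ion_pos, prop.solvent_pos, prop.solvent_dir)
            if _metropolis(rng, beta, e_new - e_cur):
                state, e_cur = prop, e_new
                acc[kind] += 1
            if record and (step + 1) % thin == 0:
                frames["ion"][k] = state.ion_pos
                frames["spos"][k] = state.solvent_pos
                frames["sdir"][k] = state.solvent_dir
                frames["e"][k] = e_cur
                k += 1
        return acc, tries

    if tune:
        for _ in range(8):
            acc, tries = sweep(150)
            if tries["ion"] + tries["trans"]:
                a = (acc["ion"] + acc["trans"]) / (tries["ion"] + tries["trans"])
                sigma = _tune(sigma, a, bounds=(1e-3, 2.0))
            if tries["rot"]:
                sig_rot = _tune(sig_rot, acc["rot"] / tries["rot"], bounds=(0.02, 1.5))
    sweep(n_equil)
    n_frames = n_steps // thin
    frames = {"ion": np.empty((n_frames, 3)), "spos": np.empty((n_frames, m, 3)),
              "sdir": np.empty((n_frames, m, 3)), "e": np.empty(n_frames)}
    acc, tries = sweep(n_frames * thin, record=True, frames=frames)
    acceptance = {k: acc[k] / tries[k] if tries[k] else 0.0 for k in acc}
    return SampleSeries(scenario_id=model.scenario_id, temperature=T, seed=seed,
                        thin=thin, energy=frames["e"], ion_pos=frames["ion"],
                        acceptance=acceptance,
                        aux={"solvent_pos": frames["spos"],
                             "solvent_dir": frames["sdir"]},
                        meta={"sigma": sigma, "sigma_rot": sig_rot})


# ---------------------------------------------------------------------------
# Umbrella sampling driver


def umbrella_scan(model, windows: Sequence[UmbrellaWindowSpec] | None = None,
                  n_steps: int = 3000, seed: int = 0, torsion_id: str | None = None,
                  **mc_kwargs) -> list[SampleSeries]:
    """Biased scans along one torsion, one series per umbrella window.

    Each window's chain starts at the window centre and runs under the
    harmonic bias ½k(Δχ)²; the returned series carry their window spec
    in ``meta['window']`` so the umbrella WHAM can re-apply the bias.
    """
    if windows is None:
        windows = default_umbrella_windows()
    if len(windows) == 0:
        raise ValueError("empty umbrella window list")
    centers = [w.center for w in windows]
    if len(set(np.round(centers, 9))) != len(centers):
        raise ValueError("duplicate umbrella window centres")

    if isinstance(model, TorsionProfileModel):
        torsion_index = None
    elif isinstance(model, BindingSiteModel):
        if torsion_id is None:
            raise ValueError("torsion_id required for binding-site models")
        torsion_index = model.ligand_index(torsion_id)
    else:
        raise TypeError("umbrella_scan supports torsion-profile and site models")

    children = np.random.SeedSequence(seed).spawn(len(windows))
    out = []
    for w, child in zip(windows, children):
        wseed = int(child.generate_state(1)[0] % (2 ** 31))
        if torsion_index is None:
            bias = lambda chi, w=w: float(umbrella_bias_energy(w, chi))
            init = w.center
        else:
            bias = lambda chi, w=w: float(umbrella_bias_energy(w, chi[torsion_index]))
            init = initial_site_state(model)
            init.chi[torsion_index] = w.center
        series = run_mc(model, n_steps, wseed, bias=bias, initial_state=init,
                        **mc_kwargs)
        series.meta["window"] = w
        series.meta["torsion_id"] = torsion_id
        out.append(series)
    return out


def window_coordinate(series: SampleSeries, model=None) -> np.ndarray:
    """The biased torsion coordinate of an umbrella series (degrees)."""
    chi = np.asarray(series.chi)
    if chi.ndim == 1:
        return chi
    tid = series.meta.get("torsion_id")
    if model is None or tid is None:
        raise ValueError("need the model to locate the biased torsion")
    return chi[:, model.ligand_index(tid)]
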