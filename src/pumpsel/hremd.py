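"""Two-dimensional Hamiltonian replica exchange: λ windows × boost levels.

The replica topology couples each λ window to a ladder of replicas whose
boosting potential is scaled from 0 to 1.  Exchanges are attempted only
(a) between adjacent boost levels within the same λ window and (b)
between adjacent λ windows at zero boost, so for n_λ windows of n_b
replicas there are n_λ·(n_b−1) + (n_λ−1) allowed edges.  Only the
zero-boost replicas contribute frames to downstream estimation; the
boosted rows exist purely to shuttle well-relaxed side-chain rotamers
down the ladder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB
from ._energy import site_evaluator
from .alchemy import interpolate_ion_params
from .sampling import SampleSeries, run_mc
from .toy_system import (
    BindingSiteModel,
    IonParameters,
    TorsionBoost,
    default_ion_parameters,
    initial_site_state,
)

__all__ = [
    "ReplicaTopology",
    "ReplicaState",
    "HremdResult",
    "build_topology",
    "attempt_exchange",
    "run_hremd",
    "fep_from_hremd",
]


@dataclass(frozen=True)
class ReplicaTopology:
    """Replica grid over (λ, boost strength) with its allowed exchange edges.

    Replica index = i_λ · n_boost + i_boost.
    """

    n_lambda: int
    n_boost: int
    lambdas: tuple[float, ...]
    boost_strengths: tuple[float, ...]
    edges: tuple[tuple[int, int], ...]

    @property
    def n_replicas(self) -> int:
        return self.n_lambda * self.n_boost

    def replica_index(self, i_lambda: int, i_boost: int) -> int:
        return i_lambda * self.n_boost + i_boost

    def grid_position(self, index: int) -> tuple[int, int]:
        return divmod(index, self.n_boost)

    def zero_boost_replicas(self) -> list[int]:
        return [self.replica_index(i, 0) for i in range(self.n_lambda)]


@dataclass
class ReplicaState:
    """One replica: its fixed potential slot and the walking configuration."""

    index: int
    configuration: object
    lam: float
    boost_strength: float
    walker: int = -1
    exchange_attempts: dict[tuple[int, int], int] = field(default_factory=dict)
    exchange_accepts: dict[tuple[int, int], int] = field(default_factory=dict)


def build_topology(n_lambda: int, n_boost: int) -> ReplicaTopology:
    """Evenly spaced λ and boost ladders with the standard edge rule.

    The production-scale setup of 16 λ windows × 8 boost levels yields
    128 replicas and 127 exchange edges.
    """
    if n_lambda < 1 or n_boost < 1:
        raise ValueError("need at least one λ window and one boost level")
    lambdas = tuple(np.linspace(0.0, 1.0, n_lambda)) if n_lambda > 1 else (0.0,)
    boosts = tuple(np.linspace(0.0, 1.0, n_boost)) if n_boost > 1 else (0.0,)
    edges = []
    for i in range(n_lambda):
        for b in range(n_boost - 1):
            edges.append((i * n_boost + b, i * n_boost + b + 1))
    for i in range(n_lambda - 1):
        edges.append((i * n_boost, (i + 1) * n_boost))
    return ReplicaTopology(n_lambda=n_lambda, n_boost=n_boost, lambdas=lambdas,
                           boost_strengths=boosts, edges=tuple(edges))


def attempt_exchange(state_a: ReplicaState, state_b: ReplicaState,
                     potentials, temperature: float,
                     rng: np.random.Generator,
                     topology: ReplicaTopology | None = None) -> bool:
    """Metropolis swap attempt between two replicas.

    ``potentials`` maps replica index → energy callable U(configuration).
    Accepted with probability min(1, exp(−βΔ)),
    Δ = [U_a(x_b) + U_b(x_a)] − [U_a(x_a) + U_b(x_b)]; on acceptance the
    configurations (and walker labels) swap while the potentials stay put.
    """
    edge = (min(state_a.index, state_b.index), max(state_a.index, state_b.index))
    if topology is not None and edge not in topology.edges:
        raise ValueError(f"exchange attempted along disallowed edge {edge}")
    u_a = potentials[state_a.index]
    u_b = potentials[state_b.index]
    delta = ((u_a(state_b.configuration) + u_b(state_a.configuration))
             - (u_a(state_a.configuration) + u_b(state_b.configuration)))
    state_a.exchange_attempts[edge] = state_a.exchange_attempts.get(edge, 0) + 1
    if math.isnan(delta):
        raise ValueError("non-finite energy in exchange attempt")
    beta = 1.0 / (KB * temperature)
    accept = delta <= 0.0 or (math.isfinite(delta)
                              and rng.random() < math.exp(-beta * delta))
    if accept:
        state_a.configuration, state_b.configuration = (
            state_b.configuration, state_a.configuration)
        state_a.walker, state_b.walker = state_b.walker, state_a.walker
        state_a.exchange_accepts[edge] = state_a.exchange_accepts.get(edge, 0) + 1
    return accept


@dataclass
class HremdResult:
    """Zero-boost series per λ window plus exchange statistics."""

    topology: ReplicaTopology
    series_by_lambda: list[SampleSeries]
    ions: list[IonParameters]
    exchange_attempts: dict[tuple[int, int], int]
    exchange_accepts: dict[tuple[int, int], int]
    walker_boost_levels: list[set[int]]

    def acceptance_rate(self, edge: tuple[int, int]) -> float:
        a = self.exchange_attempts.get(edge, 0)
        return self.exchange_accepts.get(edge, 0) / a if a else 0.0


def run_hremd(topology: ReplicaTopology, model: BindingSiteModel, seed: int, *,
              boosts: tuple[TorsionBoost, ...] = (),
              na: IonParameters | None = None, k: IonParameters | None = None,
              n_sweeps: int = 100, steps_per_sweep: int = 40,
              exchange: bool = True, **mc_kwargs) -> HremdResult:
    """Run the coupled FEP/H-REMD walk on a binding-site model.

    Replica (i_λ, i_b) samples the model with ion parameters
    interpolated at λ_i and all ``boosts`` scaled to strength s_b.  One
    sweep = a short Metropolis segment per replica followed by exchange
    attempts over alternating halves of the allowed edges.  Frames are
    collected from the zero-boost row only, one per sweep per λ window.
    """
    na = na if na is not None else default_ion_parameters("Na")
    k = k if k is not None else default_ion_parameters("K")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    ions = [interpolate_ion_params(na, k, lam) for lam in topology.lambdas]
    models = {}
    for r in range(topology.n_replicas):
        il, ib = topology.grid_position(r)
        scaled = tuple(replace(b, strength=topology.boost_strengths[ib])
                       for b in boosts)
        models[r] = model.with_ion(ions[il]).with_boosts(scaled)
    evaluators = {r: site_evaluator(models[r]) for r in models}
    potentials = {r: (lambda cfg, ev=evaluators[r]: ev.energy(cfg.ion_pos, cfg.chi))
                  for r in models}

    states = [ReplicaState(index=r, configuration=initial_site_state(model),
                           lam=topology.lambdas[topology.grid_position(r)[0]],
                           boost_strength=topology.boost_strengths[
                               topology.grid_position(r)[1]],
                           walker=r)
              for r in range(topology.n_replicas)]
    walker_levels: list[set[int]] = [set() for _ in range(topology.n_replicas)]

    zero_row = topology.zero_boost_replicas()
    nl = model.n_torsions
    frames = {r: {"ion": np.empty((n_sweeps, 3)), "chi": np.empty((n_sweeps, nl)),
                  "e": np.empty(n_sweeps)} for r in zero_row}

    seg_seeds = ss.spawn(n_sweeps)
    for sweep in range(n_sweeps):
        sweep_children = seg_seeds[sweep].spawn(topology.n_replicas)
        for st in states:
            sseed = int(sweep_children[st.index].generate_state(1)[0] % (2 ** 31))
            series = run_mc(models[st.index], steps_per_sweep, sseed,
                            initial_state=st.configuration, tune=False,
                            n_equil=0, thin=steps_per_sweep, **mc_kwargs)
            cfg = st.configuration.copy()
            cfg.ion_pos = series.ion_pos[-1].copy()
            cfg.chi = series.chi[-1].copy()
            st.configuration = cfg
            ib = topology.grid_position(st.index)[1]
            walker_levels[st.walker].add(ib)
        if exchange:
            half = sweep % 2
            for e_idx, (a, b) in enumerate(topology.edges):
                if e_idx % 2 != half:
                    continue
                attempt_exchange(states[a], states[b], potentials,
                                 model.temperature, rng, topology)
        for r in zero_row:
            cfg = states[r].configuration
            frames[r]["ion"][sweep] = cfg.ion_pos
            frames[r]["chi"][sweep] = cfg.chi
            frames[r]["e"][sweep] = potentials[r](cfg)

    series_by_lambda = []
    for i, r in enumerate(zero_row):
        series_by_lambda.append(SampleSeries(
            scenario_id=f"{model.scenario_id}:lambda={topology.lambdas[i]:.3f}",
            temperature=model.temperature, seed=seed, thin=steps_per_sweep,
            energy=frames[r]["e"], chi=frames[r]["chi"], ion_pos=frames[r]["ion"],
            meta={"lambda": topology.lambdas[i], "replica": r}))

    attempts: dict[tuple[int, int], int] = {}
    accepts: dict[tuple[int, int], int] = {}
    for st in states:
        for e, n in st.exchange_attempts.items():
            attempts[e] = attempts.get(e, 0) + n
        for e, n in st.exchange_accepts.items():
            accepts[e] = accepts.get(e, 0) + n
    return HremdResult(topology=topology, series_by_lambda=series_by_lambda,
                       ions=ions, exchange_attempts=attempts,
                       exchange_accepts=accepts, walker_boost_levels=walker_levels)


def fep_from_hremd(result: HremdResult, model: BindingSiteModel,
                   n_blocks: int = 10):
    """ΔG(λ=0 → λ=1) from the zero-boost H-REMD frames via multistate WHAM."""
    from .alchemy import AlchemyResult, _solve_with_blocks
    ev = site_evaluator(model)
    u_rows = []
    for series in result.series_by_lambda:
        u_rows.append(np.stack(
            [ev.batch_energy(series.ion_pos, series.chi, ion=ion)
             for ion in result.ions], axis=1))
    full, dg, err, est = _solve_with_blocks(
        u_rows, model.temperature, n_blocks, f"hremd@{model.scenario_id}")
    return AlchemyResult(label=f"hremd@{model.scenario_id}", dg=dg, error=err,
                         wham=full, block_estimates=est)
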