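"""Boosting potentials: cosine-series fits to torsional PMFs.

A boosting potential U_BP(χ) = Σ_n k_n{1 + cos[n(χ − χ0_n)]} is fitted
to a torsion's potential of mean force 𝒲(χ) and then applied with its
sign reversed and scaled by a strength s ∈ [0, 1], cancelling the
rotamer barriers of that torsion so that replica exchange can shuttle
well-equilibrated rotamers into the unbiased replicas.

Fitting uses the linear expansion k_n cos(n(χ−χ0_n)) =
a_n cos(nχ) + b_n sin(nχ): the least-squares problem in (a_n, b_n) plus
a free additive constant is convex and deterministic, and converts back
via k_n = √(a_n²+b_n²), χ0_n = atan2(b_n, a_n)/n, which makes every
fitted k_n ≥ 0.  The number of terms N is chosen in 3…6 by lowest RMS
residual on the PMF grid (ties favour the smaller N).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .estimators import TorsionPMF
from .sampling import TorsionProfileModel
from .toy_system import BindingSiteModel, TorsionBoost

__all__ = [
    "BoostingPotential",
    "evaluate_boost",
    "fit_boosting_potential",
    "apply_boost",
]


@dataclass(frozen=True)
class BoostingPotential:
    """Cosine-series boosting potential for one side-chain-like torsion.

    Term n (multiplicity n, 1-based) contributes k_n{1 + cos[n(χ−χ0_n)]}.
    Fitted instances carry 3–6 non-negative coefficients; tabulated
    reference rows may carry either sign and are evaluated literally.
    """

    k: tuple[float, ...]          # kcal/mol
    chi0: tuple[float, ...]       # degrees
    residue: str = ""
    fit_residual: float = float("nan")   # kcal/mol RMS on the source grid

    def __post_init__(self):
        if len(self.k) != len(self.chi0):
            raise ValueError("k and chi0 must have equal length")
        if len(self.k) == 0:
            raise ValueError("boosting potential needs at least one term")

    @property
    def n_terms(self) -> int:
        return len(self.k)

    def __call__(self, chi_deg):
        return evaluate_boost(self, chi_deg)


def evaluate_boost(bp: BoostingPotential, chi_deg) -> np.ndarray | float:
    """U_BP(χ) = Σ_n k_n{1 + cos[n(χ − χ0_n)]}, χ in degrees."""
    chi = np.asarray(chi_deg, dtype=float)
    u = np.zeros_like(chi)
    for n, (kn, c0) in enumerate(zip(bp.k, bp.chi0), start=1):
        u = u + kn * (1.0 + np.cos(np.radians(n * (chi - c0))))
    return float(u) if np.isscalar(chi_deg) else u


def fit_boosting_potential(pmf: TorsionPMF,
                           n_range: Iterable[int] = range(3, 7),
                           residue: str = "") -> BoostingPotential:
    """Least-squares cosine-series fit of a periodic PMF.

    An additive constant is free during the fit (it absorbs both the PMF
    anchor and the "+1" inside each series term) and discarded, so the
    returned potential evaluates the literal series form.
    """
    if pmf.counts is not None and np.any(np.asarray(pmf.counts) == 0):
        raise ValueError("PMF has empty bins; cannot fit across gaps")
    chi = np.radians(np.asarray(pmf.grid, dtype=float))
    y = np.asarray(pmf.values, dtype=float)
    if chi.size < 2 * max(n_range) + 1:
        raise ValueError("PMF grid too coarse for the requested term counts")

    best: tuple[float, int, np.ndarray] | None = None
    for n_terms in sorted(set(int(n) for n in n_range)):
        cols = [np.ones_like(chi)]
        for n in range(1, n_terms + 1):
            cols.append(np.cos(n * chi))
            cols.append(np.sin(n * chi))
        design = np.stack(cols, axis=1)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = float(np.sqrt(np.mean((design @ coef - y) ** 2)))
        if best is None or resid < best[0] - 1e-12:
            best = (resid, n_terms, coef)
    resid, n_terms, coef = best
    k = []
    chi0 = []
    for n in range(1, n_terms + 1):
        a, b = coef[2 * n - 1], coef[2 * n]
        k.append(float(np.hypot(a, b)))
        chi0.append(float(np.degrees(np.arctan2(b, a)) / n))
    return BoostingPotential(k=tuple(k), chi0=tuple(chi0), residue=residue,
                             fit_residual=resid)


def apply_boost(model, bp: BoostingPotential, strength: float,
                ligand_id: str | None = None):
    """Attach −strength·U_BP(χ) to one torsion of a model.

    Returns a new model whose named torsion feels the intrinsic
    potential minus the scaled boost; strength 0 returns the model
    unchanged.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("boost strength must lie in [0, 1]")
    if strength == 0.0:
        return model
    if isinstance(model, TorsionProfileModel):
        boost = TorsionBoost(ligand_id="", k=bp.k, chi0=bp.chi0,
                             strength=strength)
        return replace(model, boosts=model.boosts + (boost,))
    if isinstance(model, BindingSiteModel):
        if ligand_id is None:
            raise ValueError("ligand_id required for binding-site models")
        model.ligand_index(ligand_id)   # raises KeyError if absent
        boost = TorsionBoost(ligand_id=ligand_id, k=bp.k, chi0=bp.chi0,
                             strength=strength)
        return model.with_boosts(model.boosts + (boost,))
    raise TypeError(f"cannot boost {type(model).__name__}")
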