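"""Standard-state corrections and headline thermodynamic conversions.

This is where simulated free-energy legs turn into the quantities one
actually reports: absolute binding free energies with the analytic
rigid-rotor translational factor F_t and the 1 M standard state,
selectivity differences ΔΔG_i→j with their dissociation-constant ratios
ΔΔG = RT ln(K_D,j/K_D,i), and pKa shifts from the site/bulk
deprotonation cycle ΔpKa = (ΔG_site − ΔG_bulk)/2.303 k_BT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import C_STANDARD, KB, LN10, T_DEFAULT
from .toy_system import RestraintSpec

__all__ = [
    "StandardStateSpec",
    "PkaResult",
    "SelectivityRecord",
    "restraint_free_factor",
    "binding_free_energy",
    "assemble_binding_dg",
    "kd_ratio",
    "ddg_from_kd_ratio",
    "pka_from_legs",
]


@dataclass(frozen=True)
class StandardStateSpec:
    """Standard concentration C° (default 1 M = 1 molecule / 1661 Å³)."""

    c_standard: float = C_STANDARD    # molecules / Å³
    temperature: float = T_DEFAULT

    def __post_init__(self):
        if self.c_standard <= 0:
            raise ValueError("standard concentration must be positive")


@dataclass(frozen=True)
class PkaResult:
    """Outcome of the deprotonation thermodynamic cycle."""

    dg_site: float          # kcal/mol
    dg_bulk: float          # kcal/mol
    delta_pka: float
    reference_pka: float
    pka: float              # reference + shift
    temperature: float


@dataclass
class SelectivityRecord:
    """ΔΔG_Na→K for one site with its K_D-ratio rendering.

    Positive ΔΔG means the site prefers Na⁺ (K⁺ binds worse); negative
    means K⁺-selective.  ln(K_D,K/K_D,Na) = ΔΔG/RT holds by
    construction.
    """

    scenario_id: str
    site: str
    ddg: float              # kcal/mol, Na→K
    error: float = 0.0
    temperature: float = T_DEFAULT
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("error must be non-negative")

    @property
    def ln_kd_ratio(self) -> float:
        return self.ddg / (KB * self.temperature)

    @property
    def kd_ratio(self) -> float:
        return math.exp(self.ln_kd_ratio)

    @property
    def selective_for(self) -> str:
        return "K" if self.ddg < 0 else "Na"


# ---------------------------------------------------------------------------
# Rigid-rotor translational factor


def restraint_free_factor(spec: RestraintSpec, temperature: float = T_DEFAULT,
                          std: StandardStateSpec | None = None) -> tuple[float, float]:
    """Analytic translational freedom factor of the restrained ion.

    Under a Gaussian (rigid-rotor) approximation of the u_trans
    configurational integral in (r, θ, ψ) coordinates,

        F_t = r0² sin(θ0) (2π k_BT)^{3/2} / (k_r k_θ k_ψ)^{1/2},

    in Å³.  Returns (F_t, −k_BT ln(F_t·C°)), the latter being the
    standard-state term entering the absolute binding free energy.
    """
    if min(spec.k_r, spec.k_theta, spec.k_psi) <= 0:
        raise ValueError("all three force constants must be positive "
                         "(the unrestrained integral is unbounded)")
    std = std if std is not None else StandardStateSpec(temperature=temperature)
    kt = KB * temperature
    theta0 = math.radians(spec.theta0)
    ft = (spec.r0 ** 2 * math.sin(theta0) * (2.0 * math.pi * kt) ** 1.5
          / math.sqrt(spec.k_r * spec.k_theta * spec.k_psi))
    return ft, -kt * math.log(ft * std.c_standard)


def binding_free_energy(g_int_site: float, g_int_bulk: float,
                        g_trans_site: float, spec: RestraintSpec,
                        temperature: float = T_DEFAULT,
                        std: StandardStateSpec | None = None) -> float:
    """Absolute standard-state binding free energy of one species.

    ΔG_bind = (G_int^site − G_int^bulk) + [−k_BT ln(F_t C°) − G_trans^site].
    """
    _, std_term = restraint_free_factor(spec, temperature, std)
    return (g_int_site - g_int_bulk) + (std_term - g_trans_site)


def assemble_binding_dg(dg_site: float, dg_bulk: float, dg_trans: float = 0.0,
                        *, errors: tuple[float, float, float] = (0.0, 0.0, 0.0),
                        temperature: float = T_DEFAULT, scenario_id: str = "",
                        site: str = "") -> SelectivityRecord:
    """Assemble ΔΔG_i→j = ΔG_site − ΔG_bulk − ΔG_trans from leg differences.

    Inputs are the i→j *differences* of each leg (ΔG_trans =
    G_j,trans − G_i,trans); leg errors are propagated in quadrature.
    A negative result means species j binds more favourably.
    """
    ddg = dg_site - dg_bulk - dg_trans
    err = math.sqrt(sum(e * e for e in errors))
    return SelectivityRecord(scenario_id=scenario_id, site=site, ddg=ddg,
                             error=err, temperature=temperature,
                             meta={"dg_site": dg_site, "dg_bulk": dg_bulk,
                                   "dg_trans": dg_trans})


def kd_ratio(ddg: float, temperature: float = T_DEFAULT) -> tuple[float, float]:
    """(ln(K_D,j/K_D,i), K_D,j/K_D,i) from ΔΔG_i→j = RT ln(K_D,j/K_D,i)."""
    if not math.isfinite(ddg):
        raise ValueError("ΔΔG must be finite")
    ln_ratio = ddg / (KB * temperature)
    return ln_ratio, math.exp(ln_ratio)


def ddg_from_kd_ratio(ratio: float, temperature: float = T_DEFAULT) -> float:
    """Inverse of :func:`kd_ratio`: ΔΔG from a K_D ratio."""
    if ratio <= 0:
        raise ValueError("K_D ratio must be positive")
    return KB * temperature * math.log(ratio)


def pka_from_legs(dg_site: float, dg_bulk: float,
                  temperature: float = T_DEFAULT,
                  reference_pka: float = 4.1) -> PkaResult:
    """pKa shift from the site/bulk deprotonation free-energy legs.

    ΔpKa = (ΔG_site^deprot − ΔG_bulk^deprot) / 2.303 k_BT, added to the
    bulk reference pKa of the titratable group (4.1 for an aspartate
    side chain in water).
    """
    delta = (dg_site - dg_bulk) / (LN10 * KB * temperature)
    return PkaResult(dg_site=dg_site, dg_bulk=dg_bulk, delta_pka=delta,
                     reference_pka=reference_pka, pka=reference_pka + delta,
                     temperature=temperature)
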