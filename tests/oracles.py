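"""Independent oracles shared across the test suite.

These are deliberately written against the mathematics, not against the
package's own estimator code paths: a bisection Bennett solver, exact
Gaussian sampling of harmonic states, and direct numerical quadrature
of the restrained configurational integral.
"""

import math

import numpy as np
from scipy import integrate
from scipy.optimize import brentq

from pumpsel.alchemy import CrossEnergyMatrix
from pumpsel.constants import KB


def bennett_bar(du_forward, du_reverse, beta):
    """Two-state Bennett acceptance-ratio estimate.

    du_forward = U1−U0 on frames from state 0; du_reverse = U0−U1 on
    frames from state 1.  Solves the implicit Fermi-function equation
    Σ_0 f(β(M+ΔU_f−ΔF)) = Σ_1 f(β(−M+ΔU_r+ΔF)) by bisection.
    """
    n0, n1 = len(du_forward), len(du_reverse)
    m = np.log(n1 / n0) / beta

    def fermi(x):
        return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))

    def residual(df):
        return (np.sum(fermi(beta * (m + du_forward - df)))
                - np.sum(fermi(beta * (-m + du_reverse + df))))

    return brentq(residual, -200.0, 200.0, xtol=1e-12)


def gaussian_two_state_matrix(k0, k1, n, rng, temperature=303.15):
    """Exact samples from two harmonic states ½k x² with cross energies."""
    beta = 1.0 / (KB * temperature)
    x0 = rng.normal(scale=np.sqrt(1.0 / (beta * k0)), size=n)
    x1 = rng.normal(scale=np.sqrt(1.0 / (beta * k1)), size=n)
    x = np.concatenate([x0, x1])
    u = np.stack([0.5 * k0 * x * x, 0.5 * k1 * x * x], axis=1)
    origin = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    return CrossEnergyMatrix(energies=u, origin=origin), x0, x1


def quadrature_ft(spec, temperature):
    """3-D numerical integral ∫ r² sinθ e^{−u_trans/k_BT} dr dθ dψ."""
    kt = KB * temperature
    th0 = math.radians(spec.theta0)
    ps0 = math.radians(spec.psi0)

    def integrand(psi, theta, r):
        u = 0.5 * (spec.k_r * (r - spec.r0) ** 2
                   + spec.k_theta * (theta - th0) ** 2
                   + spec.k_psi * (psi - ps0) ** 2)
        return r * r * math.sin(theta) * math.exp(-u / kt)

    val, _ = integrate.tplquad(
        integrand, max(0.0, spec.r0 - 3.0), spec.r0 + 3.0,
        lambda r: max(1e-6, th0 - 1.0), lambda r: min(math.pi - 1e-6, th0 + 1.0),
        lambda r, t: ps0 - 1.5, lambda r, t: ps0 + 1.5,
        epsabs=1e-10, epsrel=1e-8)
    return val
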