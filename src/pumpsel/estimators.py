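"""Free-energy estimators: umbrella WHAM, multistate WHAM, block errors.

The weighted histogram analysis method (WHAM) is used in two guises:

* binned, periodic WHAM over umbrella windows along a torsion, giving
  the potential of mean force 𝒲(χ) anchored at its minimum; and
* histogram-free multistate WHAM over frames cross-evaluated under every
  alchemical state (the self-consistent form of multistate reweighting,
  equivalent to iterated Bennett), giving per-state free energies f_k
  with f_0 ≡ 0.

Statistical errors follow the block convention: the trajectory is cut
into contiguous blocks (10 by default), the estimator is applied per
block, and the *sample standard deviation* across block estimates is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .sampling import SampleSeries, UmbrellaWindowSpec, umbrella_bias_energy

__all__ = [
    "TorsionPMF",
    "WHAMResult",
    "FreeEnergyResult",
    "wham_umbrella",
    "wham_multistate",
    "block_error",
]

WHAM_TOL = 1e-8      # kcal/mol, max |Δf| between iterations
WHAM_MAX_ITER = 100_000


@dataclass
class TorsionPMF:
    """Potential of mean force on a periodic χ grid, min anchored at 0."""

    grid: np.ndarray        # bin centres, degrees, ascending over one period
    values: np.ndarray      # kcal/mol
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid/value shape mismatch")

    def anchored(self) -> "TorsionPMF":
        return TorsionPMF(self.grid, self.values - self.values.min(), self.counts)

    def interp(self, chi_deg) -> np.ndarray:
        """Periodic linear interpolation of 𝒲 at arbitrary angles."""
        chi = (np.asarray(chi_deg, dtype=float) - self.grid[0]) % 360.0 + self.grid[0]
        gx = np.append(self.grid, self.grid[0] + 360.0)
        gy = np.append(self.values, self.values[0])
        return np.interp(chi, gx, gy)


@dataclass
class WHAMResult:
    """Converged multistate WHAM output (f_0 ≡ 0)."""

    f: np.ndarray                    # per-state free energies, kcal/mol
    residual: float
    n_iter: int
    ess: np.ndarray                  # per-state effective sample sizes
    log_weights: np.ndarray | None = None   # frame mixture log-weights

    @property
    def delta_f(self) -> np.ndarray:
        return self.f - self.f[0]


@dataclass
class FreeEnergyResult:
    """Assembled alchemical legs for one site/scenario.

    ΔΔG = ΔG_site − ΔG_bulk − ΔG_trans holds by construction, with
    ΔG_trans = G_j,trans − G_i,trans the restraint-release difference
    between the two species (so ΔΔG gains +(G_i − G_j) from the lost
    translational freedom).
    """

    scenario_id: str
    dg_site: float
    dg_bulk: float
    dg_trans_i: float = 0.0
    dg_trans_j: float = 0.0
    error: float = 0.0
    site: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("block error must be non-negative")

    @property
    def dg_trans(self) -> float:
        return self.dg_trans_j - self.dg_trans_i

    @property
    def ddg(self) -> float:
        return self.dg_site - self.dg_bulk - self.dg_trans


# ---------------------------------------------------------------------------
# Umbrella WHAM


def wham_umbrella(series: Sequence[SampleSeries],
                  windows: Sequence[UmbrellaWindowSpec] | None = None,
                  temperature: float | None = None, n_bins: int = 180,
                  coordinates: Sequence[np.ndarray] | None = None) -> TorsionPMF:
    """Unbias umbrella-window histograms into a periodic torsion PMF.

    Windows default to each series' tagged ``meta['window']``.
    ``coordinates`` overrides the biased coordinate per series (needed
    when the series holds a full χ vector).  The default 180 bins give
    a 2° histogram resolution.
    """
    if len(series) < 1:
        raise ValueError("need at least one umbrella series")
    if windows is None:
        windows = [s.meta.get("window") for s in series]
        if any(w is None for w in windows):
            raise ValueError("series are missing umbrella window tags")
    if len(windows) != len(series):
        raise ValueError("one window spec per series required")
    T = temperature if temperature is not None else series[0].temperature
    beta = 1.0 / (KB * T)

    if coordinates is None:
        coordinates = []
        for s in series:
            chi = np.asarray(s.chi)
            if chi.ndim != 1:
                raise ValueError("pass explicit coordinates for multi-torsion series")
            coordinates.append(chi)

    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    K = len(windows)
    counts = np.zeros((K, n_bins))
    for k, chi in enumerate(coordinates):
        h, _ = np.histogram(np.mod(np.asarray(chi) + 180.0, 360.0) - 180.0,
                            bins=edges)
        counts[k] = h
    n_k = counts.sum(axis=1)
    total = counts.sum(axis=0)
    if np.any(total == 0):
        gaps = centers[total == 0]
        raise ValueError(
            f"umbrella coverage has empty bins near χ = {gaps[:3]}... — "
            "windows do not tile the period at this resolution")

    # bias energy of window k at bin centre b
    c_kb = np.stack([umbrella_bias_energy(w, centers) for w in windows])
    log_nk = np.log(n_k)
    f = np.zeros(K)
    log_total = np.log(total)
    for it in range(WHAM_MAX_ITER):
        # log P_b = log Σ_k n_kb − log Σ_k N_k e^{β f_k − β c_kb}
        log_denom = logsumexp(log_nk[:, None] + beta * (f[:, None] - c_kb), axis=0)
        log_p = log_total - log_denom
        log_p -= logsumexp(log_p)
        f_new = -logsumexp(log_p[None, :] - beta * c_kb, axis=1) / beta
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < WHAM_TOL:
            break
    w = -np.array(log_p) / beta
    return TorsionPMF(grid=centers, values=w - w.min(), counts=total)


# ---------------------------------------------------------------------------
# Multistate WHAM


def wham_multistate(matrix, temperature: float) -> WHAMResult:
    """Self-consistent multistate WHAM over cross-evaluated frames.

    ``matrix`` provides ``energies`` (n_frames × K, kcal/mol, every frame
    under every state) and ``origin`` (state index that generated each
    frame).  Returns converged per-state free energies with f_0 = 0; the
    result is deterministic given the matrix.
    """
    u = np.asarray(matrix.energies, dtype=float)
    origin = np.asarray(matrix.origin, dtype=int)
    if u.ndim != 2:
        raise ValueError("energy matrix must be frames × states")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite cross-energies")
    n, K = u.shape
    counts = np.bincount(origin, minlength=K).astype(float)
    if np.any(counts == 0):
        raise ValueError("every state must contribute frames")
    beta = 1.0 / (KB * temperature)
    # stabilise: subtract a per-frame reference before exponentiating
    u_shift = u - u.min(axis=1, keepdims=True)
    log_counts = np.log(counts)

    # The self-consistent equations are the stationarity conditions of a
    # convex objective; a quasi-Newton solve gets close fast, after which
    # a few self-consistent sweeps certify the fixed point to tolerance.
    from scipy.optimize import minimize

    def objective(bf):  # bf = β f_k, bf[0] pinned by symmetry removal later
        log_mix = logsumexp(log_counts[None, :] + bf[None, :] - beta * u_shift,
                            axis=1)
        val = float(np.sum(log_mix)) - float(np.dot(counts, bf))
        w = np.exp(log_counts[None, :] + bf[None, :] - beta * u_shift
                   - log_mix[:, None])
        grad = w.sum(axis=0) - counts
        return val, grad

    res = minimize(objective, np.zeros(K), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    bf = np.asarray(res.x)
    bf = bf - bf[0]

    # Newton polish with f_0 pinned: the gradient is Σ_n w_nk − N_k and
    # the Hessian diag(Σ_n w_nk) − WᵀW, so near-disjoint states (where
    # plain fixed-point iteration contracts arbitrarily slowly) still
    # converge quadratically.
    for _ in range(200):
        log_mix = logsumexp(log_counts[None, :] + bf[None, :] - beta * u_shift,
                            axis=1)
        w = np.exp(log_counts[None, :] + bf[None, :] - beta * u_shift
                   - log_mix[:, None])
        grad = w.sum(axis=0) - counts
        if np.max(np.abs(grad)) < 1e-12 * counts.sum():
            break
        hess = np.diag(w.sum(axis=0)) - w.T @ w
        h = hess[1:, 1:] + 1e-12 * np.eye(K - 1)
        try:
            step = np.linalg.solve(h, grad[1:])
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -50.0, 50.0)
        bf[1:] -= step
    f = bf / beta
    f -= f[0]

    # certify the fixed point with self-consistent sweeps
    resid = np.inf
    it = 0
    for it in range(1, WHAM_MAX_ITER + 1):
        log_mix = logsumexp(log_counts[None, :] + beta * (f[None, :] - u_shift),
                            axis=1)
        f_new = -logsumexp(-beta * u_shift - log_mix[:, None], axis=0) / beta
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < WHAM_TOL:
            break
        if it % 50 == 0:
            _, grad = objective(beta * f)
            if np.max(np.abs(grad)) < 1e-9 * counts.sum():
                break
    else:
        raise RuntimeError(f"multistate WHAM failed to converge (residual {resid:.2e})")
    log_mix = logsumexp(log_counts[None, :] + beta * (f[None, :] - u_shift), axis=1)
    log_w = -beta * u_shift - log_mix[:, None]          # n × K, unnormalised
    ess = np.exp(2 * logsumexp(log_w, axis=0) - logsumexp(2 * log_w, axis=0))
    return WHAMResult(f=f, residual=resid, n_iter=it, ess=ess,
                      log_weights=-log_mix)


# ---------------------------------------------------------------------------
# Block error


def block_error(data, n_blocks: int = 10,
                estimator: Callable[..., float] | None = None) -> tuple[float, np.ndarray]:
    """Blocked statistical error of an estimator over a trajectory.

    ``data`` is one array or a tuple of equally-long arrays sliced
    together; ``estimator`` maps the slice(s) to a scalar (default: mean
    of the first array).  The trajectory is split into ``n_blocks``
    contiguous blocks and the sample standard deviation of the per-block
    estimates is returned together with the estimates themselves.
    """
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all input arrays must have equal length")
    if n_blocks < 1 or n < n_blocks:
        raise ValueError("need at least as many frames as blocks")
    if estimator is None:
        estimator = lambda a, *rest: float(np.mean(a))
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    estimates = np.array([
        float(estimator(*(a[bounds[b]:bounds[b + 1]] for a in arrays)))
        for b in range(n_blocks)
    ])
    if n_blocks == 1:
        return 0.0, estimates
    return float(np.std(estimates, ddof=1)), estimates
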