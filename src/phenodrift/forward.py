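"""Forward model: growth, death, and phenotype transitions in tolerance space.

The population density N(x, t) (CFU/mL per tolerance bin) evolves by

    dN/dt = r_c N  −  H(x, F) N  +  D d²N/dx²  +  v dN/dx

with zero-flux boundaries at x = 0 and x = L.  Growth at the substrate-
specific rate r_c is phenotype-independent; death occurs only below the
medium formaldehyde concentration F at rate H(x, F) = α (F − b x); random
phenotype transitions act as diffusion with coefficient D; directed
transitions act as advection with rate v, a *positive* v moving the
population toward lower tolerance.

The PDE is semi-discretized on the uniform tolerance grid (method of
lines): one ODE per 0.01 mM bin by default, with conservative flux-form
central differences for diffusion and first-order donor-cell upwinding for
advection.  The resulting linear stiff system is integrated with LSODA
using its exact (banded, constant) Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .distributions import PhenotypeDensity
from .grids import ToleranceGrid

__all__ = ["ModelParameters", "SimulationResult", "death_rate", "assemble_operator", "simulate"]


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the structured-population model.

    Attributes
    ----------
    r_c : float
        Per-capita growth rate on the current substrate (h⁻¹).
    alpha : float
        Death-rate coefficient (h⁻¹ per mM formaldehyde in the medium).
    b : float
        Sensitivity of death to a cell's own tolerance (mM tolerance per
        mM formaldehyde; 0 ≤ b ≤ 1).  b = 0: all sub-threshold cells die
        equally fast; b → 1: death slows as tolerance approaches F.
    D : float
        Phenotypic diffusion coefficient (mM²·h⁻¹, tolerance units).
    v : float
        Phenotypic advection rate (mM·h⁻¹); positive values drift the
        population toward lower tolerance.
    F : float
        Formaldehyde concentration in the medium (mM).
    """

    r_c: float
    alpha: float = 0.0
    b: float = 0.0
    D: float = 0.0
    v: float = 0.0
    F: float = 0.0

    def __post_init__(self) -> None:
        if self.r_c < 0:
            raise ValueError("growth rate r_c must be non-negative")
        if self.alpha < 0:
            raise ValueError("death coefficient alpha must be non-negative")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("tolerance-sensitivity b must lie in [0, 1]")
        if self.D < 0:
            raise ValueError("diffusion coefficient D must be non-negative")
        if self.F < 0:
            raise ValueError("formaldehyde concentration F must be non-negative")

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulationResult:
    grid: ToleranceGrid
    times: np.ndarray
    densities: np.ndarray  # shape (n_times, n_bins), clipped to >= 0

    def at(self, t: float) -> PhenotypeDensity:
        i = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[i], t, atol=1e-9):
            raise KeyError(f"time {t} h not among simulated output times")
        return PhenotypeDensity(self.grid, self.densities[i])


def death_rate(x, F: float, alpha: float, b: float):
    """Per-capita death rate H(x, F) = α (F − b x) for x < F, else 0 (h⁻¹)."""
    x = np.asarray(x, dtype=float)
    h = np.where(x < F, alpha * (F - b * x), 0.0)
    return h if h.ndim else float(h)


def assemble_operator(grid: ToleranceGrid, params: ModelParameters) -> np.ndarray:
    """Banded (3, n) form of the constant linear spatial operator A.

    Row 0 holds the superdiagonal, row 1 the diagonal, row 2 the
    subdiagonal (LAPACK banded layout), so that dN/dt = A N.
    """
    n = grid.n_bins
    dx = grid.dx
    x = grid.x
    ab = np.zeros((3, n))

    # growth and death: diagonal
    ab[1] += params.r_c - death_rate(x, params.F, params.alpha, params.b)

    # diffusion: conservative flux form, zero flux through both boundaries
    if params.D > 0:
        k = params.D / dx**2
        ab[1][0] -= k
        ab[1][1:-1] -= 2 * k
        ab[1][-1] -= k
        ab[0][1:] += k  # coupling to the right neighbour
        ab[2][:-1] += k  # coupling to the left neighbour

    # advection: donor-cell upwind in flux form; mass cannot cross x=0 or x=L
    if params.v > 0:  # transport toward lower tolerance
        a = params.v / dx
        ab[1][1:] -= a          # flux out through the left face of bins 1..n-1
        ab[0][1:] += a          # flux into bin i from bin i+1
        ab[0][-1] = ab[0][-1]   # top face closed: no inflow beyond L (already 0)
        ab[1][-1] = ab[1][-1]
        # bin 0 has no left face; bin n-1 loses through its left face only
    elif params.v < 0:  # transport toward higher tolerance
        a = -params.v / dx
        ab[1][:-1] -= a         # flux out through the right face of bins 0..n-2
        ab[2][:-1] += a         # flux into bin i from bin i-1
    return ab


def _banded_matvec(ab: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = ab[1] * y
    out[:-1] += ab[0][1:] * y[1:]
    out[1:] += ab[2][:-1] * y[:-1]
    return out


def rhs(grid: ToleranceGrid, params: ModelParameters):
    """Right-hand-side function mapping a density vector to its derivative."""
    ab = assemble_operator(grid, params)
    return lambda t, y: _banded_matvec(ab, y)


def simulate(
    init: PhenotypeDensity,
    params: ModelParameters,
    times,
    rtol: float = 1e-8,
    atol: float | None = None,
) -> SimulationResult:
    """Integrate the semi-discrete model from ``init`` to the requested times.

    ``times`` must be sorted with times[0] = 0 (the simulation clock starts
    at the initial-condition sample).  Negative undershoot from the solver
    is clipped to zero in the returned densities; the raw state is checked
    for NaN/Inf and for undershoot beyond a small fraction of total mass.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a sorted 1-D array")
    if not np.isclose(times[0], 0.0):
        raise ValueError("simulation clock starts at 0 (the initial-condition time)")
    grid = init.grid
    y0 = init.values
    if atol is None:
        atol = 1e-10 * max(y0.sum() / grid.n_bins, 1e-30)

    if times.size == 1:  # only t=0 requested
        return SimulationResult(grid, times, y0[None, :].copy())

    ab = assemble_operator(grid, params)
    jac_packed = ab  # constant banded Jacobian in LAPACK layout

    sol = solve_ivp(
        lambda t, y: _banded_matvec(ab, y),
        (0.0, float(times[-1])),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac=lambda t, y: jac_packed,
        lband=1,
        uband=1,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    raw = sol.y.T
    if not np.all(np.isfinite(raw)):
        raise RuntimeError("non-finite values in solver state")
    undershoot = -raw.min()
    if undershoot > 1e-6 * max(y0.sum(), 1.0):
        raise RuntimeError(
            f"negative undershoot {undershoot:.3g} exceeds tolerance; refine grid or tolerances"
        )
    return SimulationResult(grid, times, np.maximum(raw, 0.0))
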