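"""Checkerboard Gauss-Seidel / SOR solution of the discretized PBE.

Discretization (flux-conservative 7-point stencil, kT/e units)
--------------------------------------------------------------
At an interior node 0 with the six midpoint permittivities eps_k and node
charge q0 (e), the converged linear-PBE potential satisfies

    phi0 = [ sum_k eps_k phi_k + 4 pi C_u q0 scale ]
           / [ sum_k eps_k + lambda0 * eps_solvent * (kappa h)^2 ]

where lambda0 is the ion-accessibility indicator and kappa the inverse Debye
length.  The salt term is stored as kappa_bar^2 = eps_solvent * kappa^2;
conventions differ between PB codes, so this is fixed here explicitly.

Iteration is red/black checkerboard Gauss-Seidel with successive
over-relaxation; sweeps are fully deterministic.  Convergence is declared
when the maximum unrelaxed update |delta phi| over a sweep falls below the
tolerance (kT/e) and a final explicit stencil-residual check passes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import (
    Atom,
    BoundaryCondition,
    DEFAULT_CONSTANTS,
    GridSpec,
    PhysicalConstants,
    RunParameters,
    coulomb_prefactor,
    debye_parameter,
)
from .mapping import DielectricMap, GeometricObject
from . import _kernels

__all__ = [
    "SolverConfig",
    "PotentialMap",
    "ConvergenceWarning",
    "DivergenceError",
    "optimal_omega",
    "boundary_potential",
    "solve_linear",
    "solve_nonlinear",
    "stencil_residual",
]

log = logging.getLogger(__name__)


class ConvergenceWarning(UserWarning):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Iteration controls; ``relaxation_omega=None`` selects the optimal value."""

    tolerance: float = 1.0e-4  # kT/e
    max_iterations: int = 20000
    relaxation_omega: Optional[float] = None
    nonlinear_damping: float = 0.6
    max_outer_iterations: int = 200

    def __post_init__(self) -> None:
        if not self.tolerance > 0.0:
            raise ValueError("tolerance must be > 0")
        if self.relaxation_omega is not None and not (0.0 < self.relaxation_omega < 2.0):
            raise ValueError("relaxation omega must lie in (0, 2)")
        if not (0.0 < self.nonlinear_damping <= 1.0):
            raise ValueError("nonlinear damping must lie in (0, 1]")

    @classmethod
    def from_params(cls, params: RunParameters) -> "SolverConfig":
        return cls(tolerance=params.tolerance, max_iterations=params.max_iterations)


@dataclass
class PotentialMap:
    """Node potentials in kT/e plus convergence bookkeeping."""

    grid: GridSpec
    values: np.ndarray  # (N, N, N)
    iterations_used: int
    final_residual: float
    converged: bool
    residual_trace: list = field(default_factory=list)


def optimal_omega(n: int) -> float:
    """SOR relaxation factor from the Jacobi spectral-radius estimate.

    rho = cos(pi/N) for an N^3 Dirichlet Laplacian; omega = 2/(1+sqrt(1-rho^2)).
    """
    if n < 5:
        raise ValueError("N must be >= 5")
    rho = math.cos(math.pi / n)
    return 2.0 / (1.0 + math.sqrt(1.0 - rho * rho))


def _gather_sources(atoms: Sequence[Atom], objects: Sequence[GeometricObject]):
    pos, q = [], []
    for a in atoms:
        if a.charge != 0.0:
            pos.append(a.position)
            q.append(a.charge)
    for o in objects:
        charge = getattr(o, "charge", 0.0)
        if charge != 0.0:
            lo, hi = o.bounding_box()
            pos.append(0.5 * (np.asarray(lo) + np.asarray(hi)))
            q.append(charge)
    return np.asarray(pos, dtype=float).reshape(-1, 3), np.asarray(q, dtype=float)


def _face_points(grid: GridSpec):
    """Yield (index expression, point array (M,3)) for the six cube faces."""
    n = grid.n
    ax = [grid.axis(d) for d in range(3)]
    for dim in range(3):
        for side in (0, n - 1):
            coords = []
            for d in range(3):
                coords.append(np.full(1, ax[d][side]) if d == dim else ax[d])
            g = np.meshgrid(*coords, indexing="ij")
            pts = np.stack([c.ravel() for c in g], axis=-1)
            idx = [slice(None)] * 3
            idx[dim] = side
            yield tuple(idx), pts


def boundary_potential(
    atoms: Sequence[Atom],
    objects: Sequence[GeometricObject],
    grid: GridSpec,
    params: RunParameters,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    eps_medium: Optional[float] = None,
    kappa: Optional[float] = None,
    mode: Optional[BoundaryCondition] = None,
) -> np.ndarray:
    """Potential on the six cube faces (N^3 array, interior zero).

    ``zero`` gives grounded faces; ``coulombic`` sums C_u q_i/(eps d_i) over
    all source charges; ``debye_huckel`` additionally screens each term by
    exp(-kappa d_i).  Charged objects contribute as point charges at their
    bounding-box centre.
    """
    mode = mode or params.boundary_condition
    phi = np.zeros((grid.n,) * 3, dtype=float)
    if mode is BoundaryCondition.ZERO:
        return phi
    eps = params.eps_solvent if eps_medium is None else eps_medium
    if kappa is None:
        kappa = (
            debye_parameter(params.salts, eps, constants)
            if mode is BoundaryCondition.DEBYE_HUCKEL
            else 0.0
        )
    pos, q = _gather_sources(atoms, objects)
    if len(q) == 0:
        return phi
    cu = coulomb_prefactor(constants)
    for idx, pts in _face_points(grid):
        d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=-1)
        if np.any(d == 0.0):
            raise ValueError("source charge coincides with a boundary node")
        vals = cu * q[None, :] / (eps * d)
        if kappa > 0.0:
            vals = vals * np.exp(-kappa * d)
        phi[idx] = vals.sum(axis=1).reshape(phi[idx].shape)
    return phi


def evaluate_boundary(
    scene_boundary: Callable[[np.ndarray], np.ndarray],
    grid: GridSpec,
) -> np.ndarray:
    """Fill the six faces from a user-supplied potential function."""
    phi = np.zeros((grid.n,) * 3, dtype=float)
    for idx, pts in _face_points(grid):
        phi[idx] = np.asarray(scene_boundary(pts), dtype=float).reshape(phi[idx].shape)
    return phi


def _interior_parity(n: int) -> np.ndarray:
    i = np.arange(1, n - 1)
    return (i[:, None, None] + i[None, :, None] + i[None, None, :]) % 2


def _neighbor_sum(phi: np.ndarray, ex, ey, ez) -> np.ndarray:
    """sum_k eps_k phi_k over the 6 neighbours of every interior node."""
    return (
        ex[:-1, 1:-1, 1:-1] * phi[:-2, 1:-1, 1:-1]
        + ex[1:, 1:-1, 1:-1] * phi[2:, 1:-1, 1:-1]
        + ey[1:-1, :-1, 1:-1] * phi[1:-1, :-2, 1:-1]
        + ey[1:-1, 1:, 1:-1] * phi[1:-1, 2:, 1:-1]
        + ez[1:-1, 1:-1, :-1] * phi[1:-1, 1:-1, :-2]
        + ez[1:-1, 1:-1, 1:] * phi[1:-1, 1:-1, 2:]
    )


def _eps_sum(ex, ey, ez) -> np.ndarray:
    return (
        ex[:-1, 1:-1, 1:-1]
        + ex[1:, 1:-1, 1:-1]
        + ey[1:-1, :-1, 1:-1]
        + ey[1:-1, 1:, 1:-1]
        + ez[1:-1, 1:-1, :-1]
        + ez[1:-1, 1:-1, 1:]
    )


def stencil_residual(
    phi: np.ndarray,
    diel: DielectricMap,
    source: np.ndarray,
    denominator: np.ndarray,
) -> float:
    """Max |phi_new - phi| over interior nodes (Gauss-Seidel displacement)."""
    ex, ey, ez = diel.values()
    num = _neighbor_sum(phi, ex, ey, ez) + source
    return float(np.max(np.abs(num / denominator - phi[1:-1, 1:-1, 1:-1])))


def _sor_iterate(
    phi: np.ndarray,
    diel: DielectricMap,
    source: np.ndarray,
    denominator: np.ndarray,
    tolerance: float,
    max_iterations: int,
    omega: float,
    trace: Optional[list] = None,
) -> tuple[int, float, bool]:
    """Run red/black SOR sweeps in place; return (sweeps, residual, converged)."""
    ex, ey, ez = diel.values()
    use_kernel = _kernels.HAVE_NUMBA
    if not use_kernel:
        parity = _interior_parity(phi.shape[0])
        masks = (parity == 0, parity == 1)
        interior = phi[1:-1, 1:-1, 1:-1]
    sweeps = 0
    residual = math.inf
    while sweeps < max_iterations:
        sweeps += 1
        max_delta = 0.0
        if use_kernel:
            for colour in (0, 1):
                md = _kernels.sor_colour_sweep(
                    phi, ex, ey, ez, source, denominator, omega, colour
                )
                if md > max_delta:
                    max_delta = md
        else:
            for mask in masks:
                num = _neighbor_sum(phi, ex, ey, ez) + source
                delta = num / denominator - interior
                md = float(np.max(np.abs(delta[mask])))
                if md > max_delta:
                    max_delta = md
                interior[mask] += omega * delta[mask]
        residual = max_delta
        if trace is not None:
            trace.append(max_delta)
        if max_delta <= tolerance:
            # the per-colour deltas were measured mid-sweep; confirm on the
            # final field before declaring convergence
            final = stencil_residual(phi, diel, source, denominator)
            if final <= tolerance:
                return sweeps, final, True
    return sweeps, residual, False


def _prepare_linear(
    diel: DielectricMap,
    node_charges: np.ndarray,
    ion_mask: np.ndarray,
    grid: GridSpec,
    params: RunParameters,
    constants: PhysicalConstants,
    include_salt: bool = True,
):
    cu = coulomb_prefactor(constants)
    source = 4.0 * math.pi * cu * grid.scale * node_charges[1:-1, 1:-1, 1:-1]
    ex, ey, ez = diel.values()
    den = _eps_sum(ex, ey, ez)
    if include_salt:
        kappa = debye_parameter(params.salts, params.eps_solvent, constants)
        if kappa > 0.0:
            kh2 = (kappa * grid.spacing) ** 2
            lam = ion_mask[1:-1, 1:-1, 1:-1].astype(float)
            den = den + lam * params.eps_solvent * kh2
    return source, den


def solve_linear(
    diel: DielectricMap,
    node_charges: np.ndarray,
    ion_mask: np.ndarray,
    grid: GridSpec,
    params: RunParameters,
    config: Optional[SolverConfig] = None,
    boundary: Optional[np.ndarray] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> PotentialMap:
    """Solve the linearized PBE; ``boundary`` holds fixed face values."""
    config = config or SolverConfig.from_params(params)
    n = grid.n
    if node_charges.shape != (n, n, n) or ion_mask.shape != (n, n, n):
        raise ValueError("lattice shapes do not match the grid")
    phi = (
        np.array(boundary, dtype=float, copy=True)
        if boundary is not None
        else boundary_potential([], [], grid, params, constants)
    )
    source, den = _prepare_linear(diel, node_charges, ion_mask, grid, params, constants)
    omega = config.relaxation_omega or optimal_omega(n)
    trace: list = []
    sweeps, residual, converged = _sor_iterate(
        phi, diel, source, den, config.tolerance, config.max_iterations, omega, trace
    )
    if not converged:
        warnings.warn(
            f"linear PBE not converged after {sweeps} sweeps "
            f"(max |delta phi| = {residual:.3e} kT/e)",
            ConvergenceWarning,
            stacklevel=2,
        )
    log.debug("linear solve: %d sweeps, residual %.3e", sweeps, residual)
    return PotentialMap(grid, phi, sweeps, residual, converged, trace)


def solve_nonlinear(
    diel: DielectricMap,
    node_charges: np.ndarray,
    ion_mask: np.ndarray,
    grid: GridSpec,
    params: RunParameters,
    config: Optional[SolverConfig] = None,
    boundary: Optional[np.ndarray] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> PotentialMap:
    """Solve the full (Boltzmann-ion) PBE by damped successive linearization.

    Each outer iteration linearizes the mobile-ion charge density
    rho(phi) = sum_i c'_i z_i exp(-z_i phi) about the current iterate
    (a Newton step): the negative slope -rho'(phi_bar) joins the stencil
    denominator, which keeps every inner linear solve diagonally dominant no
    matter how large the potential, and the remainder becomes a fixed source.
    Outer updates are under-relaxed by the damping factor.  In the weak-
    potential limit rho' -> -2 I', and the scheme reduces exactly to the
    linearized equation; with no salt the linear solver result is returned
    unchanged.
    """
    config = config or SolverConfig.from_params(params)
    if not params.salts:
        return solve_linear(
            diel, node_charges, ion_mask, grid, params, config, boundary, constants
        )
    n = grid.n
    phi = (
        np.array(boundary, dtype=float, copy=True)
        if boundary is not None
        else boundary_potential([], [], grid, params, constants)
    )
    # the full Boltzmann ion term replaces the linear salt term entirely
    source0, den0 = _prepare_linear(
        diel, node_charges, ion_mask, grid, params, constants, include_salt=False
    )
    cu = coulomb_prefactor(constants)
    h = grid.spacing
    lam = ion_mask[1:-1, 1:-1, 1:-1].astype(float)
    conc = np.array([s.concentration for s in params.salts]) * (
        constants.avogadro * 1.0e-27
    )  # particles/Å^3
    z = np.array([float(s.valence) for s in params.salts])
    prefac = 4.0 * math.pi * cu * h * h
    _EXP_CLIP = 60.0  # keeps exp() finite; only transients ever reach it

    def ion_density_and_slope(phi_int: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """rho(phi) and rho'(phi) of the Boltzmann ion charge density, e/Å^3."""
        rho = np.zeros_like(phi_int)
        slope = np.zeros_like(phi_int)
        for ci, zi in zip(conc, z):
            boltz = np.exp(np.clip(-zi * phi_int, -_EXP_CLIP, _EXP_CLIP))
            rho += ci * zi * boltz
            slope -= ci * zi * zi * boltz
        return rho, slope

    omega = config.relaxation_omega or optimal_omega(n)
    trace: list = []
    total_sweeps = 0
    outer_residual = math.inf
    growth_streak = 0
    converged = False
    phi_bar = phi.copy()
    for outer in range(1, config.max_outer_iterations + 1):
        pin = phi_bar[1:-1, 1:-1, 1:-1]
        rho, slope = ion_density_and_slope(pin)
        den = den0 - prefac * lam * slope
        source = source0 + prefac * lam * (rho - slope * pin)
        phi_work = phi_bar.copy()
        sweeps, inner_res, inner_ok = _sor_iterate(
            phi_work, diel, source, den, config.tolerance, config.max_iterations, omega
        )
        total_sweeps += sweeps
        change = float(np.max(np.abs(phi_work - phi_bar)))
        trace.append(change)
        if change > outer_residual:
            growth_streak += 1
            if growth_streak >= 10:
                raise DivergenceError(
                    "nonlinear PBE outer iteration diverging; "
                    "retry with a smaller nonlinear_damping"
                )
        else:
            growth_streak = 0
        outer_residual = change
        if change <= config.tolerance and inner_ok:
            phi_bar = phi_work
            converged = True
            break
        alpha = config.nonlinear_damping
        phi_bar = phi_bar + alpha * (phi_work - phi_bar)
    if not converged:
        warnings.warn(
            f"nonlinear PBE not converged after {outer} outer iterations "
            f"(outer change {outer_residual:.3e} kT/e)",
            ConvergenceWarning,
            stacklevel=2,
        )
    log.debug(
        "nonlinear solve: %d outer iterations, %d sweeps total", outer, total_sweeps
    )
    return PotentialMap(grid, phi_bar, total_sweeps, outer_residual, converged, trace)
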