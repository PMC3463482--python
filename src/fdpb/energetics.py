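"""Energy decomposition and ion-concentration maps from a converged potential.

The grid energy 1/2 sum q phi contains a spacing-dependent self-energy and is
not physical on its own; solvation (reaction-field) energies are obtained as
the difference of two grid energies computed on the identical grid and node
charge layout — one heterogeneous (solute dielectric inside, solvent and salt
outside), one uniform reference — so the self-energy cancels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .core import (
    Atom,
    BoundaryCondition,
    DEFAULT_CONSTANTS,
    DielectricScene,
    GridSpec,
    PhysicalConstants,
    RunParameters,
    SaltSpecies,
    build_grid,
    coulomb_prefactor,
)
from .mapping import (
    DielectricMap,
    build_dielectric_map,
    build_ion_mask,
    distribute_charges,
)
from .solver import (
    PotentialMap,
    SolverConfig,
    boundary_potential,
    evaluate_boundary,
    solve_linear,
    solve_nonlinear,
)
from .core import Equation

__all__ = [
    "EnergyReport",
    "SolvationResult",
    "grid_energy",
    "coulombic_energy",
    "solvation_energy",
    "ion_concentration_map",
]


@dataclass
class EnergyReport:
    """Energy components in kT plus run metadata."""

    grid_energy: float
    coulombic_energy: float
    solvation_energy: float
    metadata: dict = field(default_factory=dict)

    def rows(self) -> list[tuple[str, float]]:
        return [
            ("grid_energy_kT", self.grid_energy),
            ("coulombic_energy_kT", self.coulombic_energy),
            ("solvation_energy_kT", self.solvation_energy),
        ]


def grid_energy(node_charges: np.ndarray, potential: PotentialMap | np.ndarray) -> float:
    """1/2 sum_nodes q phi in kT.

    Contains the grid self-energy, which grows linearly with scale; only
    differences between runs with identical charge layouts are physical.
    """
    phi = potential.values if isinstance(potential, PotentialMap) else potential
    if phi.shape != node_charges.shape:
        raise ValueError("charge and potential lattices have different shapes")
    return 0.5 * float(np.sum(node_charges * phi))


def coulombic_energy(
    atoms: Sequence[Atom],
    eps_interior: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Pairwise Coulomb energy sum_{i<j} C_u q_i q_j / (eps_int r_ij) in kT."""
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    if len(atoms) < 2:
        return 0.0
    pos = np.array([a.position for a in atoms], dtype=float)
    q = np.array([a.charge for a in atoms], dtype=float)
    d = pdist(pos)
    iu = np.triu_indices(len(q), k=1)
    qq = (q[:, None] * q[None, :])[iu]
    if np.any((d == 0.0) & (qq != 0.0)):
        raise ValueError("coincident charged atoms have a divergent pair energy")
    cu = coulomb_prefactor(constants)
    mask = d > 0.0
    return float(cu / eps_interior * np.sum(qq[mask] / d[mask]))


@dataclass
class SolvationResult:
    """Two-run solvation energy with both converged potentials retained."""

    energy: float  # kT
    heterogeneous: PotentialMap
    reference: PotentialMap
    grid: GridSpec
    node_charges: np.ndarray
    converged: bool
    eps_reference: float

    def __float__(self) -> float:
        return self.energy

    def reaction_field_map(self) -> np.ndarray:
        """phi_het - phi_ref: the reaction-field potential in kT/e."""
        return self.heterogeneous.values - self.reference.values


def _infer_reference_eps(scene: DielectricScene, params: RunParameters) -> float:
    regions = {a.region_id for a in scene.atoms} | {
        o.region_id for o in scene.objects
    }
    eps = {params.eps_interior[r] for r in regions}
    if len(eps) != 1:
        raise ValueError(
            "scene has several interior permittivities; pass eps_reference "
            "explicitly for the uniform reference run"
        )
    return eps.pop()


def solvation_energy(
    scene: DielectricScene,
    config: Optional[SolverConfig] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    eps_reference: Optional[float] = None,
) -> SolvationResult:
    """Electrostatic solvation energy by the two-run grid-energy difference.

    Run 1 solves the scene as declared (heterogeneous dielectric, salt); run 2
    solves the same node charges on the same grid in a uniform dielectric
    ``eps_reference`` (by default the solute's interior permittivity) with no
    salt and the analytic uniform-medium Coulomb boundary.  The grid
    self-energy is identical in both runs and cancels in the difference.
    """
    params = scene.params
    grid = scene.grid_override or build_grid(scene.atoms, scene.objects, params)
    config = config or SolverConfig.from_params(params)
    diel = build_dielectric_map(scene.atoms, scene.objects, grid, params)
    mask = build_ion_mask(scene.atoms, scene.objects, grid, params)
    charges = distribute_charges(scene.atoms, scene.objects, grid)

    if scene.boundary_values is not None:
        bc_het = evaluate_boundary(scene.boundary_values, grid)
    else:
        bc_het = boundary_potential(scene.atoms, scene.objects, grid, params, constants)
    solve = solve_nonlinear if params.equation is Equation.NONLINEAR else solve_linear
    het = solve(diel, charges, mask, grid, params, config, bc_het, constants)

    eps_ref = eps_reference if eps_reference is not None else _infer_reference_eps(scene, params)
    n = grid.n
    diel_ref = DielectricMap(
        grid,
        np.full((n - 1, n, n), eps_ref),
        np.full((n, n - 1, n), eps_ref),
        np.full((n, n, n - 1), eps_ref),
    )
    params_ref = params.with_(salts=(), equation=Equation.LINEAR)
    bc_ref = boundary_potential(
        scene.atoms,
        scene.objects,
        grid,
        params_ref,
        constants,
        eps_medium=eps_ref,
        mode=BoundaryCondition.COULOMBIC,
    )
    ref = solve_linear(
        diel_ref, charges, np.ones_like(mask), grid, params_ref, config, bc_ref, constants
    )

    converged = het.converged and ref.converged
    if not converged:
        warnings.warn(
            "solvation energy computed from a non-converged run",
            UserWarning,
            stacklevel=2,
        )
    energy = grid_energy(charges, het) - grid_energy(charges, ref)
    return SolvationResult(
        energy=energy,
        heterogeneous=het,
        reference=ref,
        grid=grid,
        node_charges=charges,
        converged=converged,
        eps_reference=eps_ref,
    )


def ion_concentration_map(
    potential: PotentialMap,
    salts: Sequence[SaltSpecies],
    ion_mask: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> list[np.ndarray]:
    """Boltzmann concentration c_i exp(-z_i phi) per species, in mol/L.

    The potential is already in kT/e, so the Boltzmann exponent is -z_i phi
    directly; ion-inaccessible nodes are exactly zero.
    """
    phi = potential.values
    maps = []
    lam = ion_mask.astype(float)
    for s in salts:
        c = s.concentration * np.exp(np.clip(-s.valence * phi, -500.0, 500.0)) * lam
        maps.append(c)
    return maps
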