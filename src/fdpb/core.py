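"""Physical constants, unit system, grid geometry and shared domain types.

Internal unit system
--------------------
Lengths are in ångström, charges in units of the elementary charge ``e``,
potentials in kT/e and energies in kT, evaluated at the reference temperature
T = 297.33 K.  The single bridge between this system and SI is the Coulomb
prefactor

    C_u = e^2 / (4 pi eps0 * 1 Å * kT)   [kT·Å / e^2]

so that the potential of a charge ``q`` (in e) at distance ``d`` (in Å) in a
uniform medium of relative permittivity ``eps`` is ``C_u * q / (eps * d)`` in
kT/e.  With the default constants C_u ≈ 562.005 kT·Å/e².
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PhysicalConstants",
    "DEFAULT_CONSTANTS",
    "GridSpec",
    "Atom",
    "SaltSpecies",
    "BoundaryCondition",
    "Equation",
    "SurfaceMode",
    "DielectricAveraging",
    "RunParameters",
    "DielectricScene",
    "coulomb_prefactor",
    "debye_parameter",
    "ionic_strength",
    "build_grid",
    "GridSizeError",
]

#: metres per ångström
ANGSTROM = 1.0e-10
#: litres per cubic ångström times Avogadro gives particles/Å^3 from mol/L
_PER_ANG3_FROM_MOLAR = 1.0e-27


@dataclass(frozen=True)
class PhysicalConstants:
    """SI constants defining the kT/e unit bridge.

    Defaults are CODATA-2010 values at the reference temperature 297.33 K.
    The Boltzmann constant is kept at full precision: rounding it to two
    significant digits (1.38e-23) shifts every energy in this package by
    ~0.05%, which is visible at the precision of the built-in analytic
    benchmarks.
    """

    elementary_charge: float = 1.602176565e-19  # C
    vacuum_permittivity: float = 8.8541878176e-12  # F/m
    boltzmann_constant: float = 1.3806488e-23  # J/K
    temperature: float = 297.33  # K
    avogadro: float = 6.02214129e23  # 1/mol

    def __post_init__(self) -> None:
        for name in (
            "elementary_charge",
            "vacuum_permittivity",
            "boltzmann_constant",
            "temperature",
            "avogadro",
        ):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kT(self) -> float:
        """Thermal energy in joules."""
        return self.boltzmann_constant * self.temperature


DEFAULT_CONSTANTS = PhysicalConstants()


def coulomb_prefactor(constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Coulomb prefactor C_u in kT·Å per squared elementary charge.

    ``C_u * q / (eps * d)`` is the potential (kT/e) of charge ``q`` (e) at
    distance ``d`` (Å) in a uniform dielectric ``eps``.
    """
    e = constants.elementary_charge
    eps0 = constants.vacuum_permittivity
    return e * e / (4.0 * math.pi * eps0 * ANGSTROM * constants.kT)


@dataclass(frozen=True)
class SaltSpecies:
    """A mobile ion species: bulk concentration (mol/L) and signed valence."""

    concentration: float  # mol/L
    valence: int

    def __post_init__(self) -> None:
        if self.concentration < 0.0:
            raise ValueError("salt concentration must be >= 0")
        if int(self.valence) != self.valence or self.valence == 0:
            raise ValueError("salt valence must be a non-zero integer")


def _check_electroneutral(salts: Sequence[SaltSpecies]) -> None:
    net = sum(s.concentration * s.valence for s in salts)
    tot = sum(abs(s.concentration * s.valence) for s in salts)
    if tot > 0.0 and abs(net) > 1.0e-9 * tot:
        raise ValueError(
            f"salt list is not electroneutral: sum(c_i z_i) = {net:g} mol/L"
        )


def ionic_strength(salts: Sequence[SaltSpecies]) -> float:
    """I = 1/2 sum c_i z_i^2 in mol/L."""
    return 0.5 * sum(s.concentration * s.valence**2 for s in salts)


def debye_parameter(
    salts: Sequence[SaltSpecies],
    eps_solvent: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Inverse Debye screening length kappa in 1/Å.

    kappa^2 = 8 pi C_u (N_A 1e-27) I / eps_solvent with the ionic strength I
    in mol/L; an empty (or zero-concentration) salt list gives kappa = 0.
    The list must be electroneutral.
    """
    _check_electroneutral(salts)
    I = ionic_strength(salts)
    if I == 0.0:
        return 0.0
    cu = coulomb_prefactor(constants)
    number_density = constants.avogadro * _PER_ANG3_FROM_MOLAR * I  # 1/Å^3
    kappa2 = 8.0 * math.pi * cu * number_density / eps_solvent
    return math.sqrt(kappa2)


@dataclass(frozen=True)
class GridSpec:
    """Cubic lattice of N^3 nodes.

    Node (i, j, k) sits at ``origin + (i, j, k) * spacing``; N is odd so the
    centre node has index (N-1)/2 on every axis.  ``scale`` is the resolution
    in grid points per ångström; spacing is its exact reciprocal.
    """

    n: int
    scale: float
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.n < 5 or self.n % 2 == 0:
            raise ValueError("grid side N must be odd and >= 5")
        if not self.scale > 0.0:
            raise ValueError("scale must be > 0")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))

    @property
    def spacing(self) -> float:
        """Grid spacing h = 1/scale in Å."""
        return 1.0 / self.scale

    @property
    def edge_length(self) -> float:
        """Cube edge (N-1)·h in Å."""
        return (self.n - 1) * self.spacing

    @property
    def centre(self) -> np.ndarray:
        return np.asarray(self.origin) + 0.5 * (self.n - 1) * self.spacing

    def axis(self, dim: int) -> np.ndarray:
        """Node coordinates along one axis."""
        return self.origin[dim] + np.arange(self.n) * self.spacing

    def node_position(self, i: int, j: int, k: int) -> np.ndarray:
        return np.asarray(self.origin) + np.array([i, j, k]) * self.spacing

    def node_positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Axis coordinate arrays broadcastable to the N^3 lattice."""
        x = self.axis(0)[:, None, None]
        y = self.axis(1)[None, :, None]
        z = self.axis(2)[None, None, :]
        return x, y, z


@dataclass(frozen=True)
class Atom:
    """A charged sphere: position (Å), radius (Å), charge (e), region label."""

    position: tuple[float, float, float]
    radius: float
    charge: float
    region_id: int = 0
    name: str = ""
    residue_name: str = ""
    residue_number: int = 1

    def __post_init__(self) -> None:
        pos = tuple(float(x) for x in self.position)
        if len(pos) != 3 or not all(math.isfinite(x) for x in pos):
            raise ValueError("atom position must be a finite 3-vector")
        if not (math.isfinite(self.radius) and self.radius >= 0.0):
            raise ValueError("atom radius must be finite and >= 0")
        object.__setattr__(self, "position", pos)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position)


class BoundaryCondition(enum.Enum):
    ZERO = "zero"
    COULOMBIC = "coulombic"
    DEBYE_HUCKEL = "debye_huckel"


class Equation(enum.Enum):
    LINEAR = "linear"
    NONLINEAR = "nonlinear"


class SurfaceMode(enum.Enum):
    VDW = "vdw"
    SES = "ses"


class DielectricAveraging(enum.Enum):
    """How a midpoint permittivity is taken from the geometry.

    ``sharp`` assigns by point membership of the midpoint (each entry is one
    of the declared permittivities); ``harmonic`` weights the two media by
    the exact fraction of the node-to-node edge inside the solute and takes
    the harmonic mean, the flux-matched interface treatment that removes the
    O(h) surface-aliasing oscillation of sharp assignment.  Harmonic applies
    to the vdW surface (and to sphere/axis-aligned-box objects); the SES
    surface is always sharp.
    """

    SHARP = "sharp"
    HARMONIC = "harmonic"


@dataclass(frozen=True)
class RunParameters:
    """Everything a run needs besides the structure itself.

    ``eps_interior`` maps region labels to relative permittivities; atoms and
    geometric objects carry a ``region_id`` referring into this map.  The
    default filling percentage (perfil) of 70% means the largest linear
    dimension of the solute occupies 70% of the cube edge.
    """

    scale: float = 2.0
    perfil: float = 70.0
    eps_interior: Mapping[int, float] = field(default_factory=lambda: {0: 4.0})
    eps_solvent: float = 80.0
    probe_radius: float = 1.4
    ion_exclusion_radius: float = 2.0
    salts: tuple[SaltSpecies, ...] = ()
    tolerance: float = 1.0e-4  # kT/e, max |delta phi| per sweep
    max_iterations: int = 20000
    boundary_condition: BoundaryCondition = BoundaryCondition.COULOMBIC
    equation: Equation = Equation.LINEAR
    surface: SurfaceMode = SurfaceMode.SES
    dielectric_averaging: "DielectricAveraging" = None  # type: ignore[assignment]
    max_grid_points: int = 513  # memory guard on N

    def __post_init__(self) -> None:
        if not self.scale > 0.0:
            raise ValueError("scale must be > 0")
        if not (0.0 < self.perfil <= 100.0):
            raise ValueError("perfil must be in (0, 100]")
        eps = dict(self.eps_interior)
        for region, value in eps.items():
            if value < 1.0:
                raise ValueError(f"eps_interior[{region}] must be >= 1")
        object.__setattr__(self, "eps_interior", eps)
        if self.eps_solvent < 1.0:
            raise ValueError("eps_solvent must be >= 1")
        if self.probe_radius < 0.0:
            raise ValueError("probe_radius must be >= 0")
        if self.ion_exclusion_radius < 0.0:
            raise ValueError("ion_exclusion_radius must be >= 0")
        if not self.tolerance > 0.0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        salts = tuple(self.salts)
        _check_electroneutral(salts)
        object.__setattr__(self, "salts", salts)
        if self.dielectric_averaging is None:
            object.__setattr__(
                self, "dielectric_averaging", DielectricAveraging.HARMONIC
            )

    def with_(self, **kwargs) -> "RunParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class DielectricScene:
    """A complete electrostatics problem: structure, media and run settings.

    ``boundary_values`` may hold a callable ``f(points) -> phi`` (points with
    shape (..., 3) in Å, phi in kT/e) overriding the parameter-file boundary
    condition — used e.g. when an exact far-field solution is known.
    ``grid_override`` pins the lattice instead of deriving it from scale and
    perfil.
    """

    atoms: list[Atom]
    objects: list = field(default_factory=list)
    params: RunParameters = field(default_factory=RunParameters)
    boundary_values: Optional[object] = None
    grid_override: Optional[GridSpec] = None

    @property
    def total_charge(self) -> float:
        return sum(a.charge for a in self.atoms) + sum(
            getattr(o, "charge", 0.0) for o in self.objects
        )


class GridSizeError(ValueError):
    """Requested grid would exceed the configured memory guard."""


def _system_bounding_box(atoms: Sequence[Atom], objects: Sequence) -> tuple[np.ndarray, np.ndarray]:
    los, his = [], []
    for a in atoms:
        los.append(a.xyz - a.radius)
        his.append(a.xyz + a.radius)
    for o in objects:
        lo, hi = o.bounding_box()
        los.append(np.asarray(lo, dtype=float))
        his.append(np.asarray(hi, dtype=float))
    if not los:
        raise ValueError("cannot build a grid for an empty system")
    return np.min(los, axis=0), np.max(his, axis=0)


def build_grid(
    atoms: Sequence[Atom],
    objects: Sequence = (),
    params: RunParameters = RunParameters(),
) -> GridSpec:
    """Derive the cubic lattice from scale and filling percentage.

    The cube is centred on the midpoint of the system's axis-aligned bounding
    box (atom radii included); its edge is ``max_extent * 100 / perfil`` and
    the node count the smallest odd N with (N-1)·h >= edge.
    """
    lo, hi = _system_bounding_box(atoms, objects)
    centre = 0.5 * (lo + hi)
    max_extent = float(np.max(hi - lo))
    edge = max_extent * 100.0 / params.perfil
    n = int(math.ceil(edge * params.scale + 1.0 - 1e-12))
    if n % 2 == 0:
        n += 1
    n = max(n, 5)
    if n > params.max_grid_points:
        raise GridSizeError(
            f"grid of {n}^3 points exceeds the cap of "
            f"{params.max_grid_points}^3; reduce scale or raise the cap"
        )
    h = 1.0 / params.scale
    origin = centre - 0.5 * (n - 1) * h
    return GridSpec(n=n, scale=params.scale, origin=tuple(origin))
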