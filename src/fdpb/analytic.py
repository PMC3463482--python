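"""Closed-form electrostatics for the three built-in validation systems.

These are the benchmark geometries every grid code in this field is checked
against:

* a charged low-dielectric sphere in a high-dielectric medium (Born ion);
* two point charges inside a spherical low-dielectric cavity (the Kirkwood /
  Tanford two-charge problem), solved by a Legendre series;
* a charged dielectric sphere near a planar interface between two
  semi-infinite dielectric regions (image-charge solution).

All energies are returned in kT, all lengths are in Å and charges in e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import DEFAULT_CONSTANTS, PhysicalConstants, coulomb_prefactor

__all__ = [
    "BornSystem",
    "TwoChargeSystem",
    "TwoChargeBreakdown",
    "PlanarInterfaceSystem",
    "born_solvation",
    "legendre_p",
    "two_charge_energy",
    "planar_interface_energy",
    "planar_interface_potential",
]

#: relative tail threshold and hard cap for the Legendre series
SERIES_RTOL = 1.0e-12
SERIES_CAP = 10_000


@dataclass(frozen=True)
class BornSystem:
    """Charged sphere of radius r (Å) and charge Q (e) moved from a uniform
    eps_in medium into an eps_out solvent."""

    charge: float = 10.0
    radius: float = 1.0
    eps_in: float = 4.0
    eps_out: float = 80.0

    def __post_init__(self) -> None:
        if not self.radius > 0.0:
            raise ValueError("Born radius must be > 0")
        if self.eps_in < 1.0 or self.eps_out < 1.0:
            raise ValueError("permittivities must be >= 1")


def born_solvation(
    system: BornSystem, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Born electrostatic solvation energy in kT.

    dG = -(Q^2 C_u / 2r) (1/eps_in - 1/eps_out); negative whenever the
    solvent permittivity exceeds the interior one.
    """
    cu = coulomb_prefactor(constants)
    s = system
    return -(s.charge**2 * cu / (2.0 * s.radius)) * (1.0 / s.eps_in - 1.0 / s.eps_out)


def legendre_p(n: int, x: float) -> float:
    """Legendre polynomial P_n(x) for |x| <= 1 via the Bonnet recurrence."""
    if n < 0:
        raise ValueError("order must be >= 0")
    if abs(x) > 1.0:
        raise ValueError("argument must lie in [-1, 1]")
    if n == 0:
        return 1.0
    p_prev, p = 1.0, x
    for k in range(1, n):
        p_prev, p = p, ((2 * k + 1) * x * p - k * p_prev) / (k + 1)
    return p


@dataclass(frozen=True)
class TwoChargeSystem:
    """Two point charges in a spherical cavity of radius b (Å).

    Charge i sits at radial distance R_i and polar angle theta_i (the problem
    is planar); each carries an atom radius r used only for the geometric
    validity check R + r < b.
    """

    cavity_radius: float = 10.0
    r_i: float = 5.0 * math.sqrt(2.0)
    r_j: float = 5.0 * math.sqrt(2.0)
    theta_i: float = math.pi / 4.0
    theta_j: float = 3.0 * math.pi / 4.0
    q_i: float = 10.0
    q_j: float = 10.0
    atom_radius: float = 1.0
    eps_in: float = 2.0
    eps_out: float = 80.0

    def __post_init__(self) -> None:
        if not self.cavity_radius > 0.0:
            raise ValueError("cavity radius must be > 0")
        if self.r_i + self.atom_radius >= self.cavity_radius or (
            self.r_j + self.atom_radius >= self.cavity_radius
        ):
            raise ValueError("atoms must lie strictly inside the cavity")
        if self.eps_in < 1.0 or self.eps_out < 1.0:
            raise ValueError("permittivities must be >= 1")

    @property
    def separation(self) -> float:
        """R_ij by the law of cosines."""
        c = math.cos(self.theta_i - self.theta_j)
        return math.sqrt(self.r_i**2 + self.r_j**2 - 2.0 * self.r_i * self.r_j * c)


@dataclass(frozen=True)
class TwoChargeBreakdown:
    coulombic: float
    pairwise_polarization: float
    self_i: float
    self_j: float
    n_terms: int

    @property
    def total(self) -> float:
        return self.coulombic + self.pairwise_polarization + self.self_i + self.self_j

    @property
    def reaction_field(self) -> float:
        """Everything but the direct Coulomb term (the solvation part)."""
        return self.pairwise_polarization + self.self_i + self.self_j


def _series_sum(value_fn, n_max: Optional[int]) -> tuple[float, int]:
    """Sum value_fn(n) until the relative tail drops below SERIES_RTOL.

    Individual terms may vanish by symmetry (odd Legendre polynomials at
    x = 0), so three consecutive sub-threshold terms are required before the
    geometric tail is declared negligible.
    """
    total = 0.0
    cap = n_max if n_max is not None else SERIES_CAP
    n = 0
    small_streak = 0
    while n <= cap:
        term = value_fn(n)
        total += term
        if n_max is None and n > 0:
            if abs(term) < SERIES_RTOL * max(abs(total), 1e-300):
                small_streak += 1
                if small_streak >= 3:
                    break
            else:
                small_streak = 0
        n += 1
    return total, n


def two_charge_energy(
    system: TwoChargeSystem,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    n_max: Optional[int] = None,
) -> TwoChargeBreakdown:
    """Four-term series energy of the two-charge cavity system, in kT.

    dG = dG_coul + dG_pol + dG_self,i + dG_self,j with the series
    coefficients

        B_n(Ra, Rb) = (Ra Rb)^n / b^(2n+1)
                      * (n+1)(eps_in - eps_out) / [(n+1) eps_out + n eps_in]

    The pairwise polarization sums B_n(R_i, R_j) P_n(cos(theta_i - theta_j));
    each self term uses B_n(R, R) with a 1/2 prefactor.  In ``auto`` mode
    (n_max None) the series is extended until the relative tail is below
    1e-12 (geometric decay is guaranteed since R_i R_j / b^2 < 1).
    """
    s = system
    cu = coulomb_prefactor(constants)
    ei, eo, b = s.eps_in, s.eps_out, s.cavity_radius

    def bn(n: int, ra: float, rb: float) -> float:
        return (
            (ra * rb / (b * b)) ** n
            / b
            * (n + 1)
            * (ei - eo)
            / ((n + 1) * eo + n * ei)
        )

    rij = s.separation
    if rij == 0.0:
        raise ValueError("charges are coincident; pairwise terms diverge")
    coul = cu * s.q_i * s.q_j / (ei * rij)
    x = math.cos(s.theta_i - s.theta_j)
    pol, used = _series_sum(lambda n: bn(n, s.r_i, s.r_j) * legendre_p(n, x), n_max)
    self_i, _ = _series_sum(lambda n: bn(n, s.r_i, s.r_i), n_max)
    self_j, _ = _series_sum(lambda n: bn(n, s.r_j, s.r_j), n_max)
    return TwoChargeBreakdown(
        coulombic=coul,
        pairwise_polarization=cu * s.q_i * s.q_j / ei * pol,
        self_i=cu * s.q_i**2 / (2.0 * ei) * self_i,
        self_j=cu * s.q_j**2 / (2.0 * ei) * self_j,
        n_terms=used,
    )


@dataclass(frozen=True)
class PlanarInterfaceSystem:
    """Charged eps1-sphere near the planar boundary between two half-spaces.

    The half-space at signed distance d < 0 has permittivity eps1, the one at
    d > 0 has eps2 > eps1.  The solute sphere (radius r, permittivity eps1,
    central charge Q) sits at signed distance d from the interface; the
    closed form below holds only while the sphere does not straddle the
    interface (|d| > r).
    """

    eps1: float = 2.0
    eps2: float = 80.0
    radius: float = 2.0
    charge: float = 1.0
    distance: float = 6.0

    def __post_init__(self) -> None:
        if self.eps1 < 1.0 or self.eps2 < 1.0:
            raise ValueError("permittivities must be >= 1")
        if not self.eps2 > self.eps1:
            raise ValueError("eps2 must exceed eps1")
        if not self.radius > 0.0:
            raise ValueError("sphere radius must be > 0")
        if abs(self.distance) <= self.radius:
            raise ValueError(
                "sphere intersects both regions (|d| <= r); the closed form "
                "is not valid there"
            )


def planar_interface_energy(
    system: PlanarInterfaceSystem, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Solvation energy (kT) of the sphere at signed distance d.

    d > r  (sphere in the eps2 region):
        C_u Q^2/(2r) (1/eps2 - 1/eps1)
        + C_u (eps2-eps1)/(eps2+eps1) * Q^2 / (4 eps2 d)
    d < -r (sphere back in its native eps1 region):
        C_u (eps2-eps1)/(eps1+eps2) * Q^2 / (4 eps1 d)

    The reference state is the sphere in an infinite eps1 medium, so the
    energy vanishes as d -> -inf.
    """
    s = system
    cu = coulomb_prefactor(constants)
    q2 = s.charge**2
    contrast = (s.eps2 - s.eps1) / (s.eps2 + s.eps1)
    if s.distance > s.radius:
        born = cu * q2 / (2.0 * s.radius) * (1.0 / s.eps2 - 1.0 / s.eps1)
        image = cu * contrast * q2 / (4.0 * s.eps2 * s.distance)
        return born + image
    return cu * contrast * q2 / (4.0 * s.eps1 * s.distance)


def planar_interface_potential(
    charge: float,
    charge_pos: np.ndarray,
    eps1: float,
    eps2: float,
    points: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Exact potential (kT/e) of a point charge near the planar interface.

    The interface is the plane x = 0 with eps1 at x < 0 and eps2 at x > 0.
    This is the textbook image-charge solution; it ignores the finite solute
    sphere, which only perturbs the far field at O((r/d)^3), and is used to
    set accurate boundary values for the numerical planar-interface scenes.
    """
    cu = coulomb_prefactor(constants)
    pos = np.asarray(charge_pos, dtype=float)
    pts = np.asarray(points, dtype=float)
    x0 = pos[0]
    eps_src, eps_other = (eps2, eps1) if x0 > 0 else (eps1, eps2)
    mirror = pos.copy()
    mirror[0] = -x0
    k_img = (eps_src - eps_other) / (eps_src + eps_other)
    d_src = np.linalg.norm(pts - pos, axis=-1)
    d_img = np.linalg.norm(pts - mirror, axis=-1)
    same_side = (pts[..., 0] > 0) == (x0 > 0)
    with np.errstate(divide="ignore"):
        phi_same = cu * charge / eps_src * (1.0 / d_src + k_img / d_img)
        phi_other = cu * charge * 2.0 / (eps_src + eps_other) / d_src
    return np.where(same_side, phi_same, phi_other)
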