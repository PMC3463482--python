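"""Deterministic scene generators for the built-in validation systems.

Every test system used in this package is generated here from parameters —
no structure downloads are needed.  The three analytic geometries mirror the
closed forms in :mod:`fdpb.analytic`; the random cloud stands in for
protein-sized solutes in conservation, symmetry and grid-convergence
property checks.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .analytic import planar_interface_potential
from .core import (
    Atom,
    BoundaryCondition,
    DielectricScene,
    GridSpec,
    RunParameters,
    SurfaceMode,
)
from .mapping import Box, Sphere

__all__ = [
    "make_born_sphere",
    "make_two_charge_cavity",
    "make_planar_interface",
    "make_random_cloud",
    "scene_to_files",
]


def make_born_sphere(
    charge: float = 10.0,
    radius: float = 1.0,
    eps_in: float = 4.0,
    eps_out: float = 80.0,
    scale: float = 2.0,
    perfil: float = 70.0,
    **param_overrides,
) -> DielectricScene:
    """Single charged sphere at the cube centre (the Born ion)."""
    if not radius > 0.0:
        raise ValueError("radius must be > 0")
    # the Born boundary is the sphere itself: no probe rolling
    param_overrides.setdefault("surface", SurfaceMode.VDW)
    params = RunParameters(
        scale=scale,
        perfil=perfil,
        eps_interior={0: eps_in},
        eps_solvent=eps_out,
        boundary_condition=BoundaryCondition.COULOMBIC,
        **param_overrides,
    )
    atom = Atom(position=(0.0, 0.0, 0.0), radius=radius, charge=charge, name="O",
                residue_name="SPH")
    return DielectricScene(atoms=[atom], objects=[], params=params)


def make_two_charge_cavity(
    q_i: float = 10.0,
    q_j: float = 10.0,
    r_pos: float = 5.0 * math.sqrt(2.0),
    theta_i: float = math.pi / 4.0,
    theta_j: float = 3.0 * math.pi / 4.0,
    cavity_radius: float = 10.0,
    atom_radius: float = 1.0,
    eps_in: float = 2.0,
    eps_out: float = 80.0,
    scale: float = 2.0,
    perfil: float = 70.0,
    **param_overrides,
) -> DielectricScene:
    """Two charged atoms inside a spherical low-dielectric cavity.

    The cavity is a sphere object carrying the interior permittivity; the
    atoms sit in the xy-plane at polar coordinates (r_pos, theta) and share
    the cavity's region, so their own radii do not alter the dielectric map.
    """
    for r in (r_pos,):
        if r + atom_radius >= cavity_radius:
            raise ValueError("atoms must lie strictly inside the cavity")
    param_overrides.setdefault("surface", SurfaceMode.VDW)
    params = RunParameters(
        scale=scale,
        perfil=perfil,
        eps_interior={0: eps_in},
        eps_solvent=eps_out,
        boundary_condition=BoundaryCondition.COULOMBIC,
        **param_overrides,
    )
    cavity = Sphere(centre=(0.0, 0.0, 0.0), radius=cavity_radius, region_id=0)
    atoms = []
    for q, theta, tag in ((q_i, theta_i, "QI"), (q_j, theta_j, "QJ")):
        pos = (r_pos * math.cos(theta), r_pos * math.sin(theta), 0.0)
        atoms.append(
            Atom(position=pos, radius=atom_radius, charge=q, name=tag,
                 residue_name="CAV")
        )
    return DielectricScene(atoms=atoms, objects=[cavity], params=params)


def make_planar_interface(
    distance: float,
    eps1: float = 2.0,
    eps2: float = 80.0,
    radius: float = 2.0,
    charge: float = 1.0,
    scale: float = 2.0,
    edge: float = 36.0,
    **param_overrides,
) -> DielectricScene:
    """Charged eps1-sphere near a planar dielectric interface.

    The semi-infinite eps1 half-space (x < 0) is realised as a box object
    spanning the cube; eps2 is the solvent on the other side.  The cube is
    pinned to ``edge`` Å centred on the interface so the plane passes through
    grid nodes, and the exact image-charge potential supplies the boundary
    values (the finite cube then approximates the infinite domain well).
    The sphere must not straddle the interface (|d| > r).
    """
    if abs(distance) <= radius:
        raise ValueError("sphere straddles the interface (|d| <= r)")
    param_overrides.setdefault("surface", SurfaceMode.VDW)
    params = RunParameters(
        scale=scale,
        eps_interior={0: eps1, 1: eps1},
        eps_solvent=eps2,
        boundary_condition=BoundaryCondition.COULOMBIC,
        **param_overrides,
    )
    n = int(math.ceil(edge * scale + 1.0 - 1e-12))
    if n % 2 == 0:
        n += 1
    h = 1.0 / scale
    half = 0.5 * (n - 1) * h
    grid = GridSpec(n=n, scale=scale, origin=(-half, -half, -half))
    if abs(distance) + radius > half - 2.0 * h:
        raise ValueError("sphere too close to the cube boundary; enlarge edge")
    span = 4.0 * half
    left = Box(centre=(-span / 2.0, 0.0, 0.0), edges=(span, 2.0 * span, 2.0 * span),
               region_id=1)
    atom = Atom(position=(distance, 0.0, 0.0), radius=radius, charge=charge,
                name="Q", residue_name="INT")
    pos = np.array([distance, 0.0, 0.0])

    def boundary(points: np.ndarray) -> np.ndarray:
        return planar_interface_potential(charge, pos, eps1, eps2, points)

    return DielectricScene(
        atoms=[atom],
        objects=[left],
        params=params,
        boundary_values=boundary,
        grid_override=grid,
    )


def make_random_cloud(
    n_atoms: int,
    box: float = 12.0,
    charge_range: tuple[float, float] = (-1.0, 1.0),
    radius_range: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    eps_in: float = 4.0,
    eps_out: float = 80.0,
    scale: float = 2.0,
    perfil: float = 70.0,
    **param_overrides,
) -> DielectricScene:
    """Seeded random atom cloud in a cubic box of the given edge (Å).

    Identical arguments give a bit-identical scene.  Used for conservation,
    symmetry, plateau and runtime-trend properties where an irregular,
    protein-like charge distribution is wanted without external data.
    """
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    # vdW surface: the lattice SES construction carries an O(h) surface bias
    # that would dominate grid-convergence properties this fixture serves
    param_overrides.setdefault("surface", SurfaceMode.VDW)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-box / 2.0, box / 2.0, size=(n_atoms, 3))
    q = rng.uniform(*charge_range, size=n_atoms)
    r = rng.uniform(*radius_range, size=n_atoms)
    params = RunParameters(
        scale=scale,
        perfil=perfil,
        eps_interior={0: eps_in},
        eps_solvent=eps_out,
        boundary_condition=BoundaryCondition.COULOMBIC,
        **param_overrides,
    )
    atoms = [
        Atom(position=tuple(p), radius=float(ri), charge=float(qi), name=f"C{i}",
             residue_name="CLD", residue_number=i + 1)
        for i, (p, qi, ri) in enumerate(zip(pos, q, r))
    ]
    return DielectricScene(atoms=atoms, objects=[], params=params)


def scene_to_files(scene: DielectricScene, directory: Path | str,
                   stem: str = "scene") -> tuple[Path, Path]:
    """Serialize a scene as PQR + parameter file; returns the two paths."""
    from .io import write_pqr

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pqr = directory / f"{stem}.pqr"
    prm = directory / f"{stem}.prm"
    write_pqr(scene.atoms, pqr)
    p = scene.params
    lines = [
        f"in={pqr.name}",
        f"scale={p.scale:g}",
        f"perfil={p.perfil:g}",
        f"indi={p.eps_interior.get(0, 4.0):g}",
        f"exdi={p.eps_solvent:g}",
        f"prbrad={p.probe_radius:g}",
        f"ionrad={p.ion_exclusion_radius:g}",
        f"tol={p.tolerance:g}",
        f"maxit={p.max_iterations}",
        f"bndcon={p.boundary_condition.value}",
        f"equation={p.equation.value}",
        f"surface={p.surface.value}",
        f"averaging={p.dielectric_averaging.value}",
    ]
    for region, eps in sorted(p.eps_interior.items()):
        if region != 0:
            lines.append(f"eps={region}:{eps:g}")
    for s in p.salts:
        lines.append(f"salt={s.concentration:g}:{s.valence}")
    for o in scene.objects:
        lines.append("object=" + _object_declaration(o))
    prm.write_text("\n".join(lines) + "\n")
    return pqr, prm


def _object_declaration(o) -> str:
    if isinstance(o, Sphere):
        c = o.centre
        return f"sphere;{c[0]:g};{c[1]:g};{c[2]:g};{o.radius:g};{o.region_id};{o.charge:g}"
    if isinstance(o, Box):
        c, e = o.centre, o.edges
        return (
            f"box;{c[0]:g};{c[1]:g};{c[2]:g};{e[0]:g};{e[1]:g};{e[2]:g};"
            f"{o.region_id};{o.charge:g}"
        )
    from .mapping import Cone, Cylinder

    if isinstance(o, Cylinder):
        a, b = o.end_a, o.end_b
        return (
            f"cylinder;{a[0]:g};{a[1]:g};{a[2]:g};{b[0]:g};{b[1]:g};{b[2]:g};"
            f"{o.radius:g};{o.region_id};{o.charge:g}"
        )
    if isinstance(o, Cone):
        a, b = o.apex, o.base_centre
        return (
            f"cone;{a[0]:g};{a[1]:g};{a[2]:g};{b[0]:g};{b[1]:g};{b[2]:g};"
            f"{o.base_radius:g};{o.region_id};{o.charge:g}"
        )
    raise TypeError(f"cannot serialize object of type {type(o).__name__}")
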