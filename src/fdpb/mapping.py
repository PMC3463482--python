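"""Rasterization of atoms and geometric objects onto the lattice.

Produces the three staggered midpoint permittivity arrays required by the
flux-conservative 7-point stencil, the ion-accessibility (Stern exclusion)
mask, and the trilinearly distributed node charge array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import Atom, DielectricAveraging, GridSpec, RunParameters, SurfaceMode

__all__ = [
    "GeometricObject",
    "Sphere",
    "Box",
    "Cylinder",
    "Cone",
    "DielectricMap",
    "build_dielectric_map",
    "build_ion_mask",
    "distribute_charges",
    "parse_object_declaration",
]


class GeometricObject:
    """Base for exact-membership solids with a region label and optional charge.

    Subclasses implement ``contains(points)`` (exact point membership, surface
    points count as interior) and ``bounding_box()``.
    """

    kind = "object"
    region_id: int
    charge: float

    def contains(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:  # pragma: no cover
        raise NotImplementedError


@dataclass
class Sphere(GeometricObject):
    centre: tuple[float, float, float]
    radius: float
    region_id: int = 0
    charge: float = 0.0
    kind = "sphere"

    def __post_init__(self) -> None:
        if not self.radius > 0.0:
            raise ValueError("sphere radius must be > 0")
        self.centre = tuple(float(x) for x in self.centre)

    def contains(self, points: np.ndarray) -> np.ndarray:
        d2 = np.sum((np.asarray(points) - np.asarray(self.centre)) ** 2, axis=-1)
        return d2 <= self.radius**2

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.centre)
        return c - self.radius, c + self.radius


@dataclass
class Box(GeometricObject):
    """Axis-aligned unless a 3x3 rotation matrix is supplied."""

    centre: tuple[float, float, float]
    edges: tuple[float, float, float]
    region_id: int = 0
    charge: float = 0.0
    rotation: Optional[np.ndarray] = None
    kind = "box"

    def __post_init__(self) -> None:
        self.centre = tuple(float(x) for x in self.centre)
        self.edges = tuple(float(x) for x in self.edges)
        if not all(e > 0.0 for e in self.edges):
            raise ValueError("box edge lengths must be > 0")
        if self.rotation is not None:
            R = np.asarray(self.rotation, dtype=float)
            if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
                raise ValueError("rotation must be a 3x3 orthogonal matrix")
            self.rotation = R

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points) - np.asarray(self.centre)
        if self.rotation is not None:
            rel = rel @ self.rotation  # body frame
        half = 0.5 * np.asarray(self.edges)
        return np.all(np.abs(rel) <= half, axis=-1)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        half = 0.5 * np.asarray(self.edges)
        if self.rotation is not None:
            half = np.abs(self.rotation) @ half
        c = np.asarray(self.centre)
        return c - half, c + half


@dataclass
class Cylinder(GeometricObject):
    """Finite right circular cylinder between two axis endpoints."""

    end_a: tuple[float, float, float]
    end_b: tuple[float, float, float]
    radius: float
    region_id: int = 0
    charge: float = 0.0
    kind = "cylinder"

    def __post_init__(self) -> None:
        self.end_a = tuple(float(x) for x in self.end_a)
        self.end_b = tuple(float(x) for x in self.end_b)
        if not self.radius > 0.0:
            raise ValueError("cylinder radius must be > 0")
        if np.allclose(self.end_a, self.end_b):
            raise ValueError("cylinder endpoints must differ")

    def contains(self, points: np.ndarray) -> np.ndarray:
        a = np.asarray(self.end_a)
        axis = np.asarray(self.end_b) - a
        length = float(np.linalg.norm(axis))
        u = axis / length
        rel = np.asarray(points) - a
        t = rel @ u
        radial2 = np.sum(rel * rel, axis=-1) - t**2
        return (t >= 0.0) & (t <= length) & (radial2 <= self.radius**2)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        a, b = np.asarray(self.end_a), np.asarray(self.end_b)
        return np.minimum(a, b) - self.radius, np.maximum(a, b) + self.radius


@dataclass
class Cone(GeometricObject):
    """Finite right cone from apex to a base disc (base included)."""

    apex: tuple[float, float, float]
    base_centre: tuple[float, float, float]
    base_radius: float
    region_id: int = 0
    charge: float = 0.0
    kind = "cone"

    def __post_init__(self) -> None:
        self.apex = tuple(float(x) for x in self.apex)
        self.base_centre = tuple(float(x) for x in self.base_centre)
        if not self.base_radius > 0.0:
            raise ValueError("cone base radius must be > 0")
        if np.allclose(self.apex, self.base_centre):
            raise ValueError("cone apex and base centre must differ")

    def contains(self, points: np.ndarray) -> np.ndarray:
        a = np.asarray(self.apex)
        axis = np.asarray(self.base_centre) - a
        length = float(np.linalg.norm(axis))
        u = axis / length
        rel = np.asarray(points) - a
        t = rel @ u
        radial2 = np.sum(rel * rel, axis=-1) - t**2
        with np.errstate(invalid="ignore"):
            rmax = self.base_radius * t / length
        return (t >= 0.0) & (t <= length) & (radial2 <= rmax**2)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        a, b = np.asarray(self.apex), np.asarray(self.base_centre)
        return np.minimum(a, b) - self.base_radius, np.maximum(a, b) + self.base_radius


@dataclass
class DielectricMap:
    """Staggered midpoint permittivities.

    ``eps_x[i, j, k]`` is the permittivity halfway between nodes (i, j, k) and
    (i+1, j, k); likewise eps_y and eps_z along the other axes.
    """

    grid: GridSpec
    eps_x: np.ndarray  # (N-1, N, N)
    eps_y: np.ndarray  # (N, N-1, N)
    eps_z: np.ndarray  # (N, N, N-1)

    def values(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.eps_x, self.eps_y, self.eps_z

    def interior_midpoint_count(self, eps_solvent: float) -> int:
        """Number of midpoints assigned a non-solvent permittivity."""
        return int(sum(np.count_nonzero(a != eps_solvent) for a in self.values()))


def _midpoint_axes(grid: GridSpec, axis: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinate arrays (broadcastable) of the midpoint lattice along axis."""
    h = grid.spacing
    coords = []
    for dim in range(3):
        c = grid.axis(dim)
        if dim == axis:
            c = c[:-1] + 0.5 * h
        coords.append(c)
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    return x, y, z


def _region_eps(params: RunParameters, region_id: int) -> float:
    try:
        return float(params.eps_interior[region_id])
    except KeyError:
        raise ValueError(
            f"region {region_id} has no declared permittivity in eps_interior"
        ) from None


def _sphere_window(grid: GridSpec, centre: np.ndarray, radius: float, shape) -> tuple[slice, ...]:
    """Index window of a lattice (node or midpoint) overlapping a sphere."""
    h = grid.spacing
    slices = []
    for dim in range(3):
        lo = int(math.floor((centre[dim] - radius - grid.origin[dim]) / h)) - 1
        hi = int(math.ceil((centre[dim] + radius - grid.origin[dim]) / h)) + 2
        slices.append(slice(max(lo, 0), min(hi, shape[dim])))
    return tuple(slices)


def _assign_spheres_on_lattice(
    values: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    grid: GridSpec,
    centres: np.ndarray,
    radii: np.ndarray,
    fill: np.ndarray,
) -> None:
    """Set ``values`` to ``fill[i]`` inside sphere i, in order (later wins)."""
    x, y, z = coords
    for c, r, v in zip(centres, radii, fill):
        if r <= 0.0:
            continue
        win = _sphere_window(grid, c, r, values.shape)
        xs, ys, zs = x[win[0]], y[:, win[1]], z[:, :, win[2]]
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        values[win][d2 <= r * r] = v


def _sphere_edge_fraction(
    frac: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    grid: GridSpec,
    axis: int,
    centre: np.ndarray,
    radius: float,
) -> None:
    """Max-combine into ``frac`` the fraction of each edge inside a sphere.

    Each midpoint of the staggered lattice along ``axis`` represents the edge
    of length h centred on it; the in-sphere fraction is the measure of the
    segment-sphere intersection, found from the quadratic along the edge.
    """
    if radius <= 0.0:
        return
    h = grid.spacing
    half = 0.5 * h
    # pad the window by the half-edge so partially cut edges are included
    win = _sphere_window(grid, centre, radius + half, frac.shape)
    x, y, z = coords
    xs, ys, zs = x[win[0]], y[:, win[1]], z[:, :, win[2]]
    rel = [xs - centre[0], ys - centre[1], zs - centre[2]]
    du = rel[axis]  # signed distance of edge centre to sphere centre, along axis
    rho2 = sum(r * r for r in rel) - du * du
    disc = radius * radius - rho2
    valid = disc > 0.0
    root = np.sqrt(np.where(valid, disc, 0.0))
    # intersection interval along the edge, in units of h, relative to centre
    t_lo = np.maximum(-du - root, -half)
    t_hi = np.minimum(-du + root, half)
    f = np.where(valid, np.clip(t_hi - t_lo, 0.0, h) / h, 0.0)
    np.maximum(frac[win], f, out=frac[win])


def _box_edge_fraction(
    frac: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    grid: GridSpec,
    axis: int,
    box: "Box",
) -> None:
    """Max-combine the in-box fraction of each edge (axis-aligned boxes)."""
    h = grid.spacing
    half = 0.5 * h
    x, y, z = coords
    lo = np.asarray(box.centre) - 0.5 * np.asarray(box.edges)
    hi = np.asarray(box.centre) + 0.5 * np.asarray(box.edges)
    rel = [x - box.centre[0], y - box.centre[1], z - box.centre[2]]
    inside_perp = np.ones(frac.shape, dtype=bool)
    for dim, r in enumerate(rel):
        if dim != axis:
            inside_perp = inside_perp & (np.abs(r) <= 0.5 * box.edges[dim])
    centre_u = (x, y, z)[axis]
    t_lo = np.maximum(lo[axis] - centre_u, -half)
    t_hi = np.minimum(hi[axis] - centre_u, half)
    f = np.where(inside_perp, np.clip(t_hi - t_lo, 0.0, h) / h, 0.0)
    np.maximum(frac, np.broadcast_to(f, frac.shape), out=frac)


def _ses_interior(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    grid: GridSpec,
    atoms: Sequence[Atom],
    probe: float,
    shape: tuple[int, ...],
) -> np.ndarray:
    """Solvent-excluded interior of the atom union on one lattice.

    Two-pass distance construction: inflate every atom by the probe radius,
    then keep the points at least one probe radius from the probe-accessible
    (non-inflated) region.  Depth inside a single inflated sphere is known in
    closed form and is used exactly (this also guarantees vdW interior is a
    subset of the SES interior); reentrant crevice points between spheres are
    recovered by a lattice distance transform, tightened by the half cell
    diagonal so the lattice sampling cannot inflate the surface outward.
    """
    inflated = np.zeros(shape, dtype=bool)
    depth = np.full(shape, -np.inf)
    x, y, z = coords
    for a in atoms:
        if a.radius <= 0.0:
            continue
        r = a.radius + probe
        win = _sphere_window(grid, a.xyz, r, shape)
        xs, ys, zs = x[win[0]], y[:, win[1]], z[:, :, win[2]]
        d = np.sqrt(
            (xs - a.position[0]) ** 2
            + (ys - a.position[1]) ** 2
            + (zs - a.position[2]) ** 2
        )
        inflated[win] |= d <= r
        np.maximum(depth[win], r - d, out=depth[win])
    if probe == 0.0 or not inflated.any():
        return inflated
    h = grid.spacing
    dist = ndimage.distance_transform_edt(inflated, sampling=(h, h, h))
    crevice = dist - 0.5 * math.sqrt(3.0) * h >= probe
    return inflated & ((depth >= probe) | crevice)


def build_dielectric_map(
    atoms: Sequence[Atom],
    objects: Sequence[GeometricObject],
    grid: GridSpec,
    params: RunParameters,
    surface: Optional[SurfaceMode] = None,
) -> DielectricMap:
    """Assign a permittivity to every midpoint of the staggered lattices.

    In ``vdw`` mode a midpoint is interior iff it lies inside an atom sphere
    or object; in ``ses`` mode the atom union is replaced by its
    solvent-excluded volume (probe-rolled).  Atoms are painted first, objects
    after, each in declaration order, so later declarations win overlaps.
    No interface averaging is applied: each midpoint carries exactly one of
    the declared permittivities.
    """
    surface = surface or params.surface
    if params.probe_radius < 0.0:
        raise ValueError("probe_radius must be >= 0")
    # validate regions up-front
    for a in atoms:
        _region_eps(params, a.region_id)
    for o in objects:
        _region_eps(params, o.region_id)

    n = grid.n
    shapes = [(n - 1, n, n), (n, n - 1, n), (n, n, n - 1)]
    lattices = []
    probe = params.probe_radius if surface is SurfaceMode.SES else 0.0
    harmonic = (
        surface is SurfaceMode.VDW
        and params.dielectric_averaging is DielectricAveraging.HARMONIC
    )
    centres = np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)
    for axis in range(3):
        values = np.full(shapes[axis], params.eps_solvent, dtype=float)
        coords = _midpoint_axes(grid, axis)
        if harmonic:
            values = _harmonic_lattice(
                atoms, objects, grid, params, axis, coords, shapes[axis]
            )
        else:
            if atoms:
                if surface is SurfaceMode.SES and probe > 0.0:
                    interior = _ses_interior(coords, grid, atoms, probe, shapes[axis])
                    # label by inflated-sphere ownership, declaration order wins
                    radii = np.array([a.radius + probe for a in atoms])
                    eps = np.array([_region_eps(params, a.region_id) for a in atoms])
                    label = np.full(shapes[axis], params.eps_solvent, dtype=float)
                    _assign_spheres_on_lattice(label, coords, grid, centres, radii, eps)
                    values[interior] = label[interior]
                else:
                    radii = np.array([a.radius for a in atoms])
                    eps = np.array([_region_eps(params, a.region_id) for a in atoms])
                    _assign_spheres_on_lattice(values, coords, grid, centres, radii, eps)
            if objects:
                x, y, z = coords
                pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
                for o in objects:
                    values[o.contains(pts)] = _region_eps(params, o.region_id)
        lattices.append(values)
    return DielectricMap(grid=grid, eps_x=lattices[0], eps_y=lattices[1], eps_z=lattices[2])


def _harmonic_lattice(
    atoms: Sequence[Atom],
    objects: Sequence[GeometricObject],
    grid: GridSpec,
    params: RunParameters,
    axis: int,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    shape: tuple[int, ...],
) -> np.ndarray:
    """Flux-matched midpoint permittivities for one staggered lattice.

    Each edge's interior fraction is the largest fraction covered by any one
    entity (exact for spheres and axis-aligned boxes; point membership for
    other shapes), the edge's interior permittivity is that of the
    largest-fraction entity (later declarations win ties), and the midpoint
    value is the fraction-weighted harmonic mean of interior and solvent.
    Overlaps of entities with different permittivities are resolved by this
    winner-takes-the-edge rule rather than a three-medium average.
    """
    best = np.zeros(shape)
    eps_lab = np.full(shape, params.eps_solvent)
    x, y, z = coords
    pts = None
    entities: list[tuple[float, object]] = [
        (_region_eps(params, a.region_id), a) for a in atoms
    ] + [(_region_eps(params, o.region_id), o) for o in objects]
    for eps_e, ent in entities:
        f = np.zeros(shape)
        if isinstance(ent, Atom):
            _sphere_edge_fraction(f, coords, grid, axis, ent.xyz, ent.radius)
        elif isinstance(ent, Sphere):
            _sphere_edge_fraction(
                f, coords, grid, axis, np.asarray(ent.centre), ent.radius
            )
        elif isinstance(ent, Box) and ent.rotation is None:
            _box_edge_fraction(f, coords, grid, axis, ent)
        else:
            if pts is None:
                pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
            f[ent.contains(pts)] = 1.0
        take = (f > 0.0) & (f >= best)
        eps_lab[take] = eps_e
        np.maximum(best, f, out=best)
    with np.errstate(divide="ignore"):
        mixed = 1.0 / (best / eps_lab + (1.0 - best) / params.eps_solvent)
    return np.where(best > 0.0, mixed, params.eps_solvent)


def build_ion_mask(
    atoms: Sequence[Atom],
    objects: Sequence[GeometricObject],
    grid: GridSpec,
    params: RunParameters,
) -> np.ndarray:
    """Boolean node lattice, True where bulk ions can reach.

    A node is inaccessible inside any atom inflated by the ion-exclusion
    (Stern) radius, or inside any geometric object.
    """
    n = grid.n
    accessible = np.ones((n, n, n), dtype=bool)
    x = grid.axis(0)[:, None, None]
    y = grid.axis(1)[None, :, None]
    z = grid.axis(2)[None, None, :]
    for a in atoms:
        r = a.radius + params.ion_exclusion_radius
        if r <= 0.0:
            continue
        win = _sphere_window(grid, a.xyz, r, accessible.shape)
        xs, ys, zs = x[win[0]], y[:, win[1]], z[:, :, win[2]]
        d2 = (xs - a.position[0]) ** 2 + (ys - a.position[1]) ** 2 + (zs - a.position[2]) ** 2
        accessible[win] &= d2 > r * r
    if objects:
        pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
        for o in objects:
            accessible &= ~o.contains(pts)
    return accessible


def _trilinear_add(charges: np.ndarray, grid: GridSpec, pos: np.ndarray, q, label: str) -> None:
    """Spread point charges over their 8 enclosing nodes (vectorised)."""
    n = grid.n
    f = (pos - np.asarray(grid.origin)) / grid.spacing
    if np.any(f < 1.0 - 1e-9) or np.any(f > n - 2.0 + 1e-9):
        bad = int(np.argmax(np.any((f < 1.0 - 1e-9) | (f > n - 2.0 + 1e-9), axis=-1)))
        raise ValueError(
            f"{label} {bad} lies outside the cube interior "
            "(charges must sit at least one spacing from the boundary)"
        )
    f = np.clip(f, 1.0, n - 2.0)
    i0 = np.minimum(np.floor(f).astype(int), n - 2)
    w = f - i0
    q = np.broadcast_to(np.asarray(q, dtype=float), (len(pos),))
    for dx in (0, 1):
        wx = w[:, 0] if dx else 1.0 - w[:, 0]
        for dy in (0, 1):
            wy = w[:, 1] if dy else 1.0 - w[:, 1]
            for dz in (0, 1):
                wz = w[:, 2] if dz else 1.0 - w[:, 2]
                np.add.at(
                    charges,
                    (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                    q * wx * wy * wz,
                )


def distribute_charges(
    atoms: Sequence[Atom],
    objects: Sequence[GeometricObject],
    grid: GridSpec,
) -> np.ndarray:
    """Node charge array in e; total charge is conserved exactly.

    Each point charge is split over its 8 enclosing nodes with trilinear
    weights.  A charged object is discretised by uniform sub-sampling at half
    the grid spacing and each sample is spread trilinearly.
    """
    n = grid.n
    charges = np.zeros((n, n, n), dtype=float)
    charged = [a for a in atoms if a.charge != 0.0]
    if charged:
        pos = np.array([a.position for a in charged], dtype=float)
        q = np.array([a.charge for a in charged], dtype=float)
        _trilinear_add(charges, grid, pos, q, "atom")
    for o in objects:
        if getattr(o, "charge", 0.0) == 0.0:
            continue
        lo, hi = o.bounding_box()
        step = 0.5 * grid.spacing
        axes = [np.arange(lo[d], hi[d] + step, step) for d in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        inside = o.contains(pts)
        pts = pts[inside]
        if len(pts) == 0:
            raise ValueError(f"charged {o.kind} object contains no sample points")
        _trilinear_add(charges, grid, pts, o.charge / len(pts), f"{o.kind} sample")
    return charges


def parse_object_declaration(text: str) -> GeometricObject:
    """Parse an ``object=`` declaration from a parameter file.

    Grammar (version 1), semicolon-separated, charge optional:
      sphere;cx;cy;cz;radius;region_id[;charge]
      box;cx;cy;cz;ex;ey;ez;region_id[;charge]
      cylinder;ax;ay;az;bx;by;bz;radius;region_id[;charge]
      cone;ax;ay;az;bx;by;bz;base_radius;region_id[;charge]
    """
    parts = [p.strip() for p in text.split(";")]
    kind = parts[0].lower()
    try:
        nums = [float(p) for p in parts[1:]]
        if kind == "sphere":
            (cx, cy, cz, r, reg), rest = nums[:5], nums[5:]
            return Sphere((cx, cy, cz), r, int(reg), rest[0] if rest else 0.0)
        if kind == "box":
            (cx, cy, cz, ex, ey, ez, reg), rest = nums[:7], nums[7:]
            return Box((cx, cy, cz), (ex, ey, ez), int(reg), rest[0] if rest else 0.0)
        if kind == "cylinder":
            (ax, ay, az, bx, by, bz, r, reg), rest = nums[:8], nums[8:]
            return Cylinder((ax, ay, az), (bx, by, bz), r, int(reg), rest[0] if rest else 0.0)
        if kind == "cone":
            (ax, ay, az, bx, by, bz, r, reg), rest = nums[:8], nums[8:]
            return Cone((ax, ay, az), (bx, by, bz), r, int(reg), rest[0] if rest else 0.0)
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed object declaration: {text!r}") from exc
    raise ValueError(f"unknown object kind {kind!r}")
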