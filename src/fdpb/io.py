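"""Readers and writers: PQR, PDB + charge/radius tables, parameter files,
volumetric maps (OpenDX / Gaussian CUBE) and CSV energy reports.

PQR is the primary structure format (coordinates, charges and radii in one
file); the PDB + ``.crg`` + ``.siz`` path reproduces the classic three-file
workflow where charges and radii are assigned by atom/residue-name lookup.
All external lengths are in Å; CUBE files use bohr as the format requires.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np

from .core import (
    Atom,
    BoundaryCondition,
    DielectricAveraging,
    Equation,
    GridSpec,
    RunParameters,
    SaltSpecies,
    SurfaceMode,
)
from .mapping import GeometricObject, parse_object_declaration

__all__ = [
    "read_pqr",
    "write_pqr",
    "ChargeRecord",
    "RadiusRecord",
    "read_lookup_table",
    "read_charge_radius_tables",
    "RunSetup",
    "read_parameter_file",
    "VolumeMap",
    "write_volume_map",
    "read_volume_map",
    "write_energy_report",
]

BOHR_PER_ANGSTROM = 1.0 / 0.52917721092  # CODATA-2010 bohr radius

PathOrStream = Union[str, Path, TextIO]


def _as_text_stream(source: PathOrStream, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


# ---------------------------------------------------------------------------
# PQR

def read_pqr(source: PathOrStream) -> list[Atom]:
    """Parse ATOM/HETATM records from a PQR stream or path.

    Both the whitespace-delimited and column-formatted dialects are accepted:
    the last five fields of each record are taken as x, y, z (Å), charge (e)
    and radius (Å).  Malformed numeric fields raise with the line number.
    """
    stream, close = _as_text_stream(source)
    atoms: list[Atom] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            rec = line.strip()
            if not rec or not rec.startswith(("ATOM", "HETATM")):
                continue
            fields = rec.split()
            # record name + serial + atom/residue names + resSeq + 5 numbers
            if len(fields) < 10:
                raise ValueError(f"PQR line {lineno}: too few fields ({len(fields)})")
            try:
                x, y, z, q, r = (float(v) for v in fields[-5:])
            except ValueError as exc:
                raise ValueError(
                    f"PQR line {lineno}: malformed numeric field ({exc})"
                ) from None
            name = fields[2]
            resname = fields[3]
            try:
                resnum = int(re.sub(r"[^-0-9]", "", fields[-6]) or "1")
            except ValueError:
                resnum = 1
            atoms.append(
                Atom(
                    position=(x, y, z),
                    radius=r,
                    charge=q,
                    name=name,
                    residue_name=resname,
                    residue_number=resnum,
                )
            )
    finally:
        if close:
            stream.close()
    if not atoms:
        raise ValueError("PQR input contains no ATOM/HETATM records")
    return atoms


def write_pqr(atoms: Sequence[Atom], dest: PathOrStream) -> None:
    """Write atoms as whitespace-delimited PQR records."""
    stream, close = _as_text_stream(dest, "w")
    try:
        for i, a in enumerate(atoms, start=1):
            name = a.name or "X"
            res = a.residue_name or "UNK"
            stream.write(
                f"ATOM  {i:5d} {name:<4s} {res:<4s} {a.residue_number:4d}    "
                f"{a.position[0]:10.4f}{a.position[1]:10.4f}{a.position[2]:10.4f}"
                f"{a.charge:10.4f}{a.radius:8.4f}\n"
            )
        stream.write("END\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# PDB + charge/radius lookup tables

@dataclass(frozen=True)
class ChargeRecord:
    atom_name: str
    residue_name: str = ""  # blank = wildcard
    residue_number: Optional[int] = None
    value: float = 0.0  # e


@dataclass(frozen=True)
class RadiusRecord:
    atom_name: str
    residue_name: str = ""
    residue_number: Optional[int] = None
    value: float = 0.0  # Å

    def __post_init__(self) -> None:
        if self.value < 0.0:
            raise ValueError("radius must be >= 0")


def _name_matches(pattern: str, name: str) -> bool:
    """Exact match, or prefix match when the pattern ends with '*'."""
    if pattern.endswith("*"):
        return name.upper().startswith(pattern[:-1].upper())
    return name.upper() == pattern.upper()


def _match_score(rec, atom: Atom) -> Optional[tuple[int, int]]:
    """Specificity of a table record for an atom, None if it does not match.

    Precedence (higher wins): atom+residue+number > atom+residue > exact atom
    > wildcard-pattern atom; blank residue name is a wildcard.
    """
    exact_name = not rec.atom_name.endswith("*")
    if not _name_matches(rec.atom_name, atom.name):
        return None
    score = 0
    if rec.residue_name:
        if rec.residue_name.upper() != atom.residue_name.upper():
            return None
        score += 2
    if rec.residue_number is not None:
        if rec.residue_number != atom.residue_number:
            return None
        score += 4
    if exact_name:
        score += 1
    return (score, 0)


def lookup(records, atom: Atom):
    """Best-matching record for an atom; later entries break score ties."""
    best = None
    best_key = None
    for order, rec in enumerate(records):
        s = _match_score(rec, atom)
        if s is None:
            continue
        key = (s[0], order)
        if best_key is None or key > best_key:
            best, best_key = rec, key
    return best


def read_lookup_table(source: PathOrStream, kind: str) -> list:
    """Parse a whitespace-columnar .crg/.siz table.

    Columns: atom_name [residue_name [residue_number]] value; '!' and '#'
    start comments; a '*'-suffixed atom name is a prefix wildcard and a
    residue name of '*' or absence means any residue.
    """
    cls = ChargeRecord if kind == "charge" else RadiusRecord
    stream, close = _as_text_stream(source)
    records = []
    try:
        for lineno, line in enumerate(stream, start=1):
            text = re.split(r"[!#]", line)[0].strip()
            if not text or text.lower().startswith(("atom__", "charge", "radius")):
                continue
            fields = text.split()
            if len(fields) < 2:
                raise ValueError(f"table line {lineno}: need at least name and value")
            try:
                value = float(fields[-1])
            except ValueError:
                raise ValueError(
                    f"table line {lineno}: malformed numeric value {fields[-1]!r}"
                ) from None
            name = fields[0]
            resname = ""
            resnum = None
            if len(fields) >= 3:
                resname = "" if fields[1] == "*" else fields[1]
            if len(fields) >= 4:
                try:
                    resnum = int(fields[2])
                except ValueError:
                    raise ValueError(
                        f"table line {lineno}: malformed residue number {fields[2]!r}"
                    ) from None
            records.append(
                cls(atom_name=name, residue_name=resname, residue_number=resnum, value=value)
            )
    finally:
        if close:
            stream.close()
    return records


def _read_pdb_atoms(source: Union[str, Path]) -> list[Atom]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("input", str(source))
    atoms = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    x, y, z = atom.coord
                    atoms.append(
                        Atom(
                            position=(float(x), float(y), float(z)),
                            radius=0.0,
                            charge=0.0,
                            name=atom.get_name(),
                            residue_name=residue.get_resname().strip(),
                            residue_number=residue.get_id()[1],
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError("PDB input contains no atoms")
    return atoms


def read_charge_radius_tables(
    pdb_source: Union[str, Path],
    crg_source: PathOrStream,
    siz_source: PathOrStream,
    default_radius: Optional[float] = None,
) -> list[Atom]:
    """Assign charges and radii to PDB coordinates by name lookup.

    Atoms without a charge entry get charge 0; atoms without a radius entry
    get ``default_radius`` if given, otherwise the run fails.  The number of
    defaulted atoms is reported through a warning.
    """
    coords = _read_pdb_atoms(pdb_source)
    charges = read_lookup_table(crg_source, "charge")
    radii = read_lookup_table(siz_source, "radius")
    out = []
    n_charge_miss = 0
    n_radius_miss = 0
    for a in coords:
        crec = lookup(charges, a)
        q = crec.value if crec is not None else 0.0
        if crec is None:
            n_charge_miss += 1
        rrec = lookup(radii, a)
        if rrec is None:
            n_radius_miss += 1
            if default_radius is None:
                raise ValueError(
                    f"no radius entry matches atom {a.name!r} in residue "
                    f"{a.residue_name!r} {a.residue_number} and no default given"
                )
            r = default_radius
        else:
            r = rrec.value
        out.append(
            Atom(
                position=a.position,
                radius=r,
                charge=q,
                name=a.name,
                residue_name=a.residue_name,
                residue_number=a.residue_number,
            )
        )
    if n_charge_miss or n_radius_miss:
        warnings.warn(
            f"lookup defaults applied: {n_charge_miss} atoms without charge "
            f"entry, {n_radius_miss} without radius entry",
            UserWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# parameter file

@dataclass
class RunSetup:
    """A parsed parameter file: run parameters plus scene/file declarations."""

    params: RunParameters
    input_pqr: Optional[str] = None
    input_pdb: Optional[str] = None
    input_crg: Optional[str] = None
    input_siz: Optional[str] = None
    objects: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # e.g. {"phimap": "phi.dx"}


_SCALAR_KEYS = {
    "scale",
    "perfil",
    "indi",
    "exdi",
    "prbrad",
    "ionrad",
    "tol",
    "maxit",
    "bndcon",
    "equation",
    "surface",
    "averaging",
    "in",
    "pdb",
    "crg",
    "siz",
    "energy",
    "phimap",
    "dielmap",
    "ionmap",
    "format",
}
_REPEATABLE_KEYS = {"object", "salt", "eps"}


def read_parameter_file(source: PathOrStream) -> RunSetup:
    """Parse a key=value parameter file.

    Comments start with '!' or '#'; unknown keys are rejected; repeating a
    non-repeatable key is a conflict.  Defaults: perfil 70, probe radius
    1.4 Å, tolerance 1e-4 kT/e.  ``indi`` sets the permittivity of region 0;
    additional regions are declared as ``eps=<region>:<value>``.  Salts are
    ``salt=<mol/L>:<valence>`` lines, one per species.
    """
    stream, close = _as_text_stream(source)
    seen: dict[str, str] = {}
    objects = []
    salts = []
    eps_extra: dict[int, float] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            text = re.split(r"[!#]", raw)[0].strip()
            if not text:
                continue
            if "=" not in text:
                raise ValueError(f"parameter line {lineno}: expected key=value")
            key, value = (t.strip() for t in text.split("=", 1))
            key = key.lower()
            if key in _REPEATABLE_KEYS:
                if key == "object":
                    objects.append(parse_object_declaration(value))
                elif key == "salt":
                    c, z = value.replace(",", ":").split(":")
                    salts.append(SaltSpecies(float(c), int(z)))
                else:
                    region, eps = value.replace(",", ":").split(":")
                    eps_extra[int(region)] = float(eps)
                continue
            if key not in _SCALAR_KEYS:
                raise ValueError(f"parameter line {lineno}: unknown key {key!r}")
            if key in seen:
                raise ValueError(f"parameter line {lineno}: conflicting key {key!r}")
            seen[key] = value
    finally:
        if close:
            stream.close()

    def fget(key: str, default: float) -> float:
        return float(seen[key]) if key in seen else default

    eps_interior = {0: fget("indi", 4.0)}
    eps_interior.update(eps_extra)
    kwargs = dict(
        scale=fget("scale", 2.0),
        perfil=fget("perfil", 70.0),
        eps_interior=eps_interior,
        eps_solvent=fget("exdi", 80.0),
        probe_radius=fget("prbrad", 1.4),
        ion_exclusion_radius=fget("ionrad", 2.0),
        salts=tuple(salts),
        tolerance=fget("tol", 1.0e-4),
        max_iterations=int(fget("maxit", 20000)),
    )
    if "bndcon" in seen:
        kwargs["boundary_condition"] = BoundaryCondition(seen["bndcon"].lower())
    if "equation" in seen:
        kwargs["equation"] = Equation(seen["equation"].lower())
    if "surface" in seen:
        kwargs["surface"] = SurfaceMode(seen["surface"].lower())
    if "averaging" in seen:
        kwargs["dielectric_averaging"] = DielectricAveraging(seen["averaging"].lower())
    params = RunParameters(**kwargs)
    outputs = {k: seen[k] for k in ("energy", "phimap", "dielmap", "ionmap", "format") if k in seen}
    return RunSetup(
        params=params,
        input_pqr=seen.get("in"),
        input_pdb=seen.get("pdb"),
        input_crg=seen.get("crg"),
        input_siz=seen.get("siz"),
        objects=objects,
        outputs=outputs,
    )


# ---------------------------------------------------------------------------
# volumetric maps

MAP_KINDS = ("potential", "dielectric", "ion_concentration")

#: units written into map headers per kind
_KIND_UNITS = {
    "potential": "kT/e",
    "dielectric": "relative permittivity",
    "ion_concentration": "mol/L",
}


@dataclass
class VolumeMap:
    """A scalar lattice tied to a grid; ``kind`` names the physical field."""

    grid: GridSpec
    values: np.ndarray
    kind: str = "potential"

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        n = self.grid.n
        if self.values.shape != (n, n, n):
            raise ValueError("value lattice does not match the grid")


def write_volume_map(vmap: VolumeMap, format: str, dest: PathOrStream) -> None:
    """Write an OpenDX regular-grid scalar file or a Gaussian CUBE file.

    OpenDX carries the map kind and units in '#' header comments; CUBE
    records them in its two title lines and stores origin/spacing in bohr.
    """
    if np.any(~np.isfinite(vmap.values)):
        raise ValueError("volume map contains NaN or infinite values")
    if format == "opendx":
        _write_dx(vmap, dest)
    elif format == "cube":
        _write_cube(vmap, dest)
    else:
        raise ValueError(f"unknown map format {format!r}")


def _write_dx(vmap: VolumeMap, dest: PathOrStream) -> None:
    g = vmap.grid
    n = g.n
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write(f"# kind: {vmap.kind}\n")
        stream.write(f"# units: {_KIND_UNITS[vmap.kind]}\n")
        stream.write("# lengths in angstrom\n")
        stream.write(f"object 1 class gridpositions counts {n} {n} {n}\n")
        stream.write(f"origin {g.origin[0]:.9g} {g.origin[1]:.9g} {g.origin[2]:.9g}\n")
        stream.write(f"delta {g.spacing:.9g} 0 0\n")
        stream.write(f"delta 0 {g.spacing:.9g} 0\n")
        stream.write(f"delta 0 0 {g.spacing:.9g}\n")
        stream.write(f"object 2 class gridconnections counts {n} {n} {n}\n")
        stream.write(
            f"object 3 class array type double rank 0 items {n**3} data follows\n"
        )
        flat = vmap.values.ravel(order="C")
        for i in range(0, len(flat), 3):
            stream.write(" ".join(f"{v:.9e}" for v in flat[i : i + 3]) + "\n")
        stream.write('attribute "dep" string "positions"\n')
        stream.write('object "regular positions regular connections" class field\n')
        stream.write('component "positions" value 1\n')
        stream.write('component "connections" value 2\n')
        stream.write('component "data" value 3\n')
    finally:
        if close:
            stream.close()


def _write_cube(vmap: VolumeMap, dest: PathOrStream) -> None:
    g = vmap.grid
    n = g.n
    b = BOHR_PER_ANGSTROM
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write(f"kind: {vmap.kind}; units: {_KIND_UNITS[vmap.kind]}\n")
        stream.write("volumetric map (lengths in bohr as per the CUBE format)\n")
        stream.write(
            f"{1:5d}{g.origin[0]*b:12.6f}{g.origin[1]*b:12.6f}{g.origin[2]*b:12.6f}\n"
        )
        for dim in range(3):
            step = [0.0, 0.0, 0.0]
            step[dim] = g.spacing * b
            stream.write(f"{n:5d}{step[0]:12.6f}{step[1]:12.6f}{step[2]:12.6f}\n")
        # single placeholder atom record (the CUBE format requires >= 1)
        stream.write(f"{1:5d}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        flat = vmap.values.ravel(order="C")
        for i in range(0, len(flat), 6):
            stream.write(" ".join(f"{v:15.7e}" for v in flat[i : i + 6]) + "\n")
    finally:
        if close:
            stream.close()


def read_volume_map(source: Union[str, Path], format: Optional[str] = None) -> VolumeMap:
    """Read an OpenDX or CUBE map back into a VolumeMap.

    OpenDX files are parsed with gridData; CUBE files with the reader below
    (bohr converted back to Å).  The format is inferred from the extension
    when not given.
    """
    path = Path(source)
    if format is None:
        format = "cube" if path.suffix.lower() in (".cube", ".cub") else "opendx"
    if format == "opendx":
        from gridData import Grid

        g = Grid(str(path))
        kind = _scan_kind_comments(path)
        origin = tuple(float(x) for x in g.origin)
        spacing = float(g.delta[0])
        n = g.grid.shape[0]
        spec = GridSpec(n=n, scale=1.0 / spacing, origin=origin)
        return VolumeMap(grid=spec, values=np.asarray(g.grid, dtype=float), kind=kind)
    if format == "cube":
        return _read_cube(path)
    raise ValueError(f"unknown map format {format!r}")


def _scan_kind_comments(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "kind:" in line:
                kind = line.split("kind:", 1)[1].strip()
                if kind in MAP_KINDS:
                    return kind
            if not line.startswith("#"):
                break
    return "potential"


def _read_cube(path: Path) -> VolumeMap:
    b = BOHR_PER_ANGSTROM
    with open(path) as fh:
        title = fh.readline()
        fh.readline()
        first = fh.readline().split()
        natoms = int(first[0])
        origin = tuple(float(v) / b for v in first[1:4])
        counts = []
        spacing = None
        for dim in range(3):
            rec = fh.readline().split()
            counts.append(int(rec[0]))
            step = float(rec[1 + dim]) / b
            if spacing is None:
                spacing = step
        for _ in range(abs(natoms)):
            fh.readline()
        data = np.array(fh.read().split(), dtype=float)
    n = counts[0]
    if data.size != n**3:
        raise ValueError(f"CUBE data truncated: expected {n**3} values, got {data.size}")
    kind = "potential"
    if "kind:" in title:
        cand = title.split("kind:", 1)[1].split(";")[0].strip()
        if cand in MAP_KINDS:
            kind = cand
    spec = GridSpec(n=n, scale=1.0 / spacing, origin=origin)
    return VolumeMap(grid=spec, values=data.reshape(n, n, n), kind=kind)


# ---------------------------------------------------------------------------
# energy report

def write_energy_report(report, dest: PathOrStream) -> None:
    """CSV with component,value_kT rows (deterministic byte output)."""
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write("component,value_kT\n")
        for name, value in report.rows():
            stream.write(f"{name},{value:.10g}\n")
    finally:
        if close:
            stream.close()
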