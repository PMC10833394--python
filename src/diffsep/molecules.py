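"""Molecular structures: XYZ I/O, synthetic fragment generation, rigid-body moves.

A "molecule" here is the scattering unit occupying the disordered site of a
binary substitutional crystal — it may be a single atom, an organic fragment,
or the explicit zero-atom vacancy sentinel (``Molecule.vacancy()``), whose
form factor is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formfactors import FORM_FACTORS

__all__ = [
    "Atom",
    "Molecule",
    "read_xyz",
    "write_xyz",
    "random_molecule",
    "rotate_molecule",
    "rotate_group_about_bond",
]

#: padding added to the bounding-sphere radius when a molecule's scalar
#: "size" is used (grouping, Vegard lattice constants), in angstrom.
SIZE_PADDING = 1.2

#: hard floor on interatomic separation for synthetic fragments, in angstrom.
MIN_SEPARATION = 0.9

DEFAULT_ELEMENT_POOL = ("H", "C", "N", "O", "F", "S", "Cl")


class UnsupportedElementError(ValueError):
    """Element symbol has no atomic form-factor coefficients."""


class XYZParseError(ValueError):
    """Malformed XYZ file."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol plus Cartesian position in angstrom."""

    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.element not in FORM_FACTORS:
            raise UnsupportedElementError(
                f"no form-factor coefficients for element {self.element!r}"
            )
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position {self.position}")


@dataclass(frozen=True)
class Molecule:
    """An ordered collection of atoms forming one scattering unit.

    The zero-atom vacancy sentinel is permitted and is handled explicitly by
    the scattering routines (its molecular form factor is zero everywhere).
    """

    label: str
    atoms: tuple[Atom, ...] = field(default_factory=tuple)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def is_vacancy(self) -> bool:
        return len(self.atoms) == 0

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of Cartesian coordinates in angstrom."""
        if self.is_vacancy:
            return np.zeros((0, 3))
        return np.asarray([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    @property
    def centroid(self) -> np.ndarray:
        if self.is_vacancy:
            return np.zeros(3)
        return self.coords.mean(axis=0)

    @property
    def radius(self) -> float:
        """Bounding-sphere radius about the centroid, angstrom."""
        if self.is_vacancy:
            return 0.0
        return float(np.linalg.norm(self.coords - self.centroid, axis=1).max())

    @property
    def size(self) -> float:
        """Scalar size used for grouping and Vegard's law: radius + padding."""
        return self.radius + SIZE_PADDING

    @classmethod
    def vacancy(cls, label: str = "vacancy") -> "Molecule":
        return cls(label=label, atoms=())

    @classmethod
    def from_arrays(cls, label: str, elements, coords) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        atoms = tuple(
            Atom(el, (float(x), float(y), float(z)))
            for el, (x, y, z) in zip(elements, coords, strict=True)
        )
        return cls(label=label, atoms=atoms)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Molecule":
        return Molecule.from_arrays(label or self.label, self.elements, coords)


def read_xyz(path) -> Molecule:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` rows)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise XYZParseError(f"{path}: line 1: bad atom count {lines[0]!r}") from exc
    body = lines[2 : 2 + count]
    if len(body) < count:
        raise XYZParseError(
            f"{path}: count line says {count} atoms but only {len(body)} rows present"
        )
    elements, coords = [], []
    for i, row in enumerate(body, start=3):
        parts = row.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {i}: malformed row {row!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise XYZParseError(f"{path}: line {i}: bad coordinate in {row!r}") from exc
        elements.append(parts[0])
        coords.append(xyz)
    label = lines[1].strip() or "molecule"
    return Molecule.from_arrays(label, elements, np.asarray(coords))


def write_xyz(mol: Molecule, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"{mol.n_atoms}\n{comment if comment is not None else mol.label}\n")
        for a in mol.atoms:
            x, y, z = a.position
            fh.write(f"{a.element} {x:.8f} {y:.8f} {z:.8f}\n")


class PlacementError(RuntimeError):
    """Could not place atoms at the required minimum separation."""


def random_molecule(
    seed: int,
    n_atoms_range: tuple[int, int] = (4, 24),
    element_pool=DEFAULT_ELEMENT_POOL,
    extent: float = 4.0,
) -> Molecule:
    """Generate a synthetic rigid molecular fragment.

    Atoms are drawn uniformly in a cube of half-width *extent* (angstrom) and
    rejected until every pair is at least 0.9 angstrom apart; the centroid is
    then moved to the origin.  Deterministic under *seed*.  This stands in
    for a curated fragment library: it produces form factors with realistic
    magnitude and angular structure, not chemically valid geometries.
    """
    lo, hi = n_atoms_range
    if not (1 <= lo <= hi <= 200):
        raise ValueError(f"n_atoms_range must lie within [1, 200], got {n_atoms_range}")
    if extent <= 0:
        raise ValueError("extent must be positive")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(lo, hi + 1))
    elements = [str(rng.choice(element_pool)) for _ in range(n)]
    placed: list[np.ndarray] = []
    max_attempts = 10 * n
    attempts = 0
    while len(placed) < n:
        cand = rng.uniform(-extent, extent, size=3)
        if all(np.linalg.norm(cand - p) >= MIN_SEPARATION for p in placed):
            placed.append(cand)
        else:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place {n} atoms at >= {MIN_SEPARATION} A "
                    f"separation within extent {extent} A"
                )
    coords = np.asarray(placed)
    coords -= coords.mean(axis=0)
    return Molecule.from_arrays(f"synthetic-{seed}", elements, coords)


def rotation_matrix(euler_angles) -> np.ndarray:
    """Intrinsic rotations about x, then y, then z (radians)."""
    ax, ay, az = (float(a) for a in euler_angles)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rotate_molecule(mol: Molecule, euler_angles) -> Molecule:
    """Rigidly rotate a molecule about its centroid by Euler angles (radians)."""
    if not np.all(np.isfinite(euler_angles)):
        raise ValueError("euler angles must be finite")
    if mol.is_vacancy:
        return mol
    c = mol.centroid
    rot = rotation_matrix(euler_angles)
    return mol.with_coords((mol.coords - c) @ rot.T + c)


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def rotate_group_about_bond(
    mol: Molecule,
    axis_atom_a: int,
    axis_atom_b: int,
    group_atom_indices,
    angle: float,
) -> Molecule:
    """Rotate a subset of atoms rigidly about the a->b bond axis (radians).

    Used for torsion scans, e.g. rotating a tert-butyl rotor about its C-N
    bond while the rest of the molecule stays fixed.
    """
    if axis_atom_a == axis_atom_b:
        raise IndexError("axis atoms must be distinct")
    group = list(group_atom_indices)
    if axis_atom_a in group or axis_atom_b in group:
        raise IndexError("group must not contain an axis atom")
    coords = mol.coords.copy()
    origin = coords[axis_atom_a]
    axis = coords[axis_atom_b] - origin
    if np.linalg.norm(axis) == 0:
        raise ValueError("axis atoms are coincident")
    rot = _axis_angle_matrix(axis, float(angle))
    coords[group] = (coords[group] - origin) @ rot.T + origin
    return mol.with_coords(coords)
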