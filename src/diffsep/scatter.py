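"""Reciprocal-space planes, molecular form factors and the I_FF component.

For a crystal whose single disordered site hosts molecule A or B with
concentrations m_A + m_B = 1, the form-factor component of the diffuse
scattering is

    I_FF(Q) = N * m_A * m_B * |F_A(Q) - F_B(Q)|^2

with the molecular form factor

    F(Q) = sum_i f_i(|Q|) * exp(i Q . x_i)

summed over the atoms of the molecule (f_i the atomic form factor, x_i the
Cartesian position).  Everything here is evaluated on dense square grids
representing a single reciprocal-space plane (two Miller indices varying,
the third fixed), the geometry a single-crystal experiment reconstructs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .formfactors import FORM_FACTORS, atomic_form_factor
from .molecules import Molecule, UnsupportedElementError

__all__ = [
    "reciprocal_basis",
    "PlaneDefinition",
    "ComplexFieldPlane",
    "ScatteringPlane",
    "molecular_form_factor",
    "i_ff_plane",
    "save_plane",
    "load_plane",
]


def reciprocal_basis(a, b, c, alpha=90.0, beta=90.0, gamma=90.0) -> np.ndarray:
    """Reciprocal lattice vectors (rows, 1/angstrom) with the 2*pi convention.

    Cell lengths in angstrom, angles in degrees.  Q = h b1 + k b2 + l b3 so
    that Q . a_i = 2 pi h_i.
    """
    al, be, ga = np.radians([alpha, beta, gamma])
    # direct vectors: a along x, b in xy-plane
    av = np.array([a, 0.0, 0.0])
    bv = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz = np.sqrt(max(c**2 - cx**2 - cy**2, 0.0))
    cv = np.array([cx, cy, cz])
    direct = np.vstack([av, bv, cv])
    return 2.0 * np.pi * np.linalg.inv(direct).T


@dataclass(frozen=True)
class PlaneDefinition:
    """Geometry of one square reciprocal-space plane grid.

    ``fractional_coords[i, j]`` is the (h, k, l) triple of pixel (i, j);
    ``cartesian_q`` the corresponding Q vector in 1/angstrom.  Pixel centres
    span the fractional range inclusively and symmetrically, so every pixel
    has an exact Friedel partner on centred planes.
    """

    grid_size: int
    q_max: float
    reciprocal_basis: np.ndarray  # (3, 3), rows are b1, b2, b3
    in_plane_axes: tuple[int, int]
    offset: float  # fixed index along the third axis
    fractional_coords: np.ndarray = field(repr=False)  # (n, n, 3)
    cartesian_q: np.ndarray = field(repr=False)  # (n, n, 3)

    @property
    def q_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.cartesian_q, axis=-1)

    @classmethod
    def axis_plane(
        cls,
        recip: np.ndarray,
        in_plane_axes: tuple[int, int] = (0, 1),
        offset: float = 0.0,
        grid_size: int = 256,
        q_max: float = 7.0,
    ) -> "PlaneDefinition":
        """A plane with two axes varying over [-span, span] and one fixed.

        The fractional half-range along each in-plane axis is chosen so the
        grid reaches *q_max* (1/angstrom) along that reciprocal direction.
        """
        recip = np.asarray(recip, dtype=float)
        ax0, ax1 = in_plane_axes
        spans = [q_max / np.linalg.norm(recip[ax]) for ax in (ax0, ax1)]
        u = np.linspace(-spans[0], spans[0], grid_size)
        v = np.linspace(-spans[1], spans[1], grid_size)
        return cls._from_uv(recip, in_plane_axes, offset, q_max, u, v)

    @classmethod
    def from_fractional_ranges(
        cls,
        recip: np.ndarray,
        u: np.ndarray,
        v: np.ndarray,
        in_plane_axes: tuple[int, int] = (0, 1),
        offset: float = 0.0,
    ) -> "PlaneDefinition":
        """A plane from explicit fractional coordinate vectors along each axis."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if u.size != v.size:
            raise ValueError("plane grids must be square")
        recip = np.asarray(recip, dtype=float)
        qm = float(
            max(
                np.abs(u).max() * np.linalg.norm(recip[in_plane_axes[0]]),
                np.abs(v).max() * np.linalg.norm(recip[in_plane_axes[1]]),
            )
        )
        return cls._from_uv(recip, in_plane_axes, offset, qm, u, v)

    @classmethod
    def _from_uv(cls, recip, in_plane_axes, offset, q_max, u, v):
        n = u.size
        ax0, ax1 = in_plane_axes
        (ax2,) = set(range(3)) - {ax0, ax1}
        frac = np.zeros((n, n, 3))
        uu, vv = np.meshgrid(u, v, indexing="ij")
        frac[..., ax0] = uu
        frac[..., ax1] = vv
        frac[..., ax2] = offset
        cart = frac @ recip
        return cls(
            grid_size=n,
            q_max=float(q_max),
            reciprocal_basis=recip,
            in_plane_axes=(ax0, ax1),
            offset=float(offset),
            fractional_coords=frac,
            cartesian_q=cart,
        )


@dataclass(frozen=True)
class ComplexFieldPlane:
    """A complex amplitude field F(Q) on a plane grid."""

    data: np.ndarray  # (n, n) complex
    plane: PlaneDefinition


@dataclass(frozen=True)
class ScatteringPlane:
    """A real intensity field on a plane grid, tagged by component."""

    data: np.ndarray  # (n, n) float
    plane: PlaneDefinition
    component_tag: str = "TOTAL"  # one of FF, SRO, TOTAL

    def __post_init__(self) -> None:
        if self.component_tag not in ("FF", "SRO", "TOTAL"):
            raise ValueError(f"unknown component tag {self.component_tag!r}")

    def with_data(self, data, tag: str | None = None) -> "ScatteringPlane":
        return replace(self, data=np.asarray(data, float),
                       component_tag=tag or self.component_tag)


def molecular_form_factor(mol: Molecule, plane: PlaneDefinition) -> ComplexFieldPlane:
    """F(Q) = sum_i f_i(|Q|) exp(i Q . x_i) on the plane grid.

    The vacancy sentinel returns an identically zero field.
    """
    n = plane.grid_size
    if mol.is_vacancy:
        return ComplexFieldPlane(np.zeros((n, n), dtype=complex), plane)
    missing = set(mol.elements) - set(FORM_FACTORS)
    if missing:
        raise UnsupportedElementError(f"no coefficients for {sorted(missing)}")
    qmag = plane.q_magnitude
    # per-element radial factors computed once, phases summed per atom
    f_el = {el: atomic_form_factor(FORM_FACTORS[el], qmag)
            for el in set(mol.elements)}
    field_ = np.zeros((n, n), dtype=complex)
    coords = mol.coords
    for el, x in zip(mol.elements, coords):
        phase = plane.cartesian_q @ x
        field_ += f_el[el] * np.exp(1j * phase)
    return ComplexFieldPlane(field_, plane)


def i_ff_plane(
    mol_a: Molecule,
    mol_b: Molecule,
    m_a: float,
    m_b: float,
    plane: PlaneDefinition,
    scale: float = 1.0,
) -> ScatteringPlane:
    """I_FF = N m_A m_B |F_A - F_B|^2 on the plane grid.

    *scale* is the number of unit cells N; it only sets the absolute scale
    (samples are renormalized downstream) and defaults to 1.
    """
    if not (0.0 <= m_a <= 1.0 and 0.0 <= m_b <= 1.0):
        raise ValueError("concentrations must lie in [0, 1]")
    if abs(m_a + m_b - 1.0) > 1e-9:
        raise ValueError("concentrations must sum to 1")
    if scale < 1:
        raise ValueError("scale (number of unit cells) must be >= 1")
    fa = molecular_form_factor(mol_a, plane).data
    fb = molecular_form_factor(mol_b, plane).data
    intensity = scale * m_a * m_b * np.abs(fa - fb) ** 2
    return ScatteringPlane(intensity, plane, component_tag="FF")


def save_plane(sp: ScatteringPlane, path) -> None:
    """Serialize a plane (dense grid + geometry sidecar) to a .npz container."""
    meta = {
        "q_max": sp.plane.q_max,
        "in_plane_axes": list(sp.plane.in_plane_axes),
        "offset": sp.plane.offset,
        "component_tag": sp.component_tag,
    }
    np.savez(
        path,
        data=sp.data,
        reciprocal_basis=sp.plane.reciprocal_basis,
        fractional_coords=sp.plane.fractional_coords,
        meta=np.bytes_(json.dumps(meta).encode()),
    )


def load_plane(path) -> ScatteringPlane:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        frac = z["fractional_coords"]
        recip = z["reciprocal_basis"]
        plane = PlaneDefinition(
            grid_size=frac.shape[0],
            q_max=meta["q_max"],
            reciprocal_basis=recip,
            in_plane_axes=tuple(meta["in_plane_axes"]),
            offset=meta["offset"],
            fractional_coords=frac,
            cartesian_q=frac @ recip,
        )
        return ScatteringPlane(z["data"], plane, component_tag=meta["component_tag"])
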