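"""Quantitative analysis of separated scattering components.

The short-range-order route follows the classic projection method: because
I_SRO is a cosine series over integer lattice vectors, folding a scattering
plane modulo the reciprocal lattice accumulates every period into one
reciprocal unit cell.  Low-intensity regions are excluded, a rotational
symmetry can be imposed, and the Warren-Cowley parameters are then obtained
by *linear* least squares — the model

    I(h, k) = s * [ 1 + sum_classes alpha_c * g_c(h, k) ],
    g_c(h, k) = sum_{v in orbit(c)} cos(2 pi (h n1 + k n2))

is linear in (s, s*alpha_c), and the scale s is separated by pinning the
constant (v = 0) term.

The form-factor route compares a calculated I_FF, attenuated by an
isotropic Debye-Waller factor, against a separated I_FF as a structural
model is varied (here: rigid rotation of a group about a bond), scoring
each variant by the mean squared error between normalized planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import sqrt_normalize
from .molecules import Molecule, rotate_group_about_bond
from .scatter import PlaneDefinition, ScatteringPlane, i_ff_plane

__all__ = [
    "ProjectedCell",
    "SymmetryConstraint",
    "RefinementResult",
    "DebyeWallerModel",
    "project_to_unit_cell",
    "mask_low_intensity",
    "symmetrize",
    "rotation_orbit",
    "cosine_design",
    "synthesize_cell",
    "refine_alphas",
    "dw_correct",
    "fit_b_factor",
    "rotation_scan",
]


class SingularDesignError(np.linalg.LinAlgError):
    """Refinement design matrix is rank deficient."""


@dataclass
class ProjectedCell:
    """A scattering plane folded into one reciprocal unit cell.

    Bin i covers fractional coordinate i/bins (bin centres on the lattice
    i/bins so that integer rotation matrices permute bins exactly).
    ``excluded`` marks bins with no contributing pixels or masked-out
    intensity.
    """

    values: np.ndarray  # (bins, bins) mean intensity
    counts: np.ndarray  # (bins, bins) contributing pixels
    excluded: np.ndarray  # (bins, bins) bool
    recip2: np.ndarray  # 2x2 in-plane reciprocal basis (columns/rows in A^-1)

    @property
    def bins(self) -> int:
        return self.values.shape[0]

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        g = np.arange(self.bins) / self.bins
        return np.meshgrid(g, g, indexing="ij")


@dataclass(frozen=True)
class SymmetryConstraint:
    """Refinement restrictions: rotation order and vector exclusion.

    Equivalence classes of Warren-Cowley parameters are the orbits of the
    in-plane vectors under the rotation (e.g. order 6 ties [100], [110],
    [010], ...).  Vectors with a component along the projection axis are
    excluded by default (no disorder along that axis).
    """

    rotation_order: int = 1
    exclude_nonzero_vz: bool = True

    def admits(self, v) -> bool:
        if self.exclude_nonzero_vz and len(v) > 2 and v[2] != 0:
            return False
        return True


@dataclass
class RefinementResult:
    """Refined alpha per equivalence class plus fit diagnostics."""

    alphas: dict[tuple[int, int], float]
    scale: float
    rss: float
    fitted: np.ndarray
    difference: np.ndarray
    included: np.ndarray
    classes: dict[tuple[int, int], list[tuple[int, int]]] = field(default_factory=dict)


def _in_plane_rotation(recip2: np.ndarray, order: int) -> np.ndarray:
    """Integer matrix acting on fractional (h, k) under a 2pi/order rotation.

    Valid only when the rotation is a symmetry of the in-plane reciprocal
    lattice; raises otherwise.
    """
    theta = 2.0 * np.pi / order
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    b = np.asarray(recip2, dtype=float)  # rows are b1, b2 in-plane components
    # fractional transform: q = f @ b, q' = q @ rot.T, f' = q' @ inv(b)
    m = b @ rot.T @ np.linalg.inv(b)
    mi = np.rint(m)
    if not np.allclose(m, mi, atol=1e-8):
        raise ValueError(
            f"order-{order} rotation is not a symmetry of this reciprocal lattice"
        )
    return mi.astype(int)


def project_to_unit_cell(plane: ScatteringPlane, bins: int = 64) -> ProjectedCell:
    """Fold a plane's pixels modulo one reciprocal unit cell and bin them."""
    if bins < 8:
        raise ValueError("need at least 8 bins per axis")
    ax0, ax1 = plane.plane.in_plane_axes
    h = plane.plane.fractional_coords[..., ax0].ravel()
    k = plane.plane.fractional_coords[..., ax1].ravel()
    bi = np.rint(h * bins).astype(int) % bins
    bj = np.rint(k * bins).astype(int) % bins
    values = np.zeros((bins, bins))
    counts = np.zeros((bins, bins), dtype=int)
    np.add.at(values, (bi, bj), plane.data.ravel())
    np.add.at(counts, (bi, bj), 1)
    empty = counts == 0
    with np.errstate(invalid="ignore"):
        values = np.where(empty, 0.0, values / np.maximum(counts, 1))
    recip = plane.plane.reciprocal_basis
    b1 = recip[ax0]
    b2 = recip[ax1]
    # orthonormal in-plane frame spanned by (b1, b2)
    e1 = b1 / np.linalg.norm(b1)
    e2p = b2 - (b2 @ e1) * e1
    e2 = e2p / np.linalg.norm(e2p)
    recip2 = np.array([[b1 @ e1, b1 @ e2], [b2 @ e1, b2 @ e2]])
    return ProjectedCell(values=values, counts=counts, excluded=empty, recip2=recip2)


def mask_low_intensity(cell: ProjectedCell, fraction: float = 0.05) -> ProjectedCell:
    """Exclude bins below *fraction* of the cell maximum (default 5%)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    live = ~cell.excluded
    if not live.any():
        return cell
    peak = cell.values[live].max()
    flagged = cell.excluded | (cell.values < fraction * peak)
    return ProjectedCell(cell.values.copy(), cell.counts.copy(), flagged, cell.recip2)


def symmetrize(cell: ProjectedCell, order: int) -> ProjectedCell:
    """Replace each bin by the mean over its rotation orbit.

    Excluded bins are omitted from the mean; a bin whose whole orbit is
    excluded stays excluded.  Because bin centres sit on the lattice i/bins
    and the rotation acts by an integer matrix, orbits are exact bin
    permutations and the operation is idempotent.
    """
    if order < 1:
        raise ValueError("rotation order must be >= 1")
    if order == 1:
        return cell
    m = _in_plane_rotation(cell.recip2, order)
    nb = cell.bins
    ii, jj = np.meshgrid(np.arange(nb), np.arange(nb), indexing="ij")
    sums = np.where(cell.excluded, 0.0, cell.values).copy()
    cnts = (~cell.excluded).astype(float).copy()
    ci, cj = ii, jj
    for _ in range(order - 1):
        ci, cj = (m[0, 0] * ci + m[0, 1] * cj) % nb, (m[1, 0] * ci + m[1, 1] * cj) % nb
        sums += np.where(cell.excluded[ci, cj], 0.0, cell.values[ci, cj])
        cnts += (~cell.excluded[ci, cj]).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnts > 0, sums / np.maximum(cnts, 1e-300), 0.0)
    return ProjectedCell(mean, cell.counts.copy(), cnts == 0, cell.recip2)


def rotation_orbit(v: tuple[int, int], m: np.ndarray, order: int) -> list[tuple[int, int]]:
    """Distinct integer vectors in the orbit of *v* under the rotation matrix."""
    orbit = []
    cur = np.asarray(v, dtype=int)
    for _ in range(order):
        t = tuple(int(c) for c in cur)
        if t not in orbit:
            orbit.append(t)
        cur = m @ cur
    return orbit


def _orbit_classes(vector_set, constraints: SymmetryConstraint, recip2):
    """Partition admitted in-plane vectors into symmetry equivalence classes."""
    if constraints.rotation_order > 1:
        m = _in_plane_rotation(recip2, constraints.rotation_order)
    else:
        m = np.eye(2, dtype=int)
    classes: dict[tuple[int, int], list[tuple[int, int]]] = {}
    assigned: set[tuple[int, int]] = set()
    for v in vector_set:
        if not constraints.admits(v):
            continue
        v2 = (int(v[0]), int(v[1]))
        if v2 == (0, 0) or v2 in assigned:
            continue
        orbit = rotation_orbit(v2, m, constraints.rotation_order)
        # the cosine pairs each vector with its negation: include -v orbit
        full = list(orbit)
        for w in orbit:
            nw = (-w[0], -w[1])
            if nw not in full:
                full.append(nw)
        rep = v2
        classes[rep] = full
        assigned.update(full)
    return classes


def cosine_design(cell: ProjectedCell, classes) -> np.ndarray:
    """Design matrix over all bins: constant column + one column per class.

    Column c at bin (i, j) is sum over the class orbit (v and -v both
    counted, matching the lattice cosine series) of cos(2 pi (h n1 + k n2)).
    """
    hh, kk = cell.bin_centers()
    cols = [np.ones(hh.size)]
    for rep, orbit in classes.items():
        g = np.zeros(hh.size)
        for (n1, n2) in orbit:
            g += np.cos(2.0 * np.pi * (hh.ravel() * n1 + kk.ravel() * n2))
        cols.append(g)
    return np.stack(cols, axis=1)


def synthesize_cell(
    class_alphas: dict[tuple[int, int], float],
    recip2: np.ndarray,
    bins: int = 64,
    order: int = 6,
    scale: float = 1.0,
    exclude=None,
) -> ProjectedCell:
    """Forward model: build a projected cell from class alphas (plus scale)."""
    cell = ProjectedCell(
        values=np.zeros((bins, bins)),
        counts=np.ones((bins, bins), dtype=int),
        excluded=np.zeros((bins, bins), dtype=bool),
        recip2=np.asarray(recip2, float),
    )
    constraints = SymmetryConstraint(rotation_order=order)
    classes = _orbit_classes(list(class_alphas.keys()), constraints, cell.recip2)
    design = cosine_design(cell, classes)
    coeffs = np.concatenate([[1.0], [class_alphas[rep] for rep in classes]]) * scale
    cell.values = (design @ coeffs).reshape(bins, bins)
    if exclude is not None:
        cell.excluded = exclude
    return cell


def refine_alphas(
    cell: ProjectedCell,
    vector_set,
    constraints: SymmetryConstraint = SymmetryConstraint(),
) -> RefinementResult:
    """Linear least-squares Warren-Cowley refinement against a projected cell.

    Solves for the overall scale and one alpha per symmetry equivalence
    class; vectors failing the exclusion predicate are omitted.  Raises
    :class:`SingularDesignError` when classes are collinear on the
    included bins (e.g. all bins excluded, or aliased vectors).
    """
    classes = _orbit_classes(vector_set, constraints, cell.recip2)
    design = cosine_design(cell, classes)
    mask = ~cell.excluded.ravel()
    n_free = design.shape[1]
    if mask.sum() < n_free:
        raise SingularDesignError(
            f"only {int(mask.sum())} included bins for {n_free} free parameters"
        )
    a = design[mask]
    y = cell.values.ravel()[mask]
    rank = np.linalg.matrix_rank(a)
    if rank < n_free:
        raise SingularDesignError(
            f"design rank {rank} < {n_free}; collinear classes "
            f"{list(classes.keys())}"
        )
    coef, _, _, _ = np.linalg.lstsq(a, y, rcond=None)
    scale = float(coef[0])
    if scale == 0:
        raise SingularDesignError("zero scale factor; cell carries no intensity")
    alphas = {rep: float(c / scale) for rep, c in zip(classes, coef[1:])}
    fitted = (design @ coef).reshape(cell.values.shape)
    diff = np.where(cell.excluded, 0.0, cell.values - fitted)
    rss = float((diff[~cell.excluded] ** 2).sum())
    return RefinementResult(
        alphas=alphas, scale=scale, rss=rss, fitted=fitted,
        difference=diff, included=~cell.excluded, classes=classes,
    )


@dataclass(frozen=True)
class DebyeWallerModel:
    """Isotropic Debye-Waller attenuation, B in square angstrom.

    The amplitude factor exp(-B sin^2(theta)/lambda^2) = exp(-B|Q|^2/(16 pi^2))
    enters intensity squared, so intensities are damped by
    exp(-B |Q|^2 / (8 pi^2)); B = 0 is the identity.
    """

    b_iso: float = 0.0

    def __post_init__(self) -> None:
        if self.b_iso < 0:
            raise ValueError("B must be non-negative")

    def intensity_factor(self, q_magnitude) -> np.ndarray:
        q = np.asarray(q_magnitude, dtype=float)
        return np.exp(-self.b_iso * q**2 / (8.0 * np.pi**2))


def dw_correct(calc_plane: ScatteringPlane, dw: DebyeWallerModel) -> ScatteringPlane:
    """Apply the intensity Debye-Waller factor pixel-wise."""
    factor = dw.intensity_factor(calc_plane.plane.q_magnitude)
    return calc_plane.with_data(calc_plane.data * factor)


def fit_b_factor(
    calc_plane: ScatteringPlane,
    reference_plane: ScatteringPlane,
    min_rel_intensity: float = 1e-4,
) -> tuple[DebyeWallerModel, float]:
    """Refine B (and a free scale) so the damped calculation matches the
    reference: log(I_ref / I_calc) = log s - B |Q|^2 / (8 pi^2), a linear fit
    on pixels where both intensities are significant.  Returns (model, scale).
    """
    ic = calc_plane.data
    ir = reference_plane.data
    good = (ic > min_rel_intensity * ic.max()) & (ir > min_rel_intensity * ir.max())
    q2 = calc_plane.plane.q_magnitude[good] ** 2
    ratio = np.log(ir[good] / ic[good])
    design = np.stack([np.ones_like(q2), -q2 / (8.0 * np.pi**2)], axis=1)
    (log_s, b), _, _, _ = np.linalg.lstsq(design, ratio, rcond=None)
    return DebyeWallerModel(b_iso=max(float(b), 0.0)), float(np.exp(log_s))


def rotation_scan(
    molecule: Molecule,
    axis: tuple[int, int],
    group,
    angle_grid,
    reference_ff_plane: ScatteringPlane,
    dw_model: DebyeWallerModel = DebyeWallerModel(0.0),
    partner: Molecule | None = None,
    m_a: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """MSE between a separated I_FF and calculated I_FF vs torsion angle.

    For each angle the *group* atoms rotate rigidly about the bond from
    ``axis[0]`` to ``axis[1]``, I_FF is computed against *partner* (vacancy
    by default), Debye-Waller damped, square-root normalized like the
    reference, and scored by mean squared error.  Returns (angles, mse
    curve, argmin angle); the normalized comparison makes the curve
    invariant to any positive rescaling of the reference.
    """
    partner = partner if partner is not None else Molecule.vacancy()
    angles = np.asarray(angle_grid, dtype=float)
    ref_norm = sqrt_normalize(reference_ff_plane.data)
    plane = reference_ff_plane.plane
    mses = np.empty(angles.size)
    for i, theta in enumerate(angles):
        rotated = rotate_group_about_bond(molecule, axis[0], axis[1], group, theta)
        calc = i_ff_plane(rotated, partner, m_a, 1.0 - m_a, plane)
        damped = dw_correct(calc, dw_model)
        calc_norm = sqrt_normalize(damped.data)
        mses[i] = float(((calc_norm - ref_norm) ** 2).mean())
    return angles, mses, float(angles[int(np.argmin(mses))])
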