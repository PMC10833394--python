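"""Paired training-sample assembly for the scattering factorization task.

For each molecule pair the pipeline mirrors how a dataset of realistic
diffuse-scattering planes is curated:

1. draw an SRO parameter set (MC-realizable or symmetry-restricted) and a
   Vegard-law lattice from the molecular sizes and concentrations;
2. select reciprocal-space planes (12 per MC model, 4 per symmetry model);
3. evaluate I_FF, I_SRO and their product I_D = I_FF * I_SRO on each plane;
4. drop topologically redundant planes via a 1D Wasserstein distance check;
5. square-root compress and normalize every plane to [-1, 1] per sample;
6. imprint a synthetic detector-artefact mask on the input (dead pixels at
   exactly -1), keeping the clean copy as the product-consistency target.

The manifest records exact stage counts so bookkeeping is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import sro as sro_mod
from .molecules import Molecule
from .scatter import PlaneDefinition, ScatteringPlane, i_ff_plane, reciprocal_basis

__all__ = [
    "ArtifactMask",
    "DatasetSample",
    "DatasetManifest",
    "DatasetConfig",
    "vegard_lattice",
    "select_planes",
    "compose_total",
    "sqrt_normalize",
    "synthetic_artifact_mask",
    "apply_artifact",
    "wasserstein_filter",
    "build_dataset",
    "count_manifest",
]

logger = logging.getLogger(__name__)


class DegeneratePlaneError(ValueError):
    """All-zero plane cannot be normalized."""


class AlignmentError(ValueError):
    """Grids or plane definitions do not match."""


@dataclass(frozen=True)
class ArtifactMask:
    """Binary detector dead-zone mask (True = dead pixel)."""

    dead: np.ndarray  # bool (n, n)
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if self.dead.all():
            raise ValueError("mask must leave at least one live pixel")

    @property
    def live_fraction(self) -> float:
        return 1.0 - float(self.dead.mean())


@dataclass
class DatasetSample:
    """One normalized training triplet plus provenance."""

    input: np.ndarray  # artefact-stained normalized product, [-1, 1]
    gt_ff: np.ndarray  # normalized clean I_FF
    gt_sro: np.ndarray  # normalized clean I_SRO
    input_clean: np.ndarray  # normalized artefact-free product
    metadata: dict

    def validate(self) -> None:
        for name in ("input", "gt_ff", "gt_sro", "input_clean"):
            g = getattr(self, name)
            if g.shape != self.input.shape:
                raise AlignmentError(f"{name} grid size mismatch")
            if g.min() < -1 - 1e-12 or g.max() > 1 + 1e-12:
                raise ValueError(f"{name} outside [-1, 1]")


@dataclass
class DatasetManifest:
    """Stage counts and per-sample records for one dataset build."""

    n_pairs: int
    mc_models_per_pair: int
    mc_planes_per_model: int
    sym_models_per_pair: int
    sym_planes_per_model: int
    pre_filter_total: int
    removed_by_uniqueness: int = 0
    degenerate_skipped: int = 0
    records: list[dict] = field(default_factory=list)

    @property
    def planes_per_pair(self) -> int:
        return (
            self.mc_models_per_pair * self.mc_planes_per_model
            + self.sym_models_per_pair * self.sym_planes_per_model
        )

    @property
    def final_total(self) -> int:
        return self.pre_filter_total - self.removed_by_uniqueness

    def validate(self) -> None:
        if self.pre_filter_total != self.n_pairs * self.planes_per_pair:
            raise ValueError("pre-filter total inconsistent with per-pair plane count")
        if self.final_total != self.pre_filter_total - self.removed_by_uniqueness:
            raise ValueError("manifest arithmetic violated")

    def to_json(self, path) -> None:
        payload = {
            "n_pairs": self.n_pairs,
            "mc_models_per_pair": self.mc_models_per_pair,
            "mc_planes_per_model": self.mc_planes_per_model,
            "sym_models_per_pair": self.sym_models_per_pair,
            "sym_planes_per_model": self.sym_planes_per_model,
            "pre_filter_total": self.pre_filter_total,
            "removed_by_uniqueness": self.removed_by_uniqueness,
            "degenerate_skipped": self.degenerate_skipped,
            "final_total": self.final_total,
            "records": self.records,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass(frozen=True)
class DatasetConfig:
    """Knobs of the dataset builder; defaults give 200 planes per pair."""

    mc_models_per_pair: int = 12
    mc_planes_per_model: int = 12
    sym_models_per_pair: int = 14
    sym_planes_per_model: int = 4
    grid_size: int = 256
    q_max_range: tuple[float, float] = (6.0, 8.0)
    wasserstein_threshold: float = 1e-3  # fraction of per-pair dynamic range
    mc_dims: tuple[int, int, int] = (16, 16, 16)
    vector_cutoff: int = 5
    n_cells: float = 1.0


def vegard_lattice(radius_a: float, radius_b: float, m_a: float) -> float:
    """Concentration-weighted (Vegard's law) cubic lattice parameter.

    Each end-member lattice constant is twice the molecular size (bounding
    radius plus padding), so neighbouring molecules just clear each other.
    """
    if radius_a <= 0 or radius_b <= 0:
        raise ValueError("molecular radii must be positive")
    if not 0.0 <= m_a <= 1.0:
        raise ValueError("m_A must lie in [0, 1]")
    a_a = 2.0 * radius_a
    a_b = 2.0 * radius_b
    return m_a * a_a + (1.0 - m_a) * a_b


def select_planes(
    lattice_parameter: float,
    mode: str,
    seed: int,
    grid_size: int = 256,
    q_max_range: tuple[float, float] = (6.0, 8.0),
    planes_per_axis: int = 4,
    unique_axis: int = 2,
) -> list[PlaneDefinition]:
    """Choose reciprocal-space planes on a cubic (or pseudo-cubic) lattice.

    mode="mc": *planes_per_axis* planes per reciprocal axis (default 4 -> 12
    planes) with distinct integer offsets along the fixed axis.
    mode="symmetry": 4 planes normal to the unique axis.
    Each plane draws its own q_max uniformly from *q_max_range*.
    """
    if mode not in ("mc", "symmetry"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    recip = reciprocal_basis(lattice_parameter, lattice_parameter, lattice_parameter)
    planes = []
    offsets = np.arange(planes_per_axis)  # integer offsets 0..3 by default
    if mode == "mc":
        fixed_axes = range(3)
    else:
        fixed_axes = [unique_axis]
    for fixed in fixed_axes:
        in_plane = tuple(sorted(set(range(3)) - {fixed}))
        for off in offsets:
            q_max = float(rng.uniform(*q_max_range))
            planes.append(
                PlaneDefinition.axis_plane(
                    recip,
                    in_plane_axes=in_plane,
                    offset=float(off),
                    grid_size=grid_size,
                    q_max=q_max,
                )
            )
    return planes


def compose_total(iff: ScatteringPlane, isro: ScatteringPlane) -> ScatteringPlane:
    """Total diffuse scattering I_D = I_FF * I_SRO, pixel-wise."""
    if iff.data.shape != isro.data.shape or not np.allclose(
        iff.plane.fractional_coords, isro.plane.fractional_coords
    ):
        raise AlignmentError("plane definitions differ between components")
    return ScatteringPlane(iff.data * isro.data, iff.plane, component_tag="TOTAL")


def sqrt_normalize(data: np.ndarray) -> np.ndarray:
    """Square-root compress and rescale to [-1, 1] per sample.

    y = 2 sqrt(I) / max(sqrt(I)) - 1: zero intensity maps to exactly -1,
    the brightest pixel to exactly +1.  The square root emphasizes
    low-intensity features; normalization is per sample, not per dataset.
    """
    data = np.asarray(data, dtype=float)
    if data.min() < 0:
        raise ValueError("intensities must be non-negative before normalization")
    root = np.sqrt(data)
    peak = root.max()
    if peak == 0:
        raise DegeneratePlaneError("all-zero plane cannot be normalized")
    return 2.0 * root / peak - 1.0


def synthetic_artifact_mask(seed: int, grid_size: int = 256) -> ArtifactMask:
    """Emulate detector dead zones: module-gap bands, beamstop, corners.

    Deterministic under *seed*: 0-3 axis-aligned straight bands 2-8 pixels
    wide on the reference 256 grid (scaled proportionally for other sizes),
    an optional central beamstop disc with an optional holder arm, and
    rounded corners.  Construction keeps the live-pixel fraction >= 0.6.
    """
    rng = np.random.default_rng(seed)
    n = grid_size
    dead = np.zeros((n, n), dtype=bool)
    ii, jj = np.indices((n, n))
    # module-gap bands
    for _ in range(rng.integers(0, 4)):
        width = max(1, round(int(rng.integers(2, 9)) * n / 256))
        pos = int(rng.integers(0, n - width))
        if rng.random() < 0.5:
            dead[pos : pos + width, :] = True
        else:
            dead[:, pos : pos + width] = True
    # central beamstop
    if rng.random() < 0.7:
        r = float(rng.uniform(0.02, 0.06)) * n
        c = n / 2 + rng.uniform(-2, 2, size=2)
        dead |= (ii - c[0]) ** 2 + (jj - c[1]) ** 2 < r**2
        if rng.random() < 0.5:  # holder arm from beamstop to an edge
            width = max(int(r / 2), 1)
            if rng.random() < 0.5:
                dead[int(c[0]) :, int(c[1]) - width : int(c[1]) + width] = True
            else:
                dead[int(c[0]) - width : int(c[0]) + width, int(c[1]) :] = True
    # rounded corners: circular field of view
    r_fov = n * float(rng.uniform(0.68, 0.75))
    dead |= (ii - n / 2) ** 2 + (jj - n / 2) ** 2 > r_fov**2
    mask = ArtifactMask(dead=dead, provenance=f"synthetic-{seed}")
    assert mask.live_fraction >= 0.6, "mask construction violated live-fraction bound"
    return mask


def apply_artifact(normalized: np.ndarray, mask: ArtifactMask) -> np.ndarray:
    """Set dead pixels of a [-1, 1] plane to exactly -1 (idempotent)."""
    if normalized.shape != mask.dead.shape:
        raise AlignmentError("mask and plane grid sizes differ")
    out = normalized.copy()
    out[mask.dead] = -1.0
    return out


def wasserstein_filter(
    planes: list[np.ndarray], threshold: float
) -> tuple[list[int], int]:
    """Drop near-duplicate planes by 1D Wasserstein distance.

    The distance between two planes is the mean absolute difference of
    their sorted pixel intensities (the 1D optimal-transport distance
    between the empirical intensity distributions).  Scanning in input
    order, a plane closer than *threshold* to any already-kept plane is
    dropped; returns (kept indices, removed count), deterministic.
    """
    if not planes:
        raise ValueError("at least one plane required")
    sorted_pix = [np.sort(np.asarray(p, float).ravel()) for p in planes]
    kept: list[int] = []
    removed = 0
    for i, cur in enumerate(sorted_pix):
        dup = False
        for j in kept:
            if np.abs(cur - sorted_pix[j]).mean() < threshold:
                dup = True
                break
        if dup:
            removed += 1
        else:
            kept.append(i)
    return kept, removed


def count_manifest(
    n_pairs: int,
    config: DatasetConfig = DatasetConfig(),
) -> DatasetManifest:
    """Dry-run bookkeeping: the manifest a build would produce, by counting
    alone (no scattering is simulated, removed-by-uniqueness is 0)."""
    m = DatasetManifest(
        n_pairs=n_pairs,
        mc_models_per_pair=config.mc_models_per_pair,
        mc_planes_per_model=config.mc_planes_per_model,
        sym_models_per_pair=config.sym_models_per_pair,
        sym_planes_per_model=config.sym_planes_per_model,
        pre_filter_total=n_pairs
        * (
            config.mc_models_per_pair * config.mc_planes_per_model
            + config.sym_models_per_pair * config.sym_planes_per_model
        ),
    )
    m.validate()
    return m


def build_dataset(
    molecule_pairs: list[tuple[Molecule, Molecule]],
    config: DatasetConfig,
    seed: int,
) -> tuple[DatasetManifest, list[DatasetSample]]:
    """Run the full pipeline over *molecule_pairs*; returns manifest + samples.

    Degenerate (all-zero) planes are logged, skipped, and counted in the
    manifest's ``degenerate_skipped`` — they never silently vanish from the
    totals (they are counted as removed so the arithmetic stays exact).
    """
    if not molecule_pairs:
        raise ValueError("at least one molecule pair required")
    rng = np.random.default_rng(seed)
    manifest = count_manifest(len(molecule_pairs), config)
    samples: list[DatasetSample] = []
    removed_total = 0
    degenerate_total = 0
    for pair_id, (mol_a, mol_b) in enumerate(molecule_pairs):
        raw: list[tuple[np.ndarray, np.ndarray, np.ndarray, dict]] = []
        model_specs = [("mc", k) for k in range(config.mc_models_per_pair)] + [
            ("symmetry", k) for k in range(config.sym_models_per_pair)
        ]
        for source, model_id in model_specs:
            if source == "mc":
                model = sro_mod.sample_realistic_sro(
                    seed=int(rng.integers(0, 2**31 - 1)),
                    vector_cutoff=config.vector_cutoff,
                    dims=config.mc_dims,
                )
                n_planes = config.mc_planes_per_model
            else:
                params = sro_mod.OscillatorParams(
                    amplitude=float(rng.uniform(0.6, 1.5)),
                    decay=float(rng.uniform(0.1, 1.2)),
                    frequency=float(rng.uniform(0.0, 1.0)),
                )
                model = sro_mod.oscillator_alphas(params)
                n_planes = config.sym_planes_per_model
            lattice = vegard_lattice(mol_a.size, mol_b.size, model.m_a)
            planes = select_planes(
                lattice,
                mode=source,
                seed=int(rng.integers(0, 2**31 - 1)),
                grid_size=config.grid_size,
                q_max_range=config.q_max_range,
            )
            if source == "mc":
                planes = planes[:n_planes]
            else:
                planes = planes[:n_planes]
            for plane_id, plane in enumerate(planes):
                iff = i_ff_plane(
                    mol_a, mol_b, model.m_a, model.m_b, plane, scale=config.n_cells
                )
                isro = sro_mod.i_sro_plane(model, plane, scale=config.n_cells)
                total = compose_total(iff, isro)
                meta = {
                    "pair_id": pair_id,
                    "sro_source": source,
                    "sro_model_id": model_id,
                    "plane_id": plane_id,
                    "m_a": model.m_a,
                    "lattice": lattice,
                    "q_max": plane.q_max,
                }
                raw.append((iff.data, isro.data, total.data, meta))
        # normalize first (degenerate planes drop out here), then run the
        # uniqueness check on the normalized planes so the distance is
        # scale-free: the threshold is a fraction of the fixed [-1, 1]
        # dynamic range
        normalized = []
        for iff_d, isro_d, tot_d, meta in raw:
            try:
                normalized.append(
                    (sqrt_normalize(iff_d), sqrt_normalize(isro_d),
                     sqrt_normalize(tot_d), meta)
                )
            except DegeneratePlaneError:
                logger.warning("degenerate plane skipped: %s", meta)
                degenerate_total += 1
        kept, removed = wasserstein_filter(
            [t for _, _, t, _ in normalized],
            threshold=config.wasserstein_threshold * 2.0,
        )
        removed_total += removed
        for idx in kept:
            gt_ff, gt_sro, clean, meta = normalized[idx]
            mask = synthetic_artifact_mask(
                int(rng.integers(0, 2**31 - 1)), grid_size=config.grid_size
            )
            sample = DatasetSample(
                input=apply_artifact(clean, mask),
                gt_ff=gt_ff,
                gt_sro=gt_sro,
                input_clean=clean,
                metadata={**meta, "mask": mask.provenance},
            )
            sample.validate()
            samples.append(sample)
            manifest.records.append(sample.metadata)
    manifest.removed_by_uniqueness = removed_total + degenerate_total
    manifest.degenerate_skipped = degenerate_total
    manifest.validate()
    return manifest, samples


def save_samples(samples: list[DatasetSample], path) -> None:
    """Write a sample list to a single .npz container (stacked arrays)."""
    np.savez_compressed(
        path,
        input=np.stack([s.input for s in samples]),
        gt_ff=np.stack([s.gt_ff for s in samples]),
        gt_sro=np.stack([s.gt_sro for s in samples]),
        input_clean=np.stack([s.input_clean for s in samples]),
        metadata=np.bytes_(json.dumps([s.metadata for s in samples]).encode()),
    )


def load_samples(path) -> list[DatasetSample]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["metadata"]).decode())
        return [
            DatasetSample(
                input=z["input"][i],
                gt_ff=z["gt_ff"][i],
                gt_sro=z["gt_sro"][i],
                input_clean=z["input_clean"][i],
                metadata=meta[i],
            )
            for i in range(len(meta))
        ]
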