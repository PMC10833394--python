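"""Chemical short-range order: Warren-Cowley parameters and I_SRO.

For a binary A/B occupancy field on a simple lattice, the Warren-Cowley
parameter at intermolecular vector v is

    alpha_v = 1 - p_AB(v) / m_B,

where p_AB(v) is the conditional probability of finding B at v away from an
A site.  alpha_0 = 1 by construction, alpha_v = alpha_{-v}, 0 for a random
alloy, negative for unlike-neighbour preference.  The corresponding diffuse
scattering component is the cosine series

    I_SRO(Q) = N m_A m_B sum_v alpha_v cos(2 pi (h,k,l) . v).

Configurations matching target nearest-neighbour alphas are generated with a
Metropolis simulated-annealing Monte Carlo using composition-conserving swap
moves; the remaining alphas are then *measured* from the configuration, so
every sampled alpha set is realizable by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .scatter import PlaneDefinition, ScatteringPlane

__all__ = [
    "OccupancyConfiguration",
    "SROModel",
    "OscillatorParams",
    "measure_alphas",
    "mc_generate_configuration",
    "sample_realistic_sro",
    "oscillator_alphas",
    "cubic_shells",
    "i_sro_plane",
    "direct_sum_oracle",
    "canonical_vectors",
]

logger = logging.getLogger(__name__)


class DegenerateConfigurationError(ValueError):
    """Configuration contains only one species."""


@dataclass
class OccupancyConfiguration:
    """Periodic binary occupancy field; labels[i,j,k] is True where A sits."""

    labels: np.ndarray  # bool, shape dims

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D field")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_sites(self) -> int:
        return self.labels.size

    @property
    def m_a(self) -> float:
        return float(self.labels.mean())


@dataclass
class SROModel:
    """Concentrations plus a map from integer lattice vectors to alpha_v.

    ``alphas`` stores one representative per +-v pair ("canonical" storage)
    unless it was built from a full periodic vector set, in which case the
    explicit weighting mode of :func:`i_sro_plane` applies.
    """

    m_a: float
    alphas: dict[tuple[int, int, int], float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.m_a < 1.0):
            raise DegenerateConfigurationError(f"m_A = {self.m_a} is degenerate")
        if (0, 0, 0) not in self.alphas:
            raise ValueError("alpha map must contain the (0,0,0) vector")
        if abs(self.alphas[(0, 0, 0)] - 1.0) > 1e-12:
            raise ValueError("alpha at (0,0,0) must equal 1")

    @property
    def m_b(self) -> float:
        return 1.0 - self.m_a

    def pair_probability(self, v) -> float:
        """p_AB(v) = m_B (1 - alpha_v)."""
        return self.m_b * (1.0 - self.alphas[tuple(v)])

    def validate_feasible(self) -> None:
        for v, a in self.alphas.items():
            p = self.m_b * (1.0 - a)
            if not (-1e-9 <= p <= 1.0 + 1e-9):
                raise ValueError(f"alpha at {v} implies pair probability {p} outside [0,1]")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# m_A={self.m_a!r}\tm_B={self.m_b!r}\n")
            fh.write("n1\tn2\tn3\talpha\n")
            for (n1, n2, n3), a in sorted(self.alphas.items()):
                fh.write(f"{n1}\t{n2}\t{n3}\t{a!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "SROModel":
        with open(path) as fh:
            header = fh.readline()
            m_a = float(header.split("m_A=")[1].split("\t")[0])
            fh.readline()  # column names
            alphas = {}
            for line in fh:
                n1, n2, n3, a = line.split("\t")
                alphas[(int(n1), int(n2), int(n3))] = float(a)
        return cls(m_a=m_a, alphas=alphas)


def canonical_vectors(cutoff: int) -> list[tuple[int, int, int]]:
    """One representative per +-v pair with all components in [-cutoff, cutoff].

    The representative is the lexicographically positive member; (0,0,0) is
    included first.
    """
    out = [(0, 0, 0)]
    rng = range(-cutoff, cutoff + 1)
    for n1 in rng:
        for n2 in rng:
            for n3 in rng:
                v = (n1, n2, n3)
                if v > (0, 0, 0):
                    out.append(v)
    return out


def measure_alphas(config: OccupancyConfiguration, vector_set) -> SROModel:
    """Exact count-based Warren-Cowley parameters over *vector_set*.

    Pair counts for all vectors are obtained at once from the circular
    cross-correlation of the A and B indicator fields (FFT), then converted:
    p_AB(v) = N_AB(v) / n_A with N_AB(v) the number of (A at r, B at r+v)
    ordered pairs under periodic boundaries.
    """
    a_field = config.labels.astype(float)
    n_a = int(a_field.sum())
    if n_a == 0 or n_a == config.n_sites:
        raise DegenerateConfigurationError("configuration contains a single species")
    b_field = 1.0 - a_field
    m_a = n_a / config.n_sites
    m_b = 1.0 - m_a
    # N_AB(v) = sum_r A(r) B(r+v): circular cross-correlation
    corr = np.fft.ifftn(np.conj(np.fft.fftn(a_field)) * np.fft.fftn(b_field)).real
    dims = config.dims
    alphas = {}
    for v in vector_set:
        idx = tuple(int(c) % d for c, d in zip(v, dims))
        p_ab = corr[idx] / n_a
        alphas[tuple(int(c) for c in v)] = 1.0 - p_ab / m_b
    alphas[(0, 0, 0)] = 1.0  # exact by definition; clears FFT round-off
    return SROModel(m_a=m_a, alphas=alphas, meta={"dims": dims})


@njit(cache=False)
def _mc_kernel(labels, targets, m_b, sweeps, t_start, t_end, seed):  # pragma: no cover
    np.random.seed(seed)
    l1, l2, l3 = labels.shape
    n_sites = l1 * l2 * l3
    n_a = 0
    for i in range(l1):
        for j in range(l2):
            for k in range(l3):
                n_a += int(labels[i, j, k])
    denom = n_a * m_b
    # ordered A->B pair counts along +e1, +e2, +e3
    nab = np.zeros(3, dtype=np.int64)
    for i in range(l1):
        for j in range(l2):
            for k in range(l3):
                if labels[i, j, k] == 1:
                    if labels[(i + 1) % l1, j, k] == 0:
                        nab[0] += 1
                    if labels[i, (j + 1) % l2, k] == 0:
                        nab[1] += 1
                    if labels[i, j, (k + 1) % l3] == 0:
                        nab[2] += 1
    cost = 0.0
    for a in range(3):
        alpha = 1.0 - nab[a] / denom
        cost += (alpha - targets[a]) ** 2
    cost *= n_sites  # scaled so single-swap deltas are O(1) vs the schedule
    n_moves = sweeps * n_sites
    ratio = t_end / t_start
    inv = 1.0 / max(n_moves - 1, 1)
    bond_ids = np.empty(12, dtype=np.int64)  # encoded left-endpoint * 3 + axis
    cnt_before = np.zeros(3, dtype=np.int64)
    cnt_after = np.zeros(3, dtype=np.int64)
    for step in range(n_moves):
        temp = t_start * ratio ** (step * inv)
        s1 = np.random.randint(n_sites)
        s2 = np.random.randint(n_sites)
        i1, r1 = divmod(s1, l2 * l3)
        j1, k1 = divmod(r1, l3)
        i2, r2 = divmod(s2, l2 * l3)
        j2, k2 = divmod(r2, l3)
        if labels[i1, j1, k1] == labels[i2, j2, k2]:
            continue  # swap of like labels is a no-op
        # unique bonds incident to either site: left endpoints along each axis
        n_bonds = 0
        for t in range(2):
            ci = i1 if t == 0 else i2
            cj = j1 if t == 0 else j2
            ck = k1 if t == 0 else k2
            for a in range(3):
                for sgn in range(2):  # 0: bond (site, site+e_a); 1: (site-e_a, site)
                    li, lj, lk = ci, cj, ck
                    if sgn == 1:
                        if a == 0:
                            li = (ci - 1) % l1
                        elif a == 1:
                            lj = (cj - 1) % l2
                        else:
                            lk = (ck - 1) % l3
                    bid = ((li * l2 + lj) * l3 + lk) * 3 + a
                    dup = False
                    for b in range(n_bonds):
                        if bond_ids[b] == bid:
                            dup = True
                            break
                    if not dup:
                        bond_ids[n_bonds] = bid
                        n_bonds += 1
        for a in range(3):
            cnt_before[a] = 0
            cnt_after[a] = 0
        for b in range(n_bonds):
            bid = bond_ids[b]
            a = bid % 3
            lflat = bid // 3
            li, rr = divmod(lflat, l2 * l3)
            lj, lk = divmod(rr, l3)
            if a == 0:
                ri, rj, rk = (li + 1) % l1, lj, lk
            elif a == 1:
                ri, rj, rk = li, (lj + 1) % l2, lk
            else:
                ri, rj, rk = li, lj, (lk + 1) % l3
            if labels[li, lj, lk] == 1 and labels[ri, rj, rk] == 0:
                cnt_before[a] += 1
        labels[i1, j1, k1] = 1 - labels[i1, j1, k1]
        labels[i2, j2, k2] = 1 - labels[i2, j2, k2]
        for b in range(n_bonds):
            bid = bond_ids[b]
            a = bid % 3
            lflat = bid // 3
            li, rr = divmod(lflat, l2 * l3)
            lj, lk = divmod(rr, l3)
            if a == 0:
                ri, rj, rk = (li + 1) % l1, lj, lk
            elif a == 1:
                ri, rj, rk = li, (lj + 1) % l2, lk
            else:
                ri, rj, rk = li, lj, (lk + 1) % l3
            if labels[li, lj, lk] == 1 and labels[ri, rj, rk] == 0:
                cnt_after[a] += 1
        new_cost = 0.0
        for a in range(3):
            alpha = 1.0 - (nab[a] + cnt_after[a] - cnt_before[a]) / denom
            new_cost += (alpha - targets[a]) ** 2
        new_cost *= n_sites
        dc = new_cost - cost
        if dc <= 0.0 or np.random.random() < np.exp(-dc / temp):
            for a in range(3):
                nab[a] += cnt_after[a] - cnt_before[a]
            cost = new_cost
        else:  # revert
            labels[i1, j1, k1] = 1 - labels[i1, j1, k1]
            labels[i2, j2, k2] = 1 - labels[i2, j2, k2]
    return cost / n_sites


def feasible_alpha_range(m_a: float) -> tuple[float, float]:
    """alpha interval for which the implied p_AB lies in [0, 1]."""
    m_b = 1.0 - m_a
    return 1.0 - 1.0 / m_b, 1.0


def mc_generate_configuration(
    m_a: float,
    target_alphas,
    dims=(24, 24, 24),
    seed: int = 0,
    sweeps: int = 150,
    t_start: float = 1.0,
    t_end: float = 1e-3,
    tolerance: float = 1e-3,
) -> OccupancyConfiguration:
    """Anneal a composition-conserving occupancy field to target NN alphas.

    *target_alphas* are the three nearest-neighbour Warren-Cowley targets
    (alpha_[100], alpha_[010], alpha_[001]).  Metropolis swap moves conserve
    the exact A-count; the annealing cost is the summed squared deviation of
    the measured axis alphas from the targets (scaled by the site count so
    single-swap changes are O(1) against the temperature schedule).  If the
    final cost exceeds *tolerance* a warning carrying the achieved alphas is
    logged; the configuration is returned either way.
    """
    dims = tuple(int(d) for d in dims)
    if min(dims) < 8:
        raise ValueError("dims must be >= 8 per axis")
    targets = np.asarray(target_alphas, dtype=float)
    if targets.shape != (3,):
        raise ValueError("exactly three nearest-neighbour targets required")
    lo, hi = feasible_alpha_range(m_a)
    if np.any(targets < lo - 1e-9) or np.any(targets > hi + 1e-9):
        raise ValueError(
            f"targets {targets} outside the p-feasible alpha range "
            f"[{lo:.3f}, {hi:.3f}] for m_A = {m_a}"
        )
    rng = np.random.default_rng(seed)
    n_sites = int(np.prod(dims))
    n_a = int(round(m_a * n_sites))
    if n_a in (0, n_sites):
        raise DegenerateConfigurationError(f"m_A = {m_a} leaves no minority species")
    flat = np.zeros(n_sites, dtype=np.int8)
    flat[rng.permutation(n_sites)[:n_a]] = 1
    labels = flat.reshape(dims)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    final_cost = _mc_kernel(
        labels, targets, 1.0 - m_a, int(sweeps),
        float(t_start), float(t_end), kernel_seed,
    )
    config = OccupancyConfiguration(labels=labels.astype(bool))
    if final_cost > tolerance:
        measured = measure_alphas(config, [(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        achieved = [measured.alphas[v] for v in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
        logger.warning(
            "MC annealing did not reach tolerance %.1e (cost %.3e); "
            "achieved axis alphas %s for targets %s",
            tolerance, final_cost, achieved, list(targets),
        )
    return config


def sample_realistic_sro(
    seed: int,
    vector_cutoff: int = 5,
    dims=(16, 16, 16),
    sweeps: int = 120,
    m_a_range: tuple[float, float] = (0.3, 0.7),
    target_range: tuple[float, float] = (-0.4, 0.4),
) -> SROModel:
    """Draw one realizable SRO parameter set.

    Random concentration and random feasible axis targets are annealed into a
    configuration; all alphas up to *vector_cutoff* are then measured from
    it, guaranteeing a mutually consistent (realizable) parameter set.
    """
    rng = np.random.default_rng(seed)
    m_a = float(rng.uniform(*m_a_range))
    lo, hi = feasible_alpha_range(m_a)
    margin = 0.05
    t_lo = max(target_range[0], lo + margin)
    t_hi = min(target_range[1], hi - margin)
    targets = rng.uniform(t_lo, t_hi, size=3)
    config = mc_generate_configuration(
        m_a, targets, dims=dims, seed=int(rng.integers(0, 2**31 - 1)), sweeps=sweeps
    )
    model = measure_alphas(config, canonical_vectors(vector_cutoff))
    model.meta.update({"seed": seed, "targets": targets.tolist(), "source": "mc"})
    return model


@dataclass(frozen=True)
class OscillatorParams:
    """Damped-oscillator description of shell-wise alphas.

    alpha(x) = amplitude * exp(-decay * x) * cos(pi * frequency * x) with x
    the neighbour-shell index (1 = nearest).  Parameter ranges keep alphas
    within physical bounds and decayed to ~0 by the last shell.
    """

    amplitude: float  # A in [0.6, 1.5]
    decay: float  # d in [0.1, 1.2]
    frequency: float  # omega in [0, 1]

    def __post_init__(self) -> None:
        if not (0.6 <= self.amplitude <= 1.5):
            raise ValueError(f"amplitude {self.amplitude} outside [0.6, 1.5]")
        if not (0.1 <= self.decay <= 1.2):
            raise ValueError(f"decay {self.decay} outside [0.1, 1.2]")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")

    def alpha(self, shell: int) -> float:
        x = float(shell)
        return self.amplitude * np.exp(-self.decay * x) * np.cos(np.pi * self.frequency * x)


def cubic_shells(n_shells: int = 5) -> dict[tuple[int, int, int], int]:
    """Map canonical vectors of the first *n_shells* cubic neighbour shells
    to their shell index (1 = nearest neighbour, ordered by |v|^2)."""
    by_r2: dict[int, list[tuple[int, int, int]]] = {}
    for v in canonical_vectors(3):
        if v == (0, 0, 0):
            continue
        r2 = v[0] ** 2 + v[1] ** 2 + v[2] ** 2
        by_r2.setdefault(r2, []).append(v)
    shell_map: dict[tuple[int, int, int], int] = {}
    for x, r2 in enumerate(sorted(by_r2)[:n_shells], start=1):
        for v in by_r2[r2]:
            shell_map[v] = x
    return shell_map


def oscillator_alphas(
    params: OscillatorParams,
    shell_map: dict[tuple[int, int, int], int] | None = None,
) -> SROModel:
    """Symmetry-restricted SRO model from the damped oscillator.

    All symmetry-equivalent vectors in a shell share one alpha; the
    concentration is fixed at m_A = m_B = 0.5 and alphas are clamped to the
    p-feasible interval [-1, 1] at that composition.
    """
    if shell_map is None:
        shell_map = cubic_shells(5)
    if any(x < 1 for x in shell_map.values()):
        raise ValueError("shell indices must be >= 1")
    alphas = {(0, 0, 0): 1.0}
    for v, x in shell_map.items():
        a = params.alpha(x)
        alphas[tuple(v)] = float(np.clip(a, -1.0, 1.0))
    model = SROModel(m_a=0.5, alphas=alphas, meta={"source": "oscillator"})
    model.validate_feasible()
    return model


def _plane_axis_coords(plane: PlaneDefinition):
    """The separable (u, v, offset) structure of an axis-aligned plane grid."""
    ax0, ax1 = plane.in_plane_axes
    (ax2,) = set(range(3)) - set(plane.in_plane_axes)
    u = plane.fractional_coords[:, 0, ax0]
    v = plane.fractional_coords[0, :, ax1]
    return u, v, plane.offset, (ax0, ax1, ax2)


def i_sro_plane(
    model: SROModel,
    plane: PlaneDefinition,
    scale: float = 1.0,
    weighting: str = "canonical",
    clip_negative: bool = True,
) -> ScatteringPlane:
    """Cosine-series I_SRO on a plane grid.

    weighting="canonical": ``model.alphas`` holds one representative per
    +-v pair and each nonzero vector contributes twice (the v/-v cosine
    pair of the infinite-lattice series), giving e.g. 1 + 2 a cos(2 pi h)
    for a single stored (1,0,0) alpha.

    weighting="explicit": every stored vector contributes exactly once.
    Use this with a negation-closed set such as all vectors of a periodic
    box in [0, L)^3, for which the series reproduces the finite-lattice
    direct sum exactly at the box's allowed reciprocal points.

    Negative series values (possible for hand-specified alpha sets) are
    clipped at zero and the clipped fraction logged.
    """
    if weighting not in ("canonical", "explicit"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if (0, 0, 0) not in model.alphas:
        raise ValueError("alpha map must include (0,0,0)")
    u, v, offset, (ax0, ax1, ax2) = _plane_axis_coords(plane)
    vecs = np.array(list(model.alphas.keys()), dtype=float)  # (V, 3)
    avals = np.array(list(model.alphas.values()))
    weights = np.ones(len(vecs)) if weighting == "explicit" else np.where(
        np.all(vecs == 0, axis=1), 1.0, 2.0
    )
    coef = weights * avals
    # separable evaluation: phase = u*n_ax0 + v*n_ax1 + offset*n_ax2
    e_u = np.exp(2j * np.pi * np.outer(u, vecs[:, ax0]))  # (n, V)
    e_v = np.exp(2j * np.pi * np.outer(v, vecs[:, ax1]))  # (n, V)
    e_off = np.exp(2j * np.pi * offset * vecs[:, ax2])  # (V,)
    series = np.real(e_u * (coef * e_off) @ e_v.T)
    intensity = scale * model.m_a * model.m_b * series
    neg = intensity < 0
    if clip_negative and np.any(neg):
        frac = float(neg.mean())
        logger.info("i_sro_plane: clipped %.2f%% negative pixels to zero", 100 * frac)
        intensity = np.where(neg, 0.0, intensity)
    return ScatteringPlane(intensity, plane, component_tag="SRO")


def direct_sum_oracle(
    config: OccupancyConfiguration, plane: PlaneDefinition
) -> ScatteringPlane:
    """Exact finite-lattice SRO scattering of an explicit configuration.

    I(Q) = |sum_r (c_r - m_A) exp(2 pi i (h,k,l) . r)|^2 / N over the
    periodic box, normalized per cell; at the box's allowed reciprocal
    points this equals m_A m_B times the full-box Warren-Cowley cosine sum.
    Intended as a brute-force cross-check, hence the size guard.
    """
    if config.n_sites > 32**3:
        raise ValueError("direct_sum_oracle is limited to configurations <= 32^3")
    dev = config.labels.astype(float) - config.m_a
    u, v, offset, (ax0, ax1, ax2) = _plane_axis_coords(plane)
    dims = config.dims
    # contract the fixed axis first, then the two in-plane axes
    n_ax2 = np.arange(dims[ax2])
    e_off = np.exp(2j * np.pi * offset * n_ax2)
    dev_t = np.moveaxis(dev, (ax0, ax1, ax2), (0, 1, 2))
    m = dev_t @ e_off  # (L0, L1) complex
    e_u = np.exp(2j * np.pi * np.outer(u, np.arange(dims[ax0])))  # (n, L0)
    e_v = np.exp(2j * np.pi * np.outer(v, np.arange(dims[ax1])))  # (n, L1)
    s = e_u @ m @ e_v.T
    intensity = (np.abs(s) ** 2) / config.n_sites
    return ScatteringPlane(intensity, plane, component_tag="SRO")
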