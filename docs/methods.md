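# Methods

This note records the models, conventions and design choices behind
`diffsep`, in the spirit of a package's statistical/physical documentation:
what is computed, under which assumptions, with which defaults, and what
the synthetic-data experiments do and do not demonstrate.

## Physical model and scope

The package treats crystals with **pure binary substitutional disorder on a
single site per unit cell**: every cell hosts molecule A or molecule B, with
average concentrations m_A + m_B = 1.  Under that assumption (and neglecting
displacive and thermal disorder) the diffuse scattering factorizes exactly
into a form-factor envelope and a lattice-periodic occupancy-correlation
term,

    I_D(Q) = I_FF(Q) · I_SRO(Q),
    I_FF   = N m_A m_B |F_A(Q) − F_B(Q)|²,
    I_SRO  = N m_A m_B Σ_v α_v cos(2π (h,k,l)·v).

Out of scope by design: displacive (size-effect) disorder, thermal diffuse
scattering, multi-site unit cells, Bragg-peak simulation/removal, and
anomalous (complex) atomic scattering.  The Debye–Waller machinery in
`analysis` exists to *correct a calculated I_FF toward* data that contain
thermal smearing, not to model that smearing.

## Molecules and form factors

Atomic form factors use the standard crystallographic four-Gaussian
parameterization f(q) = Σ a_k exp(−b_k (q/4π)²) + c with coefficients for
H, C, N, O, F, P, S, Cl, Br embedded in `formfactors.py` (International
Tables Vol. C analytical fits; f(0) is validated against the electron count
to 2%).  Hydrogens are kept in all form-factor sums — dropping them changes
I_FF measurably.

Synthetic fragments (`random_molecule`) stand in for a curated molecular
library: uniformly placed atoms with a 0.9 Å minimum separation, centroid
at the origin, element pool {H, C, N, O, F, S, Cl}.  They are not
chemically valid geometries; they exist to give form factors with realistic
magnitudes and angular structure.  A molecule's scalar "size" — used for
grouping and lattice constants — is its bounding-sphere radius plus a 1.2 Å
contact padding; a richer shape descriptor was considered and rejected as
unnecessary for the downstream uses (a single scalar enters Vegard's law).
The zero-atom vacancy sentinel is a first-class `Molecule`; its form factor
is identically zero, which makes the B-is-a-vacancy limit (|F_A|²) exact.

## Plane geometry

A `PlaneDefinition` fixes one Miller index and varies the other two on a
square grid.  Pixel centres span the fractional range **inclusively and
symmetrically**, so a centred plane contains the exact Friedel partner of
every pixel (pixel (i, j) pairs with (n−1−i, n−1−j)); odd grids put a pixel
exactly at the zone centre, even grids (the 256-pixel default) do not.
The per-axis fractional half-range is q_max/|b_axis|, so obliquely-angled
cells can exceed q_max·√2 at extreme corners; nothing downstream depends on
the corner norm.  Q-vectors use the 2π convention (Q·a = 2π h).

## Warren–Cowley machinery

`alpha_v = 1 − p_AB(v)/m_B` with p_AB the conditional probability of B at
offset v from an A site.  Measurement is exact and count-based: all pair
counts come from one FFT circular cross-correlation of the A/B indicator
fields, so α_v = α_{−v} holds to the counting identity, and α(0) = 1 is set
exactly.

**MC generation.**  Configurations matching three nearest-neighbour axis
targets are produced by Metropolis simulated annealing with
composition-conserving swap moves (the exact A-count never changes).  The
cost is the summed squared deviation of the three measured axis alphas from
their targets, *scaled by the site count* so that a single swap changes the
cost by O(1) relative to the default geometric temperature schedule
1.0 → 1e-3; bond counts update incrementally from the (deduplicated) bonds
incident to the two swapped sites.  Defaults: 24³ sites, 150 sweeps,
~1 s per configuration (numba-compiled kernel).  If the final cost exceeds
tolerance, a warning carrying the achieved alphas is logged and the
configuration returned — the contract is target matching, not a particular
dynamics.  Because all non-target alphas are *measured* from the resulting
configuration, every sampled parameter set is realizable by construction
(all implied pair probabilities lie in [0, 1]).

**Oscillator models.**  Symmetry-restricted alternatives assign one alpha
per neighbour shell through A·exp(−d·x)·cos(π ω x), x ≥ 1 the shell index,
with A ∈ [0.6, 1.5], d ∈ [0.1, 1.2], ω ∈ [0, 1]; ω spans
no-oscillation to alternating-sign shells, and the decay range ensures the
series is negligible by the fifth shell.  Concentrations are fixed at 0.5
and alphas clamped to the feasible interval [−1, 1] at that composition.
The default shell map covers the first five cubic shells ordered by |v|².
The functional form (the cos(πωx) envelope in particular) is one
defensible choice among several; it is configurable via the shell map and
parameters.

**Two series conventions.**  `i_sro_plane` accepts
`weighting="canonical"` (alphas stored as one representative per ±v pair;
nonzero terms doubled — the infinite-lattice series, giving 1 + 2α cos(2πh)
for a single stored vector) and `weighting="explicit"` (every stored vector
once).  The explicit mode exists because the finite-periodic-box identity —
cosine series over **all** box vectors v ∈ [0, L)³ equals the direct
occupancy sum |Σ (c_r − m_A) e^{2πiQ·r}|²/N at the box's allowed reciprocal
points — requires each box vector counted exactly once, including the
self-paired L/2 vectors of even boxes.  The test suite verifies this
equivalence to ~1e-13 relative.  Negative series values (possible only for
hand-specified alpha sets) are clipped at zero with the clipped fraction
logged.

## Dataset assembly

Per molecule pair: SRO models are drawn (12 MC-realizable + 14
oscillator-type by default), a cubic lattice constant follows Vegard's law
a = m_A·2(r_A + 1.2 Å) + m_B·2(r_B + 1.2 Å), planes are selected (12 per MC
model — 4 per axis with integer offsets 0–3; 4 per symmetry model, normal
to the unique axis) with q_max drawn uniformly in [6, 8] Å⁻¹, and both
components plus their product are evaluated on 256² grids (64² in the
reduced-scale experiments).  The default model counts give 200 planes per
pair; all counts are configuration, and the manifest records exactly what
ran with the invariant `final = pre_filter − removed` enforced.

Normalization is per sample: y = 2√I/max(√I) − 1, mapping zero intensity
to −1 and the brightest pixel to +1; the square root lifts low-intensity
features.  **The uniqueness filter runs on the normalized planes**: the 1D
Wasserstein distance between two planes is the mean absolute difference of
their sorted pixel values (the exact 1D optimal-transport distance between
the empirical intensity distributions, cross-checked against
`scipy.stats.wasserstein_distance`), and a plane closer than a threshold —
default 1e-3 of the fixed [−1, 1] dynamic range — to any already-kept plane
is dropped, deterministically in input order.  Filtering after
normalization makes the distance scale-free; on raw intensities a single
bright plane dominates the dynamic range and the check degenerates.
Degenerate (all-zero) planes are logged, skipped, and counted with the
removed planes so the manifest arithmetic stays exact.

Synthetic artefact masks emulate detector dead zones: 0–3 axis-aligned
module-gap bands (2–8 px at 256, scaled proportionally), an optional
beamstop disc with holder arm, and a circular field of view rounding the
corners; construction bounds the live fraction at ≥ 0.6 (verified over
1000 seeds).  Masked pixels of the network input are set to exactly −1;
the clean copy is retained as the discriminator condition and
product-consistency target.

## Separation networks

Two conditional generator/discriminator pairs train in parallel — one per
component — on a compact numpy layer library written for this package
(strided and transposed convolution via im2col, instance normalization,
leaky ReLU/tanh/sigmoid, inverted dropout, Adam; every layer's backward
pass is verified against central differences in the test suite, and the
transposed convolution is the verified adjoint of the convolution).

* Generator: U-Net, depth log2(grid) − 2 (4 levels at 64², bottleneck 4²),
  base width 12–16, channel doubling capped at 8×, tanh output bounding
  every generated plane to [−1, 1].  Noise enters solely through 50%
  dropout on the three innermost decoder stages, active in training and
  available at inference as a sampling mode (off by default, making
  `decompose` deterministic).
* Discriminator: patch-level convolutional classifier on the candidate
  concatenated channel-wise with the conditioning plane; sigmoid patch map
  in (0, 1).  Patch-level (rather than whole-image) output is an assumption
  the package makes explicit and configurable.
* Losses: the conditional GAN objective plus λ·L1 with λ = 100; the logged
  per-head total is exactly adv + 100·L1 at every step.  After each
  iteration a joint step minimizes the smooth-L1 (β = 1) between the
  product of the two generated components and the product of the
  *normalized* ground-truth components — the product of separately
  normalized factors is not the normalized product (Cauchy–Schwarz), so
  the ground-truth product is the correct target.
* Protocol: discriminators see clean conditions (an artefact-conditioned
  discriminator cannot tell input dead zones from generated ones, so the
  generator would never learn to in-paint them); each network's opponent
  is frozen during its update — enforced structurally by giving each
  network its own optimizer and asserted by parameter-hash tests.
  Optimizer defaults are Adam(lr 2e-4, β₁ 0.5), batch 4.

Checkpoints are single `.npz` archives (float64 parameters, optimizer
moments, epoch counter, loss history, RNG states) with a version tag;
round-trips are bit-exact and training resumes identically.

**Reduced-scale experiments.**  The shipped experiments train on ~200
samples at 64² for 5 epochs (a few minutes on one CPU) — enough to show the
training signal (monotone L1 improvement, bounded outputs, held-out MSE far
below a uniform-noise baseline) but far from a converged model: full-scale
training (≈2·10⁵ samples, 200 epochs, GPU) and perception-network metrics
(FID/KID) are deliberately out of scope.  Passing these tests demonstrates
that the architecture, losses and protocol are wired correctly, not that
the desk-scale model generalizes to experimental data.

## Refinement and model discrimination

`project_to_unit_cell` folds pixels modulo one reciprocal cell into an
n×n bin grid (default 64²) with bin centres on the lattice i/n — chosen so
the integer fractional rotation matrix of a lattice symmetry permutes bins
exactly, which makes `symmetrize` an exact orbit average (idempotent, and
its output invariant under the rotation).  The in-plane rotation matrix is
derived numerically from the reciprocal basis and validated to be integer;
a sixfold request on a non-hexagonal lattice raises.  Exclusion of bins
below 5% of the projected-cell maximum (the threshold is applied to the
projected cell, not the raw plane; both are available) happens before
fitting.

The refinement solves the linear system I = s·α₀ + Σ_c (s·α_c)·g_c over
included bins, with g_c the cosine sum over the class orbit (v and −v both
counted) and the scale/alpha degeneracy resolved by pinning α₀ = 1 —
matching the "cosine series times a scale factor" formulation.  On
noiseless forward-modelled cells the recovery is exact to numerical
precision (it is a linear round trip); with 5% additive noise the fifteen
benchmark in-plane alphas of the hexagonal columnar test system come back
with mean absolute error ~6e-4 over 20 seeds.  Rank deficiency (aliased
classes, everything excluded) raises a named error.

The isotropic Debye–Waller correction multiplies intensities by
exp(−B|Q|²/8π²) (amplitude factor exp(−B|Q|²/16π²), squared).  B can be
supplied or refined: with a free scale, log(I_ref/I_calc) is linear in
|Q|², and the one-parameter fit recovers a known B to machine precision on
clean planes (the tests bound it at 1%).  `rotation_scan` rotates a chosen
group about a bond, recomputes I_FF against the partner molecule at each
angle, applies the Debye–Waller model, square-root normalizes both sides
and reports the MSE curve with its argmin; normalization makes the curve
invariant to any positive rescaling of the reference.

## Randomness and determinism

Every stochastic component takes a single integer seed and threads named
`numpy.random.Generator` instances; artifacts record their seeds in
metadata.  The MC kernel derives its own sub-seed (kept below 2³¹).  All
tests and the acceptance script are reproducible bit-for-bit given the
seed, except for the documented dropout-sampling mode.

## Known limitations

* Synthetic molecules are geometric, not chemical; conclusions about
  chemically specific effects (e.g. hydrogen-bond plausibility of a rotor
  orientation) require real coordinates.
* The projected-cell refinement of a *single* plane cannot distinguish
  vectors differing only along the projection axis (their cosines alias);
  the default exclusion of v_z ≠ 0 makes that restriction explicit.
* The annealer matches three axis targets; longer-range correlations are
  whatever the equilibrium ensemble delivers, which is realistic but not
  controllable.
* Reduced-scale training shows correct mechanics, not converged
  separation quality (see above).
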