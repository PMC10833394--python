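# diffsep

Simulation, machine-learned factorization and quantitative refinement of
single-crystal **diffuse scattering from binary substitutional disorder**.

## The problem

In a crystal whose single disordered site hosts one of two molecules A and B
(concentrations m_A + m_B = 1), the diffuse scattering factorizes into two
multiplicative components,

    I_D(Q) = I_FF(Q) · I_SRO(Q),

where

    I_FF(Q)  = N · m_A · m_B · |F_A(Q) − F_B(Q)|²,
    F(Q)     = Σ_i f_i(|Q|) · exp(i Q·x_i),
    I_SRO(Q) = N · m_A · m_B · Σ_v α_v · cos(2π (h,k,l)·v),

with f_i the atomic form factor, x_i the atomic positions, v the integer
intermolecular lattice vectors and α_v the Warren–Cowley short-range-order
parameters, α_v = 1 − p_AB(v)/m_B.  The form-factor component is a smooth
envelope carrying structural information about the two molecules; the SRO
component is a lattice-periodic modulation carrying the occupancy
correlations.  Measured data give only the product; separating the factors
is the step that unlocks quantitative analysis of either one.

`diffsep` covers this workflow end to end for method developers and
beamline scientists:

* **simulate** both components on reciprocal-space plane grids for
  arbitrary molecule pairs and SRO models (`diffsep.scatter`,
  `diffsep.sro`);
* **generate** realizable SRO parameter sets by Metropolis annealing of
  occupancy fields toward target nearest-neighbour correlations, or from
  symmetry-restricted damped-oscillator shell models (`diffsep.sro`);
* **assemble** paired, square-root-normalized, detector-artefact-stained
  training datasets with auditable stage counts (`diffsep.dataset`);
* **train** a pair of conditional U-Net image-translation networks — one
  per component, coupled by a product-consistency loss — that learn the
  factorization, and apply them to unseen planes (`diffsep.gan`, on a
  self-contained numpy backprop engine, `diffsep.nn`);
* **refine** Warren–Cowley parameters from a separated I_SRO by folding it
  into one reciprocal cell and solving a linear least-squares cosine-series
  fit with symmetry constraints, and discriminate structural models against
  a separated I_FF via Debye–Waller-corrected torsion scans
  (`diffsep.analysis`).

## Worked example

Simulate a disordered crystal, compose the observable scattering, then
recover the order parameters from the SRO component alone:

```python
import numpy as np
from diffsep.molecules import random_molecule
from diffsep.scatter import reciprocal_basis, PlaneDefinition, i_ff_plane
from diffsep.sro import (mc_generate_configuration, measure_alphas,
                         canonical_vectors, i_sro_plane)
from diffsep.dataset import compose_total
from diffsep import analysis as an

mol_a = random_molecule(seed=1, n_atoms_range=(8, 12))
mol_b = random_molecule(seed=2, n_atoms_range=(8, 12))

# anneal a 24^3 occupancy field to unlike-neighbour order along x
config = mc_generate_configuration(
    m_a=0.5, target_alphas=(-0.3, 0.1, 0.0), dims=(24, 24, 24), seed=0)
model = measure_alphas(config, [v for v in canonical_vectors(3) if v[2] == 0])
print("measured alpha[100] = %.4f, alpha[010] = %.4f" %
      (model.alphas[(1, 0, 0)], model.alphas[(0, 1, 0)]))

recip = reciprocal_basis(7.0, 7.0, 7.0)
plane = PlaneDefinition.axis_plane(recip, (0, 1), offset=0.0,
                                   grid_size=128, q_max=7.0)
iff = i_ff_plane(mol_a, mol_b, model.m_a, model.m_b, plane)
isro = i_sro_plane(model, plane, clip_negative=False)
total = compose_total(iff, isro)
print("I_D peak %.1f, I_SRO modulation %.3f..%.3f" %
      (total.data.max(), isro.data.min(), isro.data.max()))

cell = an.project_to_unit_cell(isro, bins=24)
res = an.refine_alphas(cell, [v for v in model.alphas if v != (0, 0, 0)],
                       an.SymmetryConstraint(rotation_order=1))
print("refined alpha[100] = %.4f (truth %.4f), scale = %.3f, rss = %.2e" %
      (res.alphas[(1, 0)], model.alphas[(1, 0, 0)], res.scale, res.rss))
```

Output:

```
measured alpha[100] = -0.2998, alpha[010] = 0.0998
I_D peak 631.4, I_SRO modulation 0.120..0.692
refined alpha[100] = -0.2988 (truth -0.2998), scale = 0.250, rss = 5.75e-03
```

The annealer hits the requested nearest-neighbour correlation to ~1e-3; the
refinement recovers it from the plane to ~1e-3 (the residual comes from
out-of-plane vectors truncated at the measurement cutoff).  The scale 0.250
is m_A·m_B, as the series predicts.

A command-line layer mirrors the library:
`diffsep build-dataset`, `diffsep train`, `diffsep decompose`,
`diffsep refine-sro`, `diffsep rotate-scan` (see `diffsep --help`).

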