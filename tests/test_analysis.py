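"""Projection, symmetrization, Warren-Cowley refinement, Debye-Waller
correction and torsion-scan model discrimination."""

import numpy as np
import pytest

from diffsep import analysis as an
from diffsep import sro as sro_mod
from diffsep.molecules import Molecule, random_molecule, rotate_group_about_bond
from diffsep.scatter import PlaneDefinition, ScatteringPlane, i_ff_plane

# Warren-Cowley parameters refined from a separated I_SRO of the columnar
# tricarboxamide benchmark (in-plane vectors, sixfold symmetry, v_z = 0).
BENCHMARK_ALPHAS = {
    (1, 0): -0.2474, (2, 0): 0.1094, (2, 1): 0.0824, (3, 0): -0.03075,
    (3, 1): -0.0529, (3, 2): -0.0378, (4, 0): 0.0109, (4, 1): 0.0186,
    (4, 2): 0.0252, (4, 3): 0.0107, (5, 0): -0.0026, (5, 1): -0.0055,
    (5, 2): -0.0104, (5, 3): -0.0086, (5, 4): -0.0037,
}


@pytest.fixture(scope="module")
def hex_recip2(hexagonal_recip):
    b1, b2 = hexagonal_recip[0], hexagonal_recip[1]
    e1 = b1 / np.linalg.norm(b1)
    e2 = b2 - (b2 @ e1) * e1
    e2 /= np.linalg.norm(e2)
    return np.array([[b1 @ e1, b1 @ e2], [b2 @ e1, b2 @ e2]])


class TestProjection:
    def test_periodic_plane_projects_to_single_period(self, cubic_recip):
        model = sro_mod.SROModel(
            m_a=0.5, alphas={(0, 0, 0): 1.0, (1, 0, 0): -0.3, (1, 1, 0): 0.1}
        )
        n, nb = 64, 16
        u = np.arange(n) * (4.0 / n)  # four exact periods, pixels on bin centres
        plane = PlaneDefinition.from_fractional_ranges(cubic_recip, u, u)
        isro = sro_mod.i_sro_plane(model, plane, clip_negative=False)
        cell = an.project_to_unit_cell(isro, bins=nb)
        single = isro.data[:nb, :nb]
        assert np.abs(cell.values - single).max() < 1e-10

    def test_constant_plane_constant_cell(self, small_plane):
        plane = ScatteringPlane(np.full((64, 64), 3.3), small_plane, "SRO")
        cell = an.project_to_unit_cell(plane, bins=16)
        live = ~cell.excluded
        assert np.allclose(cell.values[live], 3.3)

    def test_counts_conserved(self, small_plane):
        rng = np.random.default_rng(0)
        plane = ScatteringPlane(rng.random((64, 64)), small_plane, "SRO")
        cell = an.project_to_unit_cell(plane, bins=16)
        assert cell.counts.sum() == 64 * 64


class TestMaskLowIntensity:
    def test_zero_fraction_excludes_nothing(self, hex_recip2):
        rng = np.random.default_rng(0)
        cell = an.ProjectedCell(rng.random((16, 16)) + 0.1,
                                np.ones((16, 16), int),
                                np.zeros((16, 16), bool), hex_recip2)
        assert not an.mask_low_intensity(cell, 0.0).excluded.any()

    def test_constant_cell_nothing_excluded(self, hex_recip2):
        cell = an.ProjectedCell(np.ones((16, 16)), np.ones((16, 16), int),
                                np.zeros((16, 16), bool), hex_recip2)
        assert not an.mask_low_intensity(cell, 0.05).excluded.any()

    def test_zero_half_exactly_excluded(self, hex_recip2):
        vals = np.ones((16, 16))
        vals[:8] = 0.0
        cell = an.ProjectedCell(vals, np.ones((16, 16), int),
                                np.zeros((16, 16), bool), hex_recip2)
        out = an.mask_low_intensity(cell, 0.05)
        assert out.excluded[:8].all() and not out.excluded[8:].any()


class TestSymmetrize:
    def _random_cell(self, recip2, nb=24, seed=1):
        rng = np.random.default_rng(seed)
        return an.ProjectedCell(rng.random((nb, nb)), np.ones((nb, nb), int),
                                np.zeros((nb, nb), bool), recip2)

    def test_order_one_is_identity(self, hex_recip2):
        cell = self._random_cell(hex_recip2)
        assert an.symmetrize(cell, 1) is cell

    def test_output_invariant_and_idempotent(self, hex_recip2):
        cell = self._random_cell(hex_recip2)
        s1 = an.symmetrize(cell, 6)
        s2 = an.symmetrize(s1, 6)
        assert np.abs(s1.values - s2.values).max() < 1e-12

    def test_symmetric_input_unchanged(self, hex_recip2):
        cell = self._random_cell(hex_recip2)
        sym = an.symmetrize(cell, 6)
        again = an.symmetrize(sym, 6)
        assert np.abs(sym.values - again.values).max() < 1e-10

    def test_sixfold_requires_hexagonal_lattice(self, cubic_recip):
        b2 = np.array([[1.0, 0.0], [0.0, 1.0]])
        cell = an.ProjectedCell(np.ones((8, 8)), np.ones((8, 8), int),
                                np.zeros((8, 8), bool), b2)
        with pytest.raises(ValueError, match="symmetry"):
            an.symmetrize(cell, 6)
        # fourfold is fine on a square lattice
        an.symmetrize(cell, 4)


class TestRefineAlphas:
    def test_benchmark_roundtrip_noiseless(self, hex_recip2):
        """The 15 in-plane alphas of the hexagonal benchmark are recovered
        exactly from a noiseless forward-modelled cell."""
        cell = an.synthesize_cell(BENCHMARK_ALPHAS, hex_recip2, bins=64, order=6,
                                  scale=2.9)
        res = an.refine_alphas(
            cell, list(BENCHMARK_ALPHAS.keys()),
            an.SymmetryConstraint(rotation_order=6),
        )
        for v, truth in BENCHMARK_ALPHAS.items():
            assert abs(res.alphas[v] - truth) <= 1e-8
        assert res.scale == pytest.approx(2.9, rel=1e-10)
        assert res.rss < 1e-16

    def test_flat_cell_gives_zero_alphas(self, hex_recip2):
        cell = an.synthesize_cell({(1, 0): 0.0, (2, 0): 0.0}, hex_recip2,
                                  bins=32, order=6, scale=1.7)
        res = an.refine_alphas(cell, [(1, 0), (2, 0)],
                               an.SymmetryConstraint(rotation_order=6))
        assert max(abs(a) for a in res.alphas.values()) < 1e-12
        assert res.scale == pytest.approx(1.7)

    def test_noisy_recovery_within_tolerance(self, hex_recip2):
        cell = an.synthesize_cell(BENCHMARK_ALPHAS, hex_recip2, bins=64, order=6)
        devs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = an.ProjectedCell(
                cell.values + rng.normal(0, 0.05 * cell.values.max(),
                                         cell.values.shape),
                cell.counts, cell.excluded, cell.recip2,
            )
            res = an.refine_alphas(noisy, list(BENCHMARK_ALPHAS.keys()),
                                   an.SymmetryConstraint(rotation_order=6))
            devs.append(np.mean([abs(res.alphas[v] - BENCHMARK_ALPHAS[v])
                                 for v in BENCHMARK_ALPHAS]))
        assert np.mean(devs) <= 0.01

    def test_vz_exclusion_predicate(self, hex_recip2):
        cell = an.synthesize_cell({(1, 0): -0.2}, hex_recip2, bins=32, order=6)
        res = an.refine_alphas(
            cell, [(1, 0, 0), (1, 0, 1)],
            an.SymmetryConstraint(rotation_order=6, exclude_nonzero_vz=True),
        )
        assert set(res.alphas) == {(1, 0)}

    def test_all_bins_excluded_raises(self, hex_recip2):
        cell = an.synthesize_cell({(1, 0): -0.2}, hex_recip2, bins=16, order=6)
        cell.excluded[...] = True
        with pytest.raises(an.SingularDesignError):
            an.refine_alphas(cell, [(1, 0)], an.SymmetryConstraint(rotation_order=6))

    def test_end_to_end_config_to_refined_alphas(self, cubic_recip):
        """Simulated configuration -> I_SRO plane -> projection -> refinement
        recovers the measured alphas of the first shells."""
        cfg = sro_mod.mc_generate_configuration(
            0.5, (-0.3, 0.15, 0.0), dims=(24, 24, 24), seed=3
        )
        vecs = [v for v in sro_mod.canonical_vectors(3) if v[2] == 0]
        model = sro_mod.measure_alphas(cfg, vecs)
        plane = PlaneDefinition.axis_plane(cubic_recip, (0, 1), offset=0.0,
                                           grid_size=64, q_max=7.0)
        isro = sro_mod.i_sro_plane(model, plane, clip_negative=False)
        cell = an.project_to_unit_cell(isro, bins=24)
        res = an.refine_alphas(cell, [v for v in vecs if v != (0, 0, 0)],
                               an.SymmetryConstraint(rotation_order=1))
        for v in [(1, 0, 0), (0, 1, 0), (1, 1, 0)]:
            assert abs(res.alphas[(v[0], v[1])] - model.alphas[v]) <= 0.02


class TestDebyeWaller:
    def test_zero_b_is_identity(self, small_plane, mol_pair):
        a, b = mol_pair
        iff = i_ff_plane(a, b, 0.5, 0.5, small_plane)
        out = an.dw_correct(iff, an.DebyeWallerModel(0.0))
        assert np.array_equal(out.data, iff.data)

    def test_damping_monotone_in_q(self, offset_plane, mol_pair):
        a, b = mol_pair
        iff = i_ff_plane(a, b, 0.5, 0.5, offset_plane)
        out = an.dw_correct(iff, an.DebyeWallerModel(3.0))
        ratio = out.data / np.maximum(iff.data, 1e-300)
        q = offset_plane.q_magnitude
        order = np.argsort(q.ravel())
        r_sorted = ratio.ravel()[order]
        assert np.all(np.diff(r_sorted) <= 1e-12)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            an.DebyeWallerModel(-1.0)

    def test_b_recovery_within_one_percent(self, small_plane, mol_pair):
        a, _ = mol_pair
        iff = i_ff_plane(a, Molecule.vacancy(), 0.5, 0.5, small_plane)
        true_b = 2.5
        damped = an.dw_correct(iff, an.DebyeWallerModel(true_b))
        fit, scale = an.fit_b_factor(iff, damped)
        assert fit.b_iso == pytest.approx(true_b, rel=0.01)
        assert scale == pytest.approx(1.0, rel=1e-6)


@pytest.fixture(scope="module")
def rotor():
    return random_molecule(9, (10, 10), extent=5.0)


class TestRotationScan:
    def test_self_consistency_minimum_at_truth(self, rotor, small_plane):
        theta0 = 0.35
        ref = i_ff_plane(
            rotate_group_about_bond(rotor, 0, 1, [2, 3, 4], theta0),
            Molecule.vacancy(), 0.5, 0.5, small_plane,
        )
        angles, mses, best = an.rotation_scan(
            rotor, (0, 1), [2, 3, 4], np.linspace(-1.0, 1.0, 41), ref
        )
        assert best == pytest.approx(theta0, abs=1e-9)
        assert mses.min() < 1e-20

    def test_invariant_under_reference_rescaling(self, rotor, small_plane):
        ref = i_ff_plane(rotor, Molecule.vacancy(), 0.5, 0.5, small_plane)
        grid = np.linspace(-0.5, 0.5, 11)
        _, m1, _ = an.rotation_scan(rotor, (0, 1), [2, 3], grid, ref)
        _, m2, _ = an.rotation_scan(rotor, (0, 1), [2, 3],
                                    grid, ref.with_data(7.7 * ref.data))
        assert np.abs(m1 - m2).max() < 1e-12

    def test_threefold_rotor_has_periodic_curve(self, small_plane):
        """A rotor with exact 3-fold symmetry gives a 120-degree-periodic
        MSE curve."""
        base = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.5]])
        arm = np.array([1.2, 0.0, 2.2])
        rot120 = np.array([
            [-0.5, -np.sqrt(3) / 2, 0], [np.sqrt(3) / 2, -0.5, 0], [0, 0, 1]
        ])
        arms = [arm, rot120 @ arm, rot120 @ rot120 @ arm]
        coords = np.vstack([base, arms])
        mol = Molecule.from_arrays("rotor3", ["N", "C", "C", "C", "C"], coords)
        ref = i_ff_plane(mol, Molecule.vacancy(), 0.5, 0.5, small_plane)
        grid = np.radians(np.arange(-180.0, 180.0, 15.0))
        _, mses, _ = an.rotation_scan(mol, (0, 1), [2, 3, 4], grid, ref)
        shifted = np.roll(mses, 120 // 15)  # one 120-degree period
        assert np.abs(mses - shifted).max() < 1e-10
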