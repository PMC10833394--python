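"""Warren-Cowley measurement, MC generation, oscillator models, I_SRO."""

import numpy as np
import pytest

from diffsep.scatter import PlaneDefinition
from diffsep.sro import (
    DegenerateConfigurationError,
    OccupancyConfiguration,
    OscillatorParams,
    SROModel,
    canonical_vectors,
    cubic_shells,
    direct_sum_oracle,
    i_sro_plane,
    mc_generate_configuration,
    measure_alphas,
    oscillator_alphas,
    sample_realistic_sro,
)

AXES = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


def checkerboard(n=8):
    return OccupancyConfiguration(np.indices((n, n, n)).sum(axis=0) % 2 == 0)


class TestMeasureAlphas:
    def test_zero_vector_alpha_is_one(self):
        cfg = checkerboard()
        assert measure_alphas(cfg, [(0, 0, 0)]).alphas[(0, 0, 0)] == 1.0

    def test_checkerboard_nearest_neighbour(self):
        model = measure_alphas(checkerboard(), AXES)
        for v in AXES:
            assert model.alphas[v] == pytest.approx(-1.0, abs=1e-12)

    def test_random_config_alpha_within_binomial_bound(self):
        n = 32
        devs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cfg = OccupancyConfiguration(rng.random((n, n, n)) < 0.5)
            devs.append(abs(measure_alphas(cfg, AXES).alphas[(1, 0, 0)]))
        assert max(devs) <= 4 / np.sqrt(n**3)

    def test_degenerate_configuration_rejected(self):
        cfg = OccupancyConfiguration(np.ones((8, 8, 8), dtype=bool))
        with pytest.raises(DegenerateConfigurationError):
            measure_alphas(cfg, AXES)

    def test_alpha_symmetric_under_negation(self):
        rng = np.random.default_rng(3)
        cfg = OccupancyConfiguration(rng.random((10, 10, 10)) < 0.4)
        model = measure_alphas(cfg, [(2, 1, 0), (-2, -1, 0)])
        assert model.alphas[(2, 1, 0)] == pytest.approx(
            model.alphas[(-2, -1, 0)], abs=1e-12
        )


class TestMCGeneration:
    def test_zero_targets_reach_low_cost(self):
        cfg = mc_generate_configuration(0.5, (0, 0, 0), dims=(24, 24, 24), seed=0)
        model = measure_alphas(cfg, AXES)
        assert sum(model.alphas[v] ** 2 for v in AXES) < 1e-3

    def test_negative_target_recovered(self):
        cfg = mc_generate_configuration(
            0.5, (-0.5, 0.0, 0.0), dims=(24, 24, 24), seed=1
        )
        a = measure_alphas(cfg, AXES).alphas[(1, 0, 0)]
        assert -0.55 <= a <= -0.45

    def test_swap_moves_conserve_composition(self):
        dims = (12, 12, 12)
        n_sites = np.prod(dims)
        target_na = round(0.37 * n_sites)
        cfg = mc_generate_configuration(0.37, (0.2, -0.1, 0.0), dims=dims, seed=2,
                                        sweeps=40)
        assert int(cfg.labels.sum()) == target_na

    def test_infeasible_target_rejected(self):
        # at m_A = 0.3, alpha = -0.9 implies p_AB = 0.7 * 1.9 > 1
        with pytest.raises(ValueError, match="feasible"):
            mc_generate_configuration(0.3, (-0.9, 0, 0), seed=0)


class TestSampleRealisticSRO:
    def test_different_seeds_differ(self):
        a = sample_realistic_sro(1, vector_cutoff=2, dims=(12, 12, 12), sweeps=40)
        b = sample_realistic_sro(2, vector_cutoff=2, dims=(12, 12, 12), sweeps=40)
        assert a.alphas != b.alphas

    def test_all_alphas_imply_valid_probabilities(self):
        model = sample_realistic_sro(3, vector_cutoff=3, dims=(12, 12, 12), sweeps=40)
        model.validate_feasible()
        assert model.alphas[(0, 0, 0)] == 1.0

    def test_deterministic_under_seed(self):
        a = sample_realistic_sro(5, vector_cutoff=2, dims=(12, 12, 12), sweeps=40)
        b = sample_realistic_sro(5, vector_cutoff=2, dims=(12, 12, 12), sweeps=40)
        assert a.alphas == b.alphas and a.m_a == b.m_a


class TestOscillator:
    def test_no_oscillation_positive_decreasing(self):
        p = OscillatorParams(amplitude=1.0, decay=0.5, frequency=0.0)
        vals = [p.alpha(x) for x in range(1, 6)]
        assert all(v > 0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_strong_decay_bound(self):
        p = OscillatorParams(amplitude=1.5, decay=1.2, frequency=0.3)
        assert all(abs(p.alpha(x)) < 0.46 for x in range(1, 10))

    def test_model_feasible_after_clamp(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = OscillatorParams(
                amplitude=float(rng.uniform(0.6, 1.5)),
                decay=float(rng.uniform(0.1, 1.2)),
                frequency=float(rng.uniform(0, 1)),
            )
            model = oscillator_alphas(p)
            bound = 1.5 * np.exp(-0.1)
            for v, a in model.alphas.items():
                if v != (0, 0, 0):
                    assert -bound < a < bound
            model.validate_feasible()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            OscillatorParams(amplitude=2.0, decay=0.5, frequency=0.5)

    def test_shells_share_alpha(self):
        model = oscillator_alphas(OscillatorParams(1.0, 0.4, 0.7))
        shells = cubic_shells(5)
        for x in set(shells.values()):
            vals = {model.alphas[v] for v, s in shells.items() if s == x}
            assert len(vals) == 1


class TestISROPlane:
    def test_constant_term_only_gives_flat_plane(self, small_plane):
        model = SROModel(m_a=0.5, alphas={(0, 0, 0): 1.0})
        out = i_sro_plane(model, small_plane, scale=4.0)
        assert np.allclose(out.data, 4.0 * 0.25)

    def test_single_alpha_closed_form(self, small_plane):
        a = 0.3
        model = SROModel(m_a=0.5, alphas={(0, 0, 0): 1.0, (1, 0, 0): a})
        out = i_sro_plane(model, small_plane, clip_negative=False)
        h = small_plane.fractional_coords[..., 0]
        expected = 0.25 * (1 + 2 * a * np.cos(2 * np.pi * h))
        assert np.abs(out.data - expected).max() < 1e-10

    def test_periodic_under_integer_shift(self, cubic_recip):
        model = SROModel(
            m_a=0.4, alphas={(0, 0, 0): 1.0, (1, 0, 0): -0.2, (1, 1, 0): 0.1}
        )
        n = 16
        u = np.arange(n) / n
        base = PlaneDefinition.from_fractional_ranges(cubic_recip, u, u)
        shifted = PlaneDefinition.from_fractional_ranges(cubic_recip, u + 1.0, u + 1.0)
        i0 = i_sro_plane(model, base, clip_negative=False)
        i1 = i_sro_plane(model, shifted, clip_negative=False)
        assert np.abs(i0.data - i1.data).max() < 1e-10

    def test_clipping_logs_and_clips(self, small_plane, caplog):
        model = SROModel(m_a=0.5, alphas={(0, 0, 0): 1.0, (1, 0, 0): -0.9})
        with caplog.at_level("INFO", logger="diffsep.sro"):
            out = i_sro_plane(model, small_plane)
        assert out.data.min() == 0.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_missing_zero_vector_rejected(self, small_plane):
        with pytest.raises(ValueError):
            SROModel(m_a=0.5, alphas={(1, 0, 0): 0.1})


class TestOracleEquivalence:
    def test_all_a_config_rejected_but_uniform_mix_flat(self, cubic_recip):
        rng = np.random.default_rng(0)
        labels = rng.random((8, 8, 8)) < 0.5
        cfg = OccupancyConfiguration(labels)
        u = np.arange(8) / 8
        plane = PlaneDefinition.from_fractional_ranges(cubic_recip, u, u)
        oracle = direct_sum_oracle(cfg, plane)
        assert oracle.data.min() >= 0

    def test_checkerboard_peaks_at_zone_boundary(self, cubic_recip):
        cfg = checkerboard(8)
        u = np.arange(16) / 8  # allowed points, two cells
        plane = PlaneDefinition.from_fractional_ranges(
            cubic_recip, u, u, offset=0.5
        )
        oracle = direct_sum_oracle(cfg, plane)
        peak = np.unravel_index(np.argmax(oracle.data), oracle.data.shape)
        h, k = u[peak[0]], u[peak[1]]
        assert h % 1 == 0.5 and k % 1 == 0.5

    def test_cosine_series_matches_direct_sum_on_box(self, cubic_recip):
        """Measured alphas over all in-box vectors reproduce the direct
        occupancy sum exactly at the supercell's allowed reciprocal points."""
        L = 16
        cfg = mc_generate_configuration(
            0.5, (-0.25, 0.15, 0.05), dims=(L, L, L), seed=7, sweeps=80
        )
        box = [(a, b, c) for a in range(L) for b in range(L) for c in range(L)]
        model = measure_alphas(cfg, box)
        u = np.arange(2 * L) / L - 1.0
        plane = PlaneDefinition.from_fractional_ranges(cubic_recip, u, u, offset=0.0)
        series = i_sro_plane(model, plane, weighting="explicit", clip_negative=False)
        oracle = direct_sum_oracle(cfg, plane)
        rel = np.abs(series.data - oracle.data).max() / oracle.data.max()
        assert rel <= 0.01

    def test_size_guard(self, cubic_recip):
        cfg = OccupancyConfiguration(np.zeros((33, 33, 33), dtype=bool))
        u = np.arange(8) / 8.0
        plane = PlaneDefinition.from_fractional_ranges(cubic_recip, u, u)
        with pytest.raises(ValueError, match="32"):
            direct_sum_oracle(cfg, plane)


def test_model_tsv_roundtrip(tmp_path):
    model = SROModel(m_a=0.45, alphas={(0, 0, 0): 1.0, (1, 0, 0): -0.123456,
                                       (2, 1, 0): 0.05})
    path = tmp_path / "model.tsv"
    model.to_tsv(path)
    back = SROModel.from_tsv(path)
    assert back.m_a == model.m_a
    assert back.alphas == model.alphas


def test_canonical_vectors_cover_half_space():
    vecs = canonical_vectors(2)
    assert (0, 0, 0) in vecs
    assert len(vecs) == (5**3 - 1) // 2 + 1
    for v in vecs:
        if v != (0, 0, 0):
            assert tuple(-c for c in v) not in vecs
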