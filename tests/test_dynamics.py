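import numpy as np
import pytest

from contactseer.dynamics import (
    dynamic_index,
    hull_volume,
    migration_map,
    order_by_pseudotime,
    pseudo_bulk,
    reconstruct_3d,
    sample_interactions,
    switch_map,
    vibration_map,
    volume_series,
)


class TestOrderByPseudotime:
    def test_hand_sort(self):
        order = order_by_pseudotime([0.3, 0.1, 0.2])
        assert order.delta.tolist() == [1, 2, 0]
        assert order.sorted_t.tolist() == [0.1, 0.2, 0.3]

    def test_sorted_input_gives_identity(self):
        assert order_by_pseudotime([1.0, 2.0, 3.0]).delta.tolist() == [0, 1, 2]

    def test_ties_keep_original_order(self):
        assert order_by_pseudotime([0.5, 0.5]).delta.tolist() == [0, 1]

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            order_by_pseudotime([0.1, float("nan")])


class TestSampleInteractions:
    def test_single_nonzero_entry_localizes_draws(self):
        m = np.zeros((5, 5))
        m[2, 3] = 7.0
        pts = sample_interactions(m, 100, jitter_bins=1.0, rng_seed=0)
        assert np.all(np.abs(pts[:, 0] - 2) <= 0.5)
        assert np.all(np.abs(pts[:, 1] - 3) <= 0.5)

    def test_sampling_proportional_to_contact_value(self):
        m = np.zeros((2, 2))
        m[0, 0], m[1, 1] = 9.0, 1.0
        pts = sample_interactions(m, 10_000, jitter_bins=0.0, rng_seed=1)
        frac_a = np.mean((pts[:, 0] < 0.5) & (pts[:, 1] < 0.5))
        assert frac_a == pytest.approx(0.9, abs=0.01)

    def test_seed_reproducibility(self):
        m = np.arange(9).reshape(3, 3).astype(float)
        a = sample_interactions(m, 50, rng_seed=5)
        b = sample_interactions(m, 50, rng_seed=5)
        np.testing.assert_array_equal(a, b)

    def test_zero_map_rejected(self):
        with pytest.raises(ValueError):
            sample_interactions(np.zeros((3, 3)), 10)


class TestMigrationMap:
    def test_single_point_populates_one_cell(self):
        raw, _ = migration_map(np.array([[0.6, 1.2]]), np.array([0.5]),
                               K_h=2, factor=2, upsample=None)
        assert raw.M[1, 2] == pytest.approx(0.5)
        filled = ~np.isnan(raw.M)
        assert filled.sum() == 1

    def test_cell_value_is_mean_pseudotime(self):
        pts = np.array([[0.1, 0.1], [0.2, 0.2]])
        raw, _ = migration_map(pts, np.array([0.2, 0.4]), K_h=2, factor=2,
                               upsample=None)
        assert raw.M[0, 0] == pytest.approx(0.3)

    def test_constant_field_interpolates_constant(self, rng):
        pts = rng.uniform(0, 4, size=(200, 2))
        t = np.full(200, 0.7)
        raw, fine = migration_map(pts, t, K_h=4, factor=2, upsample=5)
        assert np.nanmax(np.abs(raw.M - 0.7)) < 1e-12
        inside = ~np.isnan(fine.M)
        assert inside.any()
        assert np.nanmax(np.abs(fine.M[inside] - 0.7)) < 1e-6

    def test_count_weighted_mean_conserves_total(self, rng):
        pts = rng.uniform(0, 3, size=(50, 2))
        t = rng.uniform(0, 1, size=50)
        raw, _ = migration_map(pts, t, K_h=3, factor=2, upsample=None)
        counts = np.zeros_like(raw.M)
        a = np.floor(pts[:, 0] * 2).astype(int)
        b = np.floor(pts[:, 1] * 2).astype(int)
        np.add.at(counts, (a, b), 1)
        filled = counts > 0
        weighted = np.nansum(raw.M[filled] * counts[filled]) / counts.sum()
        assert weighted == pytest.approx(t.mean(), abs=1e-9)


class TestVibrationSwitch:
    def test_constant_stack_gives_zero_maps(self):
        maps = np.ones((4, 3, 3))
        assert vibration_map(maps).max() == 0
        assert switch_map(maps).max() == 0

    def test_hand_vibration_value(self):
        maps = np.zeros((3, 2, 2))
        maps[:, 0, 1] = [1, 4, 2]
        xv = vibration_map(maps)
        assert xv[0, 1] == pytest.approx(2.5)  # (|3| + |-2|) / 2

    def test_hand_switch_value(self):
        maps = np.zeros((3, 1, 1))
        maps[:, 0, 0] = [0, 3, 4]  # steps 3, 1 -> X_v = 2 -> indicators 1, 0
        xs = switch_map(maps)
        assert xs[0, 0] == pytest.approx(0.5)

    def test_absolute_homogeneity(self, rng):
        maps = rng.normal(size=(5, 4, 4))
        np.testing.assert_allclose(vibration_map(-3 * maps),
                                   3 * vibration_map(maps))

    def test_switch_in_unit_interval_and_never_all_ones(self, rng):
        for _ in range(20):
            maps = rng.normal(size=(6, 4, 4))
            xs = switch_map(maps)
            assert xs.min() >= 0 and xs.max() <= 1
            assert not np.all(xs == 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_loops(self, seed):
        rng = np.random.default_rng(seed)
        maps = rng.normal(size=(6, 4, 4))
        n = maps.shape[0]
        xv = np.zeros((4, 4))
        for i in range(n - 1):
            xv += np.abs(maps[i + 1] - maps[i])
        xv /= n - 1
        xs = np.zeros((4, 4))
        for i in range(n - 1):
            xs += (np.abs(maps[i + 1] - maps[i]) > xv).astype(float)
        xs /= n - 1
        np.testing.assert_allclose(vibration_map(maps), xv, atol=1e-12)
        np.testing.assert_allclose(switch_map(maps), xs, atol=1e-12)

    def test_too_few_maps_rejected(self):
        with pytest.raises(ValueError):
            vibration_map(np.ones((1, 2, 2)))


class TestDynamicIndex:
    def test_tie_rule_takes_lexicographic_first(self):
        xv = np.ones((5, 5))
        entries, mask = dynamic_index(xv, 0.05)
        assert entries[0][:2] == (0, 1)
        assert mask.sum() == 2  # one interaction, symmetric positions

    def test_dominant_entry_ranks_first(self):
        xv = np.zeros((4, 4))
        xv[1, 3] = xv[3, 1] = 9.0
        entries, mask = dynamic_index(xv, 0.2)
        assert entries[0][:2] == (1, 3)
        assert mask[1, 3] and mask[3, 1]

    def test_matches_sort_oracle(self, rng):
        xv = rng.random((6, 6))
        xv = (xv + xv.T) / 2
        entries, _ = dynamic_index(xv, 1.0)
        vals = [e[2] for e in entries]
        assert vals == sorted(vals, reverse=True)
        iu, ju = np.triu_indices(6, 1)
        assert len(entries) == len(iu)


class TestPseudoBulk:
    def test_identical_maps(self, stack_factory):
        m = np.arange(16).reshape(4, 4).astype(float)
        m = (m + m.T) / 2
        stack = stack_factory([m, m, m])
        np.testing.assert_allclose(pseudo_bulk(stack), m)

    def test_hand_two_map_average(self):
        a = np.zeros((2, 2))
        b = np.full((2, 2), 4.0)
        np.testing.assert_allclose(pseudo_bulk(np.stack([a, b])),
                                   np.full((2, 2), 2.0))

    def test_linearity(self, rng):
        maps = rng.random((4, 3, 3))
        np.testing.assert_allclose(pseudo_bulk(5 * maps), 5 * pseudo_bulk(maps))


class TestReconstruct3D:
    def test_two_block_map_separates_blocks(self):
        k = 8
        m = np.full((k, k), 0.1)
        m[:4, :4] = 5.0
        m[4:, 4:] = 5.0
        np.fill_diagonal(m, 10.0)
        coords = reconstruct_3d(m)
        from scipy.spatial.distance import cdist

        d = cdist(coords, coords)
        within = np.concatenate([d[:4, :4][np.triu_indices(4, 1)],
                                 d[4:, 4:][np.triu_indices(4, 1)]])
        between = d[:4, 4:].ravel()
        assert within.mean() < between.mean()

    def test_uniform_map_gives_near_uniform_distances(self):
        m = np.full((6, 6), 2.0)
        coords = reconstruct_3d(m)
        from scipy.spatial.distance import pdist

        d = pdist(coords)
        assert d.std() / d.mean() < 0.2

    def test_deterministic(self, rng):
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.testing.assert_array_equal(reconstruct_3d(m, rng_seed=3),
                                      reconstruct_3d(m, rng_seed=3))

    def test_too_small_map_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_3d(np.ones((3, 3)))


class TestHullVolume:
    def test_unit_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        assert hull_volume(pts) == pytest.approx(1 / 6, abs=1e-9)

    def test_unit_cube(self):
        pts = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                        for k in (0, 1)], dtype=float)
        assert hull_volume(pts) == pytest.approx(1.0, abs=1e-9)

    def test_coplanar_points_give_zero_with_warning(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.warns(UserWarning):
            assert hull_volume(pts) == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hull_volume(np.zeros((3, 3)))


class TestVolumeSeries:
    def test_shapes(self, rng):
        maps = rng.random((100, 6, 6))
        vs = volume_series(maps, windows=10)
        assert vs.volumes.shape == (10,) and vs.delta_volumes.shape == (9,)

    def test_identical_maps_give_flat_series(self):
        m = np.random.default_rng(0).random((6, 6))
        m = (m + m.T) / 2
        maps = np.stack([m] * 20)
        vs = volume_series(maps, windows=4)
        np.testing.assert_allclose(vs.delta_volumes, 0, atol=1e-9)

    def test_planted_decompaction_grows_volume(self):
        rng = np.random.default_rng(1)
        n, k = 80, 10
        maps = []
        for i in range(n):
            frac = i / (n - 1)
            m = np.full((k, k), 0.5)
            m[:5, :5] += 8.0 * (1 - frac)  # block contacts weaken over time
            m = (m + m.T) / 2
            maps.append(m + rng.random((k, k)) * 0.01)
        vs = volume_series(np.stack(maps), windows=8)
        from scipy.stats import spearmanr

        rho = spearmanr(np.arange(8), vs.volumes).statistic
        assert rho > 0

    def test_more_windows_than_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            volume_series(rng.random((3, 5, 5)), windows=5)
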