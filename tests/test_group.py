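"""Group-inference tests: permutation ensembles, bootstrap null support,
voxelwise thresholding self-consistency, clustering, and BH-FDR."""

import numpy as np
import pytest

from sentencode.encoding import GeneralizationMap
from sentencode.errors import SentencodeError
from sentencode.group import (
    AnalysisConfig,
    GroupNull,
    bootstrap_group_null,
    null_fpr,
    permutation_maps,
    threshold_and_cluster,
    voxelwise_pvalues,
)
from sentencode.simulate import VoxelGrid


def _gmap(data, grid, pid="sub-01"):
    return GeneralizationMap(
        data=data, grid=grid, participant_id=pid, model_name="bag_of_verbs"
    )


class TestConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(SentencodeError):
            AnalysisConfig(voxel_p=0.0)
        with pytest.raises(SentencodeError):
            AnalysisConfig(connectivity=10)

    def test_connectivity_structures(self):
        assert AnalysisConfig(connectivity=6).structure.sum() == 7
        assert AnalysisConfig(connectivity=18).structure.sum() == 19
        assert AnalysisConfig(connectivity=26).structure.sum() == 27


@pytest.fixture(scope="module")
def perms(planted_dataset):
    cfg = AnalysisConfig(n_perm_per_subject=6, n_bootstrap=50, seed=42, fwhm_mm=0.0)
    return permutation_maps(planted_dataset, "narrow_roles", cfg), cfg


@pytest.fixture(scope="module")
def iid_null():
    grid = VoxelGrid.box((10, 10, 10))
    rng = np.random.default_rng(7)
    values = rng.standard_normal((grid.n_mask_voxels, 800))
    return GroupNull(values=values, grid=grid), rng


class TestPermutationMaps:
    def test_count_per_participant(self, perms, planted_dataset):
        maps, cfg = perms
        assert set(maps) == {p.participant_id for p in planted_dataset.participants}
        assert all(len(v) == 6 for v in maps.values())

    def test_identical_seed_identical_schedule(self, perms, planted_dataset):
        maps, cfg = perms
        again = permutation_maps(planted_dataset, "narrow_roles", cfg)
        for pid in maps:
            for a, b in zip(maps[pid], again[pid]):
                np.testing.assert_array_equal(a.data, b.data)

    def test_planted_voxels_centered_under_permutation(self, perms, planted_dataset):
        """Mean over permutations at planted voxels within 3 SE of 0."""
        maps, _ = perms
        blob = planted_dataset.truth.labeled_mask("narrow_roles")
        vals = np.array(
            [m.data[blob].mean() for pm in maps.values() for m in pm]
        )
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se


class TestBootstrapNull:
    def test_support_is_cartesian_combinations(self):
        """With 2 subjects x 2 permutation maps, every bootstrap group mean
        equals the average of one of the 4 possible pairs."""
        grid = VoxelGrid.box((8, 8, 8))
        rng = np.random.default_rng(0)
        maps = {
            pid: [
                _gmap(rng.standard_normal(grid.dims), grid, pid) for _ in range(2)
            ]
            for pid in ("sub-01", "sub-02")
        }
        cfg = AnalysisConfig(n_bootstrap=16, seed=1)
        null = bootstrap_group_null(maps, cfg)
        combos = np.stack(
            [
                (maps["sub-01"][i].data.ravel() + maps["sub-02"][j].data.ravel()) / 2
                for i in range(2)
                for j in range(2)
            ]
        )
        for b in range(null.n_bootstrap):
            dists = np.abs(combos - null.values[:, b]).max(axis=1)
            assert dists.min() < 1e-12

    def test_shape_matches_config(self):
        grid = VoxelGrid.box((8, 8, 8))
        rng = np.random.default_rng(0)
        maps = {
            pid: [_gmap(rng.standard_normal(grid.dims), grid, pid)]
            for pid in ("a", "b", "c")
        }
        null = bootstrap_group_null(maps, AnalysisConfig(n_bootstrap=123, seed=0))
        assert null.values.shape == (grid.n_mask_voxels, 123)

    def test_empty_or_single_participant_rejected(self):
        grid = VoxelGrid.box((8, 8, 8))
        with pytest.raises(SentencodeError):
            bootstrap_group_null({}, AnalysisConfig(n_bootstrap=4))
        with pytest.raises(SentencodeError):
            bootstrap_group_null(
                {"a": [_gmap(np.zeros(grid.dims), grid)]},
                AnalysisConfig(n_bootstrap=4),
            )


class TestThresholdAndCluster:
    def test_null_draw_suprathreshold_rate(self, iid_null):
        """An observed map drawn from the null has ~voxel_p suprathreshold
        voxels (binomial tolerance)."""
        null, rng = iid_null
        cfg = AnalysisConfig(n_bootstrap=800, voxel_p=0.05, seed=0)
        rates = []
        for b in range(30):
            obs3d = np.zeros(null.grid.dims)
            obs3d.ravel()[: null.values.shape[0]] = rng.standard_normal(
                null.values.shape[0]
            )
            res = threshold_and_cluster(obs3d, null, cfg)
            rates.append(res.suprathreshold.mean())
        n = 30 * null.values.shape[0]
        se = np.sqrt(0.05 * 0.95 / n)
        assert np.mean(rates) == pytest.approx(0.05, abs=4 * se)

    def test_single_isolated_voxel_is_cluster_of_one(self):
        grid = VoxelGrid.box((8, 8, 8))
        rng = np.random.default_rng(3)
        values = rng.standard_normal((grid.n_mask_voxels, 400))
        null = GroupNull(values=values, grid=grid)
        obs = np.zeros(grid.dims)
        obs[4, 4, 4] = 1e6
        cfg = AnalysisConfig(n_bootstrap=400, voxel_p=0.005, seed=0)
        res = threshold_and_cluster(obs, null, cfg)
        assert res.suprathreshold.sum() == 1
        assert len(res.clusters) == 1 and res.clusters[0].size == 1
        assert res.clusters[0].peak == (4, 4, 4)

    def test_no_suprathreshold_is_empty_not_error(self):
        grid = VoxelGrid.box((8, 8, 8))
        rng = np.random.default_rng(4)
        null = GroupNull(
            values=rng.standard_normal((grid.n_mask_voxels, 200)), grid=grid
        )
        res = threshold_and_cluster(
            np.full(grid.dims, -10.0), null, AnalysisConfig(n_bootstrap=200)
        )
        assert res.clusters == [] and not res.suprathreshold.any()

    def test_qvalues_match_independent_bh(self):
        """Cluster q-values equal an independently coded Benjamini-Hochberg
        transform of the cluster p-values."""
        grid = VoxelGrid.box((10, 10, 10))
        rng = np.random.default_rng(5)
        null = GroupNull(
            values=rng.standard_normal((grid.n_mask_voxels, 300)), grid=grid
        )
        obs = np.zeros(grid.dims)
        # several separated blobs of different sizes
        obs[1:3, 1:3, 1:3] = 50
        obs[7:9, 7:9, 7:9] = 40
        obs[1, 8, 1] = 30
        cfg = AnalysisConfig(n_bootstrap=300, voxel_p=0.01, seed=0)
        res = threshold_and_cluster(obs, null, cfg)
        assert len(res.clusters) >= 2
        p = np.array([c.p_uncorrected for c in res.clusters])
        # oracle BH: q_i = min_{j: p_j >= p_i} (m * p_j / rank_j)
        m = len(p)
        order = np.argsort(p)
        q_sorted = (p[order] * m / np.arange(1, m + 1))[::-1]
        q_sorted = np.minimum.accumulate(q_sorted)[::-1]
        q_oracle = np.empty(m)
        q_oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(
            [c.q_fdr for c in res.clusters], q_oracle, atol=1e-12
        )

    def test_cluster_monotone_in_effect_size(self):
        """Enlarging a planted effect never shrinks its recovered cluster."""
        grid = VoxelGrid.box((10, 10, 10))
        rng = np.random.default_rng(6)
        null = GroupNull(
            values=rng.standard_normal((grid.n_mask_voxels, 300)), grid=grid
        )
        cfg = AnalysisConfig(n_bootstrap=300, voxel_p=0.01, seed=0)
        base = rng.standard_normal(grid.dims) * 0.1
        from sentencode.simulate import sphere_mask

        blob = sphere_mask(grid.dims, (5, 5, 5), 2.5)
        sizes = []
        for amp in (2.0, 4.0, 8.0, 16.0):
            obs = base + amp * blob
            res = threshold_and_cluster(obs, null, cfg)
            sizes.append(max((c.size for c in res.clusters), default=0))
        assert sizes == sorted(sizes)

    def test_global_height_mode(self):
        grid = VoxelGrid.box((8, 8, 8))
        rng = np.random.default_rng(8)
        null = GroupNull(
            values=rng.standard_normal((grid.n_mask_voxels, 200)), grid=grid
        )
        cfg = AnalysisConfig(
            n_bootstrap=200, voxel_p=0.01, seed=0, height_mode="global"
        )
        obs = np.zeros(grid.dims)
        obs[2, 2, 2] = 100.0
        res = threshold_and_cluster(obs, null, cfg)
        assert res.suprathreshold[2, 2, 2]


class TestCalibrationHelpers:
    def test_null_fpr_matches_voxel_p_on_iid_null(self):
        grid = VoxelGrid.box((10, 10, 10))
        rng = np.random.default_rng(9)
        null = GroupNull(
            values=rng.standard_normal((grid.n_mask_voxels, 500)), grid=grid
        )
        cfg = AnalysisConfig(n_bootstrap=500, voxel_p=0.05, seed=0)
        rate = null_fpr(null, cfg)
        # exact discrete rate: floor(p*(B+1))/B
        expected = np.floor(0.05 * 501) / 500
        assert rate == pytest.approx(expected, abs=3 * np.sqrt(0.05 * 0.95 / 500))

    def test_voxelwise_pvalues_range_and_outside_mask(self):
        grid = VoxelGrid.box((8, 8, 8))
        rng = np.random.default_rng(10)
        null = GroupNull(
            values=rng.standard_normal((grid.n_mask_voxels, 100)), grid=grid
        )
        p = voxelwise_pvalues(rng.standard_normal(grid.dims), null)
        assert p.min() >= 1 / 101 and p.max() <= 1.0
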