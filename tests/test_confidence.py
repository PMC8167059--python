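"""Noise estimation, voxel p-values, FDR adjustment and confidence maps."""

import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from conftest import brute_force_fdr
from fdrval.confidence import (
    NoiseRegionSpec,
    check_noise_regions,
    confidence_map,
    default_noise_regions,
    estimate_noise,
    fdr_adjust,
    voxel_p_values,
)
from fdrval.errors import ConfigurationError, DegenerateNoiseError
from fdrval.map_io import DensityMap
from fdrval.synthetic import make_scene


def noise_only_map(size=48, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    return DensityMap(rng.normal(0.0, sd, size=(size,) * 3), 1.0, (0, 0, 0))


class TestNoiseRegions:
    def test_default_four_cubes_pool_expected_voxel_count(self):
        dmap = DensityMap(np.zeros((64, 64, 64)), 1.0, (0, 0, 0))
        spec = default_noise_regions(dmap, edge_voxels=9, guard_fraction=0.35)
        assert len(spec.cube_centers) == 4
        assert spec.n_voxels == 4 * 729 == 2916

    def test_cube_too_large_for_guard_margin_errors(self):
        dmap = DensityMap(np.zeros((48, 48, 48)), 1.0, (0, 0, 0))
        with pytest.raises(ConfigurationError):
            default_noise_regions(dmap, edge_voxels=21, guard_fraction=0.45)

    @pytest.mark.parametrize("size", [48, 57, 64, 96, 128])
    def test_default_regions_satisfy_invariants(self, size):
        dmap = DensityMap(np.zeros((size,) * 3, dtype=np.float32), 1.0, (0, 0, 0))
        spec = default_noise_regions(dmap)
        spec.validate(dmap.dims)  # inside grid, pairwise disjoint
        assert spec.edge_voxels % 2 == 1 and spec.edge_voxels >= 5

    def test_overlapping_cubes_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseRegionSpec(((10, 10, 10), (12, 10, 10)), 5).validate((32, 32, 32))


class TestCheckNoiseRegions:
    def test_pure_noise_rarely_flagged(self):
        flagged = 0
        for seed in range(200):
            dmap = noise_only_map(size=48, seed=seed)
            diag = check_noise_regions(dmap, default_noise_regions(dmap), k=5.0)
            flagged += 0 if diag.ok else 1
        assert flagged <= 2  # >= 99% clean under the null at k=5

    def test_signal_contaminated_cube_is_flagged(self):
        dmap = noise_only_map(size=48, seed=1)
        spec = default_noise_regions(dmap)
        # drop a strong Gaussian blob (SNR 5) onto the first cube
        center = np.asarray(spec.cube_centers[0], dtype=float)
        gx, gy, gz = np.meshgrid(*[np.arange(s) for s in dmap.dims], indexing="ij")
        d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
        dmap.values += 5.0 * np.exp(-d2 / (2.0 * 2.0**2))
        diag = check_noise_regions(dmap, spec, k=5.0)
        assert 0 in diag.flagged

    def test_constant_cubes_reported_degenerate(self):
        dmap = DensityMap(np.zeros((48, 48, 48)), 1.0, (0, 0, 0))
        diag = check_noise_regions(dmap, default_noise_regions(dmap))
        assert diag.degenerate == (0, 1, 2, 3)
        assert all(sd == 0.0 for sd in diag.cube_sds)


class TestEstimateNoise:
    def test_hand_computed_single_spike(self):
        dmap = DensityMap(np.zeros((32, 32, 32)), 1.0, (0, 0, 0))
        spec = NoiseRegionSpec(((4, 4, 4), (4, 4, 20), (20, 4, 4), (20, 20, 20)), 5)
        dmap.values[4, 4, 4] = 1.0
        est = estimate_noise(dmap, spec)
        n = 4 * 125
        mean = 1.0 / n
        var = ((1.0 - mean) ** 2 + (n - 1) * mean**2) / (n - 1)
        assert est.n_voxels == n
        assert est.mean == pytest.approx(mean, abs=1e-15)
        assert est.sd == pytest.approx(math.sqrt(var), rel=1e-12)

    def test_standard_normal_recovered_within_standard_error(self):
        dmap = noise_only_map(size=64, seed=5)
        spec = default_noise_regions(dmap, edge_voxels=9)  # 2916 voxels
        est = estimate_noise(dmap, spec)
        assert est.mean == pytest.approx(0.0, abs=0.05)
        assert est.sd == pytest.approx(1.0, abs=0.05)

    def test_pooling_two_cubes_equals_union_moments(self):
        dmap = noise_only_map(size=32, seed=9)
        a = NoiseRegionSpec(((5, 5, 5),), 5)
        b = NoiseRegionSpec(((24, 24, 24),), 5)
        union = NoiseRegionSpec(((5, 5, 5), (24, 24, 24)), 5)
        ea, eb, eu = (estimate_noise(dmap, s) for s in (a, b, union))
        n = ea.n_voxels
        pooled_mean = (ea.mean + eb.mean) / 2
        # pooled sample variance from per-cube moments (sum of squares identity)
        ss = (n - 1) * (ea.sd**2 + eb.sd**2) + n * (ea.mean**2 + eb.mean**2)
        pooled_var = (ss - 2 * n * pooled_mean**2) / (2 * n - 1)
        assert eu.mean == pytest.approx(pooled_mean, rel=1e-12)
        assert eu.sd == pytest.approx(math.sqrt(pooled_var), rel=1e-10)

    def test_zero_spread_raises_masked_map_error(self):
        dmap = DensityMap(np.zeros((48, 48, 48)), 1.0, (0, 0, 0))
        with pytest.raises(DegenerateNoiseError, match="[Mm]asked"):
            estimate_noise(dmap, default_noise_regions(dmap))


class TestVoxelPValues:
    def test_value_at_mean_gives_half(self, random_map):
        est = estimate_noise(random_map, NoiseRegionSpec(((3, 3, 3), (8, 10, 12)), 5))
        dmap = random_map.with_values(np.full(random_map.dims, est.mean))
        np.testing.assert_allclose(voxel_p_values(dmap, est), 0.5, atol=1e-12)

    def test_gaussian_tail_quantile(self, random_map):
        est = estimate_noise(random_map, NoiseRegionSpec(((3, 3, 3), (8, 10, 12)), 5))
        dmap = random_map.with_values(np.full(random_map.dims, est.mean + 1.6449 * est.sd))
        np.testing.assert_allclose(voxel_p_values(dmap, est), 0.05, atol=1e-4)

    def test_strictly_decreasing_in_value(self, random_map):
        est = estimate_noise(random_map, NoiseRegionSpec(((3, 3, 3), (8, 10, 12)), 5))
        v = np.sort(np.unique(random_map.values.ravel()))[:200]
        p = voxel_p_values(random_map.with_values(v.reshape(-1, 1, 1)), est).ravel()
        assert np.all(np.diff(p) < 0)


class TestFdrAdjust:
    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(fdr_adjust([1.0, 1.0, 1.0], "by"), [1.0, 1.0, 1.0])

    def test_hand_stepup_by_case(self):
        q = fdr_adjust([0.01, 0.02, 0.03], "by")
        np.testing.assert_allclose(q, [0.055, 0.055, 0.055], atol=1e-12)

    @pytest.mark.parametrize("method", ["by", "bh"])
    def test_matches_brute_force_oracle_bitwise(self, method):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            m = int(rng.integers(1, 51))
            p = rng.uniform(1e-6, 1.0, size=m)
            np.testing.assert_array_equal(fdr_adjust(p, method), brute_force_fdr(p, method))

    @pytest.mark.parametrize("method,label", [("by", "fdr_by"), ("bh", "fdr_bh")])
    def test_matches_statsmodels(self, method, label):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(2, 80)))
            _, q_ref, _, _ = multipletests(p, method=label)
            np.testing.assert_allclose(fdr_adjust(p, method), q_ref, rtol=1e-12)

    def test_by_never_below_bh(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1.0, size=100)
        assert np.all(fdr_adjust(p, "by") >= fdr_adjust(p, "bh"))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5], "by")
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5], "by")


class TestConfidenceMap:
    def test_values_bounded_and_monotone_in_raw_value(self, scene_snr5):
        cmap = confidence_map(scene_snr5.noisy_map)
        assert cmap.values.min() >= 0.0 and cmap.values.max() <= 1.0
        raw = scene_snr5.noisy_map.values.ravel()
        order = np.argsort(raw)
        conf_sorted = cmap.values.ravel()[order]
        assert np.all(np.diff(conf_sorted) >= 0)

    def test_equal_raw_values_get_equal_confidence(self):
        dmap = noise_only_map(size=48, seed=13)
        dmap.values[0, 0, 0] = dmap.values[47, 47, 47] = 3.3
        cmap = confidence_map(dmap)
        assert cmap.values[0, 0, 0] == cmap.values[47, 47, 47]

    def test_pure_noise_has_no_high_confidence_voxels(self):
        # smoke version of the global-null guard (full run in acceptance)
        hits = sum(
            int(np.any(confidence_map(noise_only_map(seed=seed)).values >= 0.99))
            for seed in range(300, 320)
        )
        assert hits <= 1

    @pytest.mark.parametrize("snr", [3.0, 5.0, 10.0])
    def test_empirical_fdr_controlled_across_snr(self, snr):
        fdps = []
        for seed in range(40, 45):
            scene = make_scene(snr=snr, seed=seed)
            cmap = confidence_map(scene.noisy_map)
            sel = cmap.values >= 0.99
            if sel.sum():
                fdps.append((sel & ~scene.truth_mask).sum() / sel.sum())
        mc_se = np.std(fdps, ddof=1) / math.sqrt(len(fdps)) if len(fdps) > 1 else 0.0
        assert np.mean(fdps) <= 0.01 + 3 * mc_se + 1e-12

    def test_provenance_recorded(self, scene_snr5):
        cmap = confidence_map(scene_snr5.noisy_map, method="bh")
        assert cmap.fdr_method == "bh"
        assert cmap.noise is not None and cmap.noise.sd > 0
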