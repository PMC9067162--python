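import numpy as np
import pytest
from scipy import ndimage

from nisslsplit.channels import (
    STRUCT_26,
    BandThresholds,
    ChannelSet,
    PlaqueSignatureParams,
    detect_dark_bodies,
    detect_plaques,
    extract_processes,
    extract_vessels,
    fit_band_thresholds,
    fuse_channels,
    plaque_score,
)
from nisslsplit.errors import ValidationError
from nisslsplit.volume import Volume

from conftest import flood_fill_oracle


class TestBandThresholds:
    def test_quantiles_match_direct_computation(self, rng):
        vals = np.concatenate(
            [rng.normal(40, 5, 4000), rng.normal(220, 5, 4000)]
        ).clip(0, 255)
        arr = vals.astype(np.uint8).reshape(20, 20, 20)
        vol = Volume(arr, (1, 1, 1))
        bands = fit_band_thresholds(vol, 0.10, 0.95)
        assert bands.t_dark == np.quantile(arr, 0.10)
        assert bands.t_bright == np.quantile(arr, 0.95)
        assert bands.t_dark < 60 < 200 < bands.t_bright

    def test_extreme_quantiles_span_range(self, rng):
        arr = rng.integers(0, 256, (8, 8, 8)).astype(np.uint8)
        arr.flat[0], arr.flat[1] = 0, 255
        bands = fit_band_thresholds(Volume(arr, (1, 1, 1)), 1e-9, 1 - 1e-9)
        assert (bands.t_dark, bands.t_bright) == (0, 255)

    def test_inverted_quantiles_rejected(self, rng):
        vol = Volume(rng.integers(0, 256, (4, 4, 4)).astype(np.uint8), (1, 1, 1))
        with pytest.raises(ValidationError):
            fit_band_thresholds(vol, 0.9, 0.1)

    def test_constant_image_is_degenerate(self):
        vol = Volume(np.full((4, 4, 4), 7, np.uint8), (1, 1, 1))
        with pytest.raises(ValidationError, match="degenerate"):
            fit_band_thresholds(vol, 0.1, 0.9)


class TestRegionGrowing:
    def test_bright_tube_equals_flood_fill(self):
        arr = np.full((20, 20, 40), 120, np.uint8)
        arr[9:12, 9:12, 5:35] = 240
        vol = Volume(arr, (1, 1, 1))
        bands = BandThresholds(60, 200)
        mask = extract_vessels(vol, bands, seed_quantile=0.995, grow_tolerance=0,
                               min_component_um3=0)
        seeds = arr >= max(np.quantile(arr, 0.995), 200)
        oracle = flood_fill_oracle(arr, 200, seeds)
        np.testing.assert_array_equal(mask, oracle)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_fixture_equals_flood_fill(self, seed):
        r = np.random.default_rng(seed)
        arr = r.integers(0, 256, size=(24, 24, 24)).astype(np.uint8)
        vol = Volume(arr, (1, 1, 1))
        bands = BandThresholds(50, 180)
        tol = float(r.integers(0, 40))
        mask = extract_vessels(vol, bands, seed_quantile=0.99, grow_tolerance=tol,
                               min_component_um3=0)
        seeds = arr >= max(np.quantile(arr, 0.99), 180)
        oracle = flood_fill_oracle(arr, 180 - tol, seeds)
        np.testing.assert_array_equal(mask, oracle)

    def test_uniform_volume_gives_empty_mask_with_warning(self):
        vol = Volume(np.full((8, 8, 8), 100, np.uint8), (1, 1, 1))
        with pytest.warns(UserWarning):
            mask = extract_vessels(vol, BandThresholds(50, 200))
        assert not mask.any()

    def test_only_seeded_component_returned(self):
        arr = np.full((10, 10, 30), 100, np.uint8)
        arr[4:6, 4:6, 2:8] = 255   # seeded (brightest)
        arr[4:6, 4:6, 20:26] = 210  # above grow threshold but unseeded
        vol = Volume(arr, (1, 1, 1))
        mask = extract_vessels(vol, BandThresholds(50, 205), seed_quantile=0.999,
                               grow_tolerance=0, min_component_um3=0)
        assert mask[5, 5, 4] and not mask[5, 5, 22]

    def test_small_components_removed(self):
        arr = np.full((10, 10, 10), 100, np.uint8)
        arr[5, 5, 5] = 255
        vol = Volume(arr, (1, 1, 1))
        mask = extract_vessels(vol, BandThresholds(50, 200), seed_quantile=0.999,
                               grow_tolerance=0, min_component_um3=10)
        assert not mask.any()


class TestPlaqueScore:
    PARAMS = PlaqueSignatureParams(core_radius_um=7.5, rim_inner_um=8.5,
                                   rim_outer_um=13.5, min_score=80,
                                   min_diameter_um=10, max_diameter_um=30)

    def test_pompon_center_score_matches_neighbourhood_means(self, pompon_volume):
        score = plaque_score(pompon_volume, self.PARAMS)
        arr = pompon_volume.voxels.astype(float)
        zz, yy, xx = np.ogrid[:48, :48, :48]
        d2 = (zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2
        ball = d2 <= 7.5**2
        ann = (d2 >= 8.5**2) & (d2 <= 13.5**2)
        expected = arr[ann].mean() - arr[ball].mean()
        assert score[24, 24, 24] == pytest.approx(expected, abs=0.5)
        assert expected == pytest.approx(120, abs=10)
        assert abs(score[4, 4, 4]) < 2

    def test_uniform_volume_scores_zero(self):
        vol = Volume(np.full((32, 32, 32), 90, np.uint8), (1, 1, 1))
        score = plaque_score(vol, self.PARAMS)
        assert np.abs(score).max() < 1e-3

    def test_shift_invariance(self, pompon_volume):
        s1 = plaque_score(pompon_volume, self.PARAMS)
        shifted = pompon_volume.with_voxels(pompon_volume.voxels + 20)
        s2 = plaque_score(shifted, self.PARAMS)
        assert np.abs(s1 - s2).max() < 0.01

    def test_rimless_ball_scores_below_pompon(self, pompon_volume, dark_ball_volume):
        sp = plaque_score(pompon_volume, self.PARAMS)[24, 24, 24]
        sb = plaque_score(dark_ball_volume, self.PARAMS)[24, 24, 24]
        assert sb < sp

    def test_oversized_kernel_rejected(self):
        vol = Volume(np.zeros((64, 64, 64), np.uint8), (1, 1, 1))
        with pytest.raises(ValidationError):
            plaque_score(vol, PlaqueSignatureParams(rim_outer_um=30.0,
                                                    rim_inner_um=28.0,
                                                    core_radius_um=20.0))


def _pompon(arr, center, core_r, rim_out, core=60, rim=150):
    zz, yy, xx = np.ogrid[: arr.shape[0], : arr.shape[1], : arr.shape[2]]
    d2 = sum((g - c) ** 2 for g, c in zip((zz, yy, xx), center))
    arr[d2 <= rim_out**2] = rim
    arr[d2 <= core_r**2] = core


class TestDetectPlaques:
    PARAMS = PlaqueSignatureParams(min_score=75, min_diameter_um=15,
                                   max_diameter_um=30)
    BANDS = BandThresholds(90, 200)

    def test_single_pompon_detected_at_truth_centroid(self):
        arr = np.full((64, 64, 64), 120, np.uint8)
        _pompon(arr, (32, 32, 32), 10, 14)
        mask, table = detect_plaques(Volume(arr, (1, 1, 1)), self.PARAMS, self.BANDS)
        assert len(table) == 1
        cent = table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].iloc[0]
        assert np.abs(cent.to_numpy() - 32).max() <= 1.0
        assert table["equivalent_diameter_um"].iloc[0] == pytest.approx(20, rel=0.1)

    def test_uniform_volume_no_detections(self):
        vol = Volume(np.full((48, 48, 48), 120, np.uint8), (1, 1, 1))
        mask, table = detect_plaques(vol, self.PARAMS, self.BANDS)
        assert len(table) == 0 and not mask.any()

    def test_rimless_ball_rejected_pompon_kept(self):
        arr = np.full((48, 48, 96), 120, np.uint8)
        _pompon(arr, (24, 24, 24), 10, 14)
        zz, yy, xx = np.ogrid[:48, :48, :96]
        arr[(zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 72) ** 2 <= 10**2] = 60
        mask, table = detect_plaques(Volume(arr, (1, 1, 1)), self.PARAMS, self.BANDS)
        assert len(table) == 1
        assert table["centroid_x_um"].iloc[0] == pytest.approx(24, abs=1)


class TestDarkBodies:
    def test_three_ellipsoids_become_somata(self):
        arr = np.full((48, 64, 64), 150, np.uint8)
        centers = [(12, 16, 16), (24, 40, 20), (36, 30, 48)]
        for c, radii in zip(centers, [(4, 5, 4), (6, 5, 7), (5, 5, 5)]):
            zz, yy, xx = np.ogrid[:48, :64, :64]
            e = sum(((g - ci) / r) ** 2 for g, ci, r in zip((zz, yy, xx), c, radii))
            arr[e <= 1] = 60
        soma, tract, table = detect_dark_bodies(
            Volume(arr, (1, 1, 1)), BandThresholds(100, 200)
        )
        assert len(table) == 3
        got = table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
        for c in centers:
            assert np.min(np.linalg.norm(got - c, axis=1)) <= 1.0
        assert not tract.any()

    def test_empty_dark_band_empty_outputs(self):
        vol = Volume(np.full((8, 8, 8), 150, np.uint8), (1, 1, 1))
        soma, tract, table = detect_dark_bodies(vol, BandThresholds(100, 200))
        assert not soma.any() and not tract.any() and len(table) == 0

    def test_large_dark_cylinder_routed_to_tract(self):
        arr = np.full((64, 64, 304), 150, np.uint8)
        zz, yy = np.ogrid[:64, :64]
        disk = (zz - 32) ** 2 + (yy - 32) ** 2 <= 30**2
        arr[disk, 2:302] = 60
        soma, tract, table = detect_dark_bodies(
            Volume(arr, (1, 1, 1)), BandThresholds(100, 200)
        )
        assert tract.any()
        assert len(table) == 0  # not in the soma table

    def test_misaligned_exclude_rejected(self):
        vol = Volume(np.zeros((8, 8, 8), np.uint8), (1, 1, 1))
        with pytest.raises(ValidationError):
            detect_dark_bodies(vol, BandThresholds(50, 200),
                               exclude=[np.zeros((4, 4, 4), bool)])

    def test_overlapping_excludes_rejected(self):
        vol = Volume(np.zeros((8, 8, 8), np.uint8), (1, 1, 1))
        m = np.ones((8, 8, 8), bool)
        with pytest.raises(ValidationError):
            detect_dark_bodies(vol, BandThresholds(50, 200), exclude=[m, m])


class TestProcesses:
    BANDS = BandThresholds(100, 200)

    def _filament_volume(self):
        arr = np.full((60, 60, 100), 150, np.uint8)
        fil = np.zeros_like(arr, bool)
        for x in range(10, 90):
            fil[29:31, 29:31, x] = True
        arr[fil] = 125
        return Volume(arr, (1, 1, 1)), fil

    def test_thin_filament_mostly_retained(self):
        vol, fil = self._filament_volume()
        mask = extract_processes(vol, self.BANDS)
        assert (mask & fil).sum() >= 0.8 * fil.sum()

    def test_isotropic_blob_mostly_rejected(self):
        arr = np.full((64, 64, 64), 150, np.uint8)
        zz, yy, xx = np.ogrid[:64, :64, :64]
        blob = (zz - 32) ** 2 + (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
        arr[blob] = 125
        mask = extract_processes(Volume(arr, (1, 1, 1)), self.BANDS)
        assert (mask & blob).sum() <= 0.1 * blob.sum()

    def test_fully_excluded_gives_empty_mask(self):
        vol, fil = self._filament_volume()
        mask = extract_processes(vol, self.BANDS,
                                 exclude=[np.ones(vol.shape, bool)])
        assert not mask.any()


class TestFusion:
    def test_disjoint_channels_reproduced_exactly(self):
        shape = (6, 6, 6)
        vessel = np.zeros(shape, bool); vessel[0] = True
        soma = np.zeros(shape, bool); soma[3] = True
        cs = ChannelSet(spacing=(1, 1, 1), vessel=vessel, soma=soma)
        fused = fuse_channels(cs)
        np.testing.assert_array_equal(fused.mask("vessel"), vessel)
        np.testing.assert_array_equal(fused.mask("soma"), soma)

    def test_overlap_resolved_by_precedence(self):
        shape = (2, 2, 2)
        both = np.ones(shape, bool)
        cs = ChannelSet(spacing=(1, 1, 1), vessel=both, plaque=both)
        fused = fuse_channels(cs)
        assert np.all(fused.labels == 1)  # vessel wins

    @pytest.mark.parametrize("seed", range(5))
    def test_random_overlaps_match_per_voxel_oracle(self, seed):
        r = np.random.default_rng(seed)
        shape = (8, 8, 8)
        masks = {n: r.random(shape) < 0.3
                 for n in ("vessel", "plaque", "soma", "tract", "process")}
        fused = fuse_channels(ChannelSet(spacing=(1, 1, 1), **masks))
        order = ["vessel", "plaque", "soma", "tract", "process"]
        ids = {n: i + 1 for i, n in enumerate(order)}
        expect = np.zeros(shape, np.int32)
        for idx in np.ndindex(shape):
            for n in order:
                if masks[n][idx]:
                    expect[idx] = ids[n]
                    break
        np.testing.assert_array_equal(fused.labels, expect)
        # partition: union preserved, per-label masks disjoint
        union = np.zeros(shape, bool)
        for m in masks.values():
            union |= m
        np.testing.assert_array_equal(fused.labels > 0, union)

    def test_fusion_idempotent(self, rng):
        shape = (6, 6, 6)
        masks = {n: rng.random(shape) < 0.4
                 for n in ("vessel", "plaque", "soma", "tract", "process")}
        fused = fuse_channels(ChannelSet(spacing=(1, 1, 1), **masks))
        again = fuse_channels(ChannelSet(
            spacing=(1, 1, 1), **{n: fused.mask(n) for n in masks}))
        np.testing.assert_array_equal(fused.labels, again.labels)

    def test_misaligned_channels_rejected(self):
        cs = ChannelSet(spacing=(1, 1, 1), vessel=np.zeros((2, 2, 2), bool),
                        soma=np.zeros((3, 3, 3), bool))
        with pytest.raises(ValidationError):
            fuse_channels(cs)
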