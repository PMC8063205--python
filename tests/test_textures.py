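"""Texture features against closed forms, brute-force oracles and symmetries."""

import logging

import numpy as np
import pytest

import _oracles
from radkinetics import textures
from radkinetics.textures import VoxelVolume


def random_labelled_volume(seed, shape=(6, 6, 3), n_levels=4, mask_density=0.85):
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < mask_density
    mask.flat[0] = True  # never empty
    return labels * mask, mask


class TestResample:
    def test_identity_resample_returns_input(self, rng):
        vol = VoxelVolume(rng.random((8, 8, 8)), (1.0, 1.0, 3.0))
        out = textures.resample_trilinear(vol, (1.0, 1.0, 3.0))
        np.testing.assert_array_equal(out.values, vol.values)

    def test_linear_ramp_is_reproduced_exactly(self):
        ramp = np.tile(np.arange(8.0)[:, None, None], (1, 4, 4))
        vol = VoxelVolume(ramp, (1.0, 1.0, 1.0))
        out = textures.resample_trilinear(vol, (2.0, 1.0, 1.0))
        np.testing.assert_allclose(out.values[:, 0, 0], [0.5, 2.5, 4.5, 6.5])

    def test_matches_corner_weight_oracle_at_probe_voxels(self, rng):
        vals = rng.random((8, 8, 8))
        vol = VoxelVolume(vals, (1.0, 1.0, 1.0))
        out = textures.resample_trilinear(vol, (2.0, 2.0, 2.0))
        for probe in [(1, 1, 1), (2, 1, 2), (1, 2, 2), (2, 2, 1), (2, 2, 2)]:
            expected = _oracles.trilinear_probe(vals, (1, 1, 1), (2, 2, 2), probe)
            assert out.values[probe] == pytest.approx(expected, abs=1e-12)

    def test_physical_extent_preserved(self, rng):
        vol = VoxelVolume(rng.random((10, 12, 6)), (0.7, 0.7, 2.0))
        out = textures.resample_trilinear(vol, (1.0, 1.0, 3.0))
        np.testing.assert_allclose(
            np.array(out.values.shape) * out.spacing_mm,
            np.array(vol.values.shape) * vol.spacing_mm,
            rtol=0.2,
        )


class TestDiscretize:
    @pytest.mark.parametrize(
        "values, n_levels, expected",
        [
            (np.arange(256.0), 8, {0: 1, 255: 8, 96: 4}),
            (np.array([1.0, 2.0, 3.0, 4.0]), 2, {1: 1, 2: 1, 3: 2, 4: 2}),
        ],
    )
    def test_equal_width_bin_examples(self, values, n_levels, expected):
        vol = values.reshape(-1, 1, 1)
        mask = np.ones_like(vol, bool)
        labels = textures.discretize_levels(vol, mask, n_levels)
        for value, level in expected.items():
            idx = int(np.flatnonzero(values == value)[0])
            assert labels[idx, 0, 0] == level

    def test_constant_region_maps_to_level_one(self):
        vol = np.full((3, 3, 3), 7.0)
        mask = np.ones_like(vol, bool)
        assert np.all(textures.discretize_levels(vol, mask, 8)[mask] == 1)


class TestGLCM:
    def test_constant_region_gives_single_entry(self):
        labels = np.ones((3, 3, 3), np.int32)
        mask = np.ones((3, 3, 3), bool)
        P = textures.compute_glcm(labels, mask, mode="3D", n_levels=2)
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_checkerboard_closed_form(self):
        board = (np.indices((4, 4, 1)).sum(axis=0) % 2 + 1).astype(np.int32)
        mask = np.ones((4, 4, 1), bool)
        P = textures.compute_glcm(board, mask, n_levels=2, offsets=[(1, 0, 0)])
        np.testing.assert_allclose(P, [[0, 0.5], [0.5, 0]])
        fv = textures.glcm_features(P)
        assert fv["contrast"] == pytest.approx(1.0)
        assert fv["dissimilarity"] == pytest.approx(1.0)
        assert fv["correlation"] == pytest.approx(-1.0)
        assert fv["cluster_shade"] == pytest.approx(0.0)

    @pytest.mark.parametrize("mode", ["3D", "2.5D"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_normalized_and_symmetric(self, seed, mode):
        labels, mask = random_labelled_volume(seed)
        P = textures.compute_glcm(labels, mask, mode=mode, n_levels=4)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(P, P.T, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_features_match_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        P = rng.random((4, 4))
        P = (P + P.T) / 2
        P /= P.sum()
        ours = textures.glcm_features(P).values
        oracle = _oracles.glcm_features(P)
        for name, expected in oracle.items():
            assert ours[name] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_correlation_is_flagged(self):
        P = np.zeros((3, 3))
        P[0, 0] = 1.0
        fv = textures.glcm_features(P)
        assert "correlation" in fv.undefined
        assert "information_measure_correlation_1" in fv.undefined


class TestGLRL:
    def test_single_run_on_a_constant_line(self):
        labels = np.ones((1, 1, 8), np.int32)
        mask = np.ones((1, 1, 8), bool)
        fv = textures.glrl_features(labels, mask, n_levels=1, offsets=[(0, 0, 1)])
        assert fv["run_percentage"] == pytest.approx(1 / 8)
        assert fv["long_run_emphasis"] == pytest.approx(64.0)

    def test_alternating_line_has_all_unit_runs(self):
        labels = (np.arange(8) % 2 + 1).reshape(1, 1, 8).astype(np.int32)
        mask = np.ones((1, 1, 8), bool)
        fv = textures.glrl_features(labels, mask, n_levels=2, offsets=[(0, 0, 1)])
        assert fv["short_run_emphasis"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_total_equals_run_count(self, seed):
        labels, mask = random_labelled_volume(seed)
        R = textures.compute_glrl(labels, mask, mode="3D", n_levels=4)
        n_runs = sum(
            len(_oracles.glrl_runs(labels, mask, off)) for off in textures.OFFSETS_3D
        )
        assert R.sum() == n_runs

    @pytest.mark.parametrize("seed", range(5))
    def test_features_match_line_sweep_oracle(self, seed):
        labels, mask = random_labelled_volume(seed)
        ours = textures.glrl_features(labels, mask, mode="3D", n_levels=4).values
        oracle = _oracles.glrl_features(labels, mask, textures.OFFSETS_3D)
        for name, expected in oracle.items():
            assert ours[name] == pytest.approx(expected, abs=1e-10)


class TestNGTDM:
    def test_constant_region_degenerates_to_zero(self):
        labels = np.ones((5, 5, 3), np.int32)
        mask = np.ones((5, 5, 3), bool)
        fv = textures.ngtdm_features(labels, mask, neighborhood=3, mode="3D")
        assert fv["contrast"] == 0.0
        assert fv["texture_strength"] == 0.0

    @pytest.mark.parametrize("mode", ["3D", "2.5D"])
    @pytest.mark.parametrize("seed", range(5))
    def test_features_match_window_loop_oracle(self, seed, mode):
        rng = np.random.default_rng(seed + 50)
        labels = rng.integers(1, 4, size=(6, 6, 3)).astype(np.int32)
        mask = np.ones((6, 6, 3), bool)
        ours = textures.ngtdm_features(labels, mask, neighborhood=3, mode=mode).values
        oracle = _oracles.ngtdm_features(labels, mask, 3, mode)
        for name, expected in oracle.items():
            assert ours[name] == pytest.approx(expected, abs=1e-12)

    def test_window_larger_than_mask_errors(self):
        labels = np.ones((5, 5, 5), np.int32)
        mask = np.ones((5, 5, 5), bool)
        with pytest.raises(ValueError, match="window"):
            textures.ngtdm_features(labels, mask, neighborhood=7, mode="3D")


class TestFirstOrder:
    def test_constant_region(self):
        vol = VoxelVolume(np.full((4, 4, 3), 5.0), (1, 1, 1))
        mask = np.ones((4, 4, 3), bool)
        fv = textures.first_order_features(vol, mask)
        assert fv["mean"] == 5.0
        assert fv["sd"] == 0.0
        assert fv["local_entropy_median"] == 0.0
        assert fv["voxel_volume"] == 48.0

    def test_mean_of_small_set(self):
        vol = VoxelVolume(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1), (1, 1, 1))
        mask = np.ones((4, 1, 1), bool)
        assert textures.first_order_features(vol, mask)["mean"] == 2.5

    def test_local_entropy_matches_per_voxel_oracle(self, rng):
        vals = rng.random((6, 6, 3))
        mask = rng.random((6, 6, 3)) < 0.9
        mask[:3, :3, :] = True
        vol = VoxelVolume(vals, (1, 1, 1))
        labels = textures.discretize_levels(vals, mask, 4)
        fv = textures.first_order_features(vol, mask, n_levels=4, labels=labels)
        assert fv["local_entropy_median"] == pytest.approx(
            _oracles.local_entropy_median(labels, mask), abs=1e-12
        )


class TestSymmetries:
    @pytest.mark.parametrize("axes", [(0, 1), (0, 2), (1, 2)])
    def test_direction_merged_3d_features_rotation_invariant(self, rng, axes):
        labels, mask = random_labelled_volume(7, shape=(5, 5, 5))
        rl, rm = np.rot90(labels, axes=axes).copy(), np.rot90(mask, axes=axes).copy()
        f0 = textures.glcm_features(textures.compute_glcm(labels, mask, "3D", 4)).values
        f1 = textures.glcm_features(textures.compute_glcm(rl, rm, "3D", 4)).values
        for k in f0:
            if not np.isnan(f0[k]):
                assert f0[k] == pytest.approx(f1[k], abs=1e-9)
        g0 = textures.glrl_features(labels, mask, "3D", 4).values
        g1 = textures.glrl_features(rl, rm, "3D", 4).values
        for k in g0:
            assert g0[k] == pytest.approx(g1[k], abs=1e-9)


class TestExtraction:
    def _voi_records(self, seed=0, months=(0, 2, 6), voi_id="V1"):
        rng = np.random.default_rng(seed)
        for month in months:
            vol = VoxelVolume(100 + 10 * rng.random((12, 12, 6)), (1.0, 1.0, 3.0))
            mask = np.zeros((12, 12, 6), bool)
            mask[2:10, 2:10, 1:5] = True
            yield {
                "voi_id": voi_id,
                "patient_id": "P1",
                "label": "ORN",
                "timepoint_month": month,
                "volume": vol,
                "mask": mask,
            }

    def test_one_voi_three_months_three_rows(self):
        cfg = textures.ExtractionConfig(n_levels=8, nid_neighborhoods=(3,))
        table = textures.extract_feature_table(self._voi_records(), cfg)
        assert len(table) == 3
        assert table["timepoint_month"].tolist() == [0, 2, 6]
        assert table.columns[0] == "voi_id"

    def test_missing_month_drops_voi_with_warning(self, caplog):
        cfg = textures.ExtractionConfig(n_levels=8, nid_neighborhoods=(3,))
        records = list(self._voi_records(months=(0, 2))) + list(
            self._voi_records(voi_id="V2")
        )
        with caplog.at_level(logging.WARNING):
            table = textures.extract_feature_table(records, cfg)
        assert set(table["voi_id"]) == {"V2"}
        assert any("missing month" in r.message for r in caplog.records)

    def test_nifti_round_trip_preserves_volume_and_mask(self, rng, tmp_path):
        from radkinetics import synthetic

        vol, mask_a, _ = synthetic.generate_textured_phantom(
            synthetic.PhantomSpec(grid_shape=(24, 24, 8), mask_radius_mm=6.0, seed=2)
        )
        vpath = textures.save_nifti_volume(vol, tmp_path / "vol.nii.gz")
        mpath = textures.save_nifti_volume(
            mask_a.astype(float), vol.spacing_mm, tmp_path / "mask.nii.gz"
        )
        back = textures.load_nifti_volume(vpath)
        np.testing.assert_allclose(back.values, vol.values, rtol=1e-6)
        np.testing.assert_allclose(back.spacing_mm, vol.spacing_mm)
        back_mask = textures.load_nifti_volume(mpath).values >= 0.5
        np.testing.assert_array_equal(back_mask, mask_a)

    def test_extraction_is_deterministic(self):
        cfg = textures.ExtractionConfig(n_levels=8, nid_neighborhoods=(3,))
        t1 = textures.extract_feature_table(self._voi_records(), cfg)
        t2 = textures.extract_feature_table(self._voi_records(), cfg)
        assert t1.equals(t2)
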