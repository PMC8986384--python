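"""Preprocessing chain: resampling, metadata registration, ROI z-scoring,
3x3x3 neighbourhood smoothing, feature-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from habitatkit import (
    SEQUENCE_NAMES,
    StudyBundle,
    VolumeGrid,
    build_feature_matrix,
    neighborhood_mean_smooth,
    preprocess_study,
    register_by_metadata,
    resample_to_common_grid,
    standardize_in_roi,
)


def _line_volume(values, spacing=1.0):
    """Embed a 1-D profile along axis 0 of a 3-D grid."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return VolumeGrid(arr, spacing=(spacing, 1.0, 1.0))


class TestResample:
    def test_identity_spacing_is_identity(self):
        rng = np.random.default_rng(0)
        vol = VolumeGrid(rng.normal(size=(4, 5, 6)), spacing=(1.5, 2.0, 1.0))
        out = resample_to_common_grid(vol, vol.spacing)
        assert np.array_equal(out.values, vol.values)
        assert out.spacing == vol.spacing

    def test_constant_volume_stays_constant(self):
        vol = VolumeGrid(np.full((4, 4, 4), 3.25), spacing=(2.0, 2.0, 2.0))
        out = resample_to_common_grid(vol, (0.7, 1.3, 0.5))
        assert np.all(out.values == 3.25)

    def test_upsampling_line_with_midpoint_tie_break(self):
        """[0, 10] at 2 mm -> [0, 0, 10] at 1 mm: the midpoint is equidistant
        from both input centres and must take the lower-index value."""
        vol = _line_volume([0.0, 10.0], spacing=2.0)
        out = resample_to_common_grid(vol, (1.0, 1.0, 1.0))
        assert out.values[:, 0, 0].tolist() == [0.0, 0.0, 10.0]
        assert out.origin == vol.origin

    def test_bad_spacing_rejected(self):
        vol = _line_volume([1.0, 2.0])
        with pytest.raises(ValueError):
            resample_to_common_grid(vol, (0.0, 1.0, 1.0))


def _bundle_from(values_by_name, mask, **mask_kw):
    sequences = {n: v for n, v in values_by_name.items()}
    return StudyBundle(sequences, VolumeGrid(mask, **mask_kw))


class TestRegister:
    def _study(self, dwi_values, other_grid):
        shape = dwi_values.shape
        sequences = {"DWI": VolumeGrid(dwi_values)}
        for name in SEQUENCE_NAMES[1:]:
            sequences[name] = other_grid
        mask = np.zeros(shape, dtype=np.uint8)
        mask[1:3, 1:3, 1:3] = 1
        return StudyBundle(sequences, VolumeGrid(mask))

    def test_aligned_study_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 5, 5))
        study = self._study(vals, VolumeGrid(vals.copy()))
        out = register_by_metadata(study)
        for name in SEQUENCE_NAMES:
            assert np.array_equal(out.sequences[name].values, vals)

    def test_one_voxel_translation_is_inverted(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 6, 6))
        shifted = VolumeGrid(vals, origin=(1.0, 0.0, 0.0))  # +1 voxel on axis 0
        study = self._study(vals, shifted)
        out = register_by_metadata(study)
        got = out.sequences["T1"].values
        # ref coordinate x maps to source index x-1; index 0 clips to source 0
        assert np.array_equal(got[1:], vals[:-1])

    def test_double_spacing_matches_resample_oracle(self):
        rng = np.random.default_rng(3)
        coarse = rng.normal(size=(3, 6, 6))
        src = VolumeGrid(coarse, spacing=(2.0, 1.0, 1.0))
        expected = resample_to_common_grid(src, (1.0, 1.0, 1.0))
        dwi = np.zeros((5, 6, 6))
        study = self._study(dwi, src)
        out = register_by_metadata(study)
        assert np.array_equal(out.sequences["T1"].values, expected.values)

    def test_disjoint_fov_raises(self):
        vals = np.zeros((4, 4, 4))
        far = VolumeGrid(vals, origin=(1000.0, 0.0, 0.0))
        study = self._study(vals, far)
        with pytest.raises(ValueError, match="overlap"):
            register_by_metadata(study)


class TestStandardize:
    def test_two_voxel_roi_hand_case(self):
        vals = np.zeros((3, 3, 3))
        vals[0, 0, 0], vals[0, 0, 1] = 1.0, 3.0
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, :2] = True
        out = standardize_in_roi(VolumeGrid(vals), mask)
        assert out.values[0, 0, 0] == pytest.approx(-1.0)
        assert out.values[0, 0, 1] == pytest.approx(1.0)
        assert np.all(out.values[~mask] == 0.0)

    def test_definitional_mean_zero_unit_variance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(3.0, 5.0, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.4
        out = standardize_in_roi(VolumeGrid(vals), mask)
        roi = out.values[mask]
        assert abs(roi.mean()) < 1e-10
        assert abs(roi.var() - 1.0) < 1e-8

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        once = standardize_in_roi(VolumeGrid(vals), mask)
        twice = standardize_in_roi(once, mask)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0),
           seed=st.integers(0, 10_000))
    def test_affine_invariance(self, a, b, seed):
        """standardize(a*x + b) == standardize(x) for a > 0."""
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        base = standardize_in_roi(VolumeGrid(vals), mask)
        scaled = standardize_in_roi(VolumeGrid(a * vals + b), mask)
        assert np.allclose(base.values, scaled.values, atol=1e-7)

    def test_zero_variance_names_sequence(self):
        vals = np.ones((3, 3, 3))
        mask = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="FatT2"):
            standardize_in_roi(VolumeGrid(vals), mask, name="FatT2")


class TestSmooth:
    def test_constant_volume_unchanged(self):
        vol = VolumeGrid(np.full((5, 5, 5), 2.5))
        out = neighborhood_mean_smooth(vol)
        assert np.allclose(out.values, 2.5)

    def test_interior_impulse_spreads_to_unit_block(self):
        vals = np.zeros((7, 7, 7))
        vals[3, 3, 3] = 27.0
        out = neighborhood_mean_smooth(VolumeGrid(vals))
        assert np.allclose(out.values[2:5, 2:5, 2:5], 1.0)
        assert np.allclose(out.values[0], 0.0)

    def test_corner_uses_eight_inbounds_neighbors(self):
        vals = np.zeros((6, 6, 6))
        vals[0, 0, 0] = 8.0
        out = neighborhood_mean_smooth(VolumeGrid(vals))
        assert out.values[0, 0, 0] == pytest.approx(1.0)

    def test_never_widens_value_range(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(8, 8, 8))
        out = neighborhood_mean_smooth(VolumeGrid(vals))
        assert out.values.min() >= vals.min() - 1e-12
        assert out.values.max() <= vals.max() + 1e-12


class TestFeatureMatrix:
    def test_shape_and_spot_check(self, small_params):
        from habitatkit import generate_phantom
        study, _ = generate_phantom(small_params)
        processed, fm = preprocess_study(study)
        assert fm.features.shape == (int(study.mask_array.sum()), 6)
        rng = np.random.default_rng(0)
        for r in rng.integers(0, fm.n_voxels, size=10):
            i, j, k = fm.voxel_index[r]
            for s, name in enumerate(SEQUENCE_NAMES):
                assert fm.features[r, s] == processed.sequences[name].values[i, j, k]

    def test_zero_noise_has_exactly_k_distinct_rows(self, noiseless_features):
        fm, truth = noiseless_features
        assert len(np.unique(fm.features, axis=0)) == 3

    def test_row_count_invariant_under_monotone_rescaling(self, small_params):
        from habitatkit import generate_phantom
        study, _ = generate_phantom(small_params)
        _, fm = preprocess_study(study)
        rescaled = StudyBundle(
            {n: VolumeGrid(3.0 * g.values + 1.0, g.spacing, g.origin)
             for n, g in study.sequences.items()},
            study.roi_mask, study.study_id)
        _, fm2 = preprocess_study(rescaled)
        assert fm2.n_voxels == fm.n_voxels
        # z-scoring makes the matrix invariant to the affine rescale entirely
        assert np.allclose(fm2.features, fm.features, atol=1e-9)

    def test_missing_sequence_named_in_error(self, small_params):
        from habitatkit import generate_phantom
        study, _ = generate_phantom(small_params)
        broken = dict(study.sequences)
        del broken["WaterT2"]
        with pytest.raises(ValueError, match="WaterT2"):
            StudyBundle(broken, study.roi_mask)
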