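"""Volume containers, I/O round-trips, and grid preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hectorvi import (
    LungMask,
    ScalarVolume,
    crop_pad_to_margin,
    median_filter,
    normalize_intensity,
    preprocess_pair,
    read_volume,
    resample_to_grid,
    write_volume,
)
from hectorvi.volume import (
    DegenerateInputError,
    DomainError,
    FormatError,
    ParameterError,
)


class TestIO:
    @pytest.mark.parametrize("ext", [".nii", ".nii.gz", ".mha", ".mhd"])
    def test_round_trip_preserves_values_and_geometry(self, tmp_path, ext, random_hu_volume):
        path = tmp_path / f"vol{ext}"
        write_volume(random_hu_volume, path)
        back = read_volume(path, unit="hu")
        np.testing.assert_array_equal(back.values, random_hu_volume.values)
        assert back.spacing == pytest.approx(random_hu_volume.spacing)
        assert back.origin == pytest.approx(random_hu_volume.origin)
        np.testing.assert_allclose(back.direction, random_hu_volume.direction)

    def test_round_trip_zeros(self, tmp_path):
        vol = ScalarVolume(np.zeros((4, 4, 4)))
        write_volume(vol, tmp_path / "z.nii.gz")
        back = read_volume(tmp_path / "z.nii.gz")
        np.testing.assert_array_equal(back.values, 0.0)

    def test_non_3d_payload_rejected(self, tmp_path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.zeros((5, 5)))
        sitk.WriteImage(img, str(tmp_path / "flat.nii"))
        with pytest.raises(FormatError):
            read_volume(tmp_path / "flat.nii")

    def test_unsupported_format_rejected(self, tmp_path):
        p = tmp_path / "vol.npy"
        p.write_bytes(b"x")
        with pytest.raises(FormatError):
            read_volume(p)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_volume(tmp_path / "nope.nii")


class TestScalarVolume:
    def test_rejects_tiny_or_flat_grids(self):
        with pytest.raises(FormatError):
            ScalarVolume(np.zeros((1, 4, 4)))
        with pytest.raises(FormatError):
            ScalarVolume(np.zeros((4, 4)))

    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            ScalarVolume(np.zeros((4, 4, 4)), spacing=(1, 0, 1))

    def test_unit_range_enforced(self):
        with pytest.raises(ValueError):
            ScalarVolume(np.full((4, 4, 4), -2000.0), unit="hu")
        with pytest.raises(ValueError):
            ScalarVolume(np.full((4, 4, 4), 1.5), unit="normalized")

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError):
            LungMask(np.zeros((4, 4, 4), bool))


def _face_distances(mask_values):
    """Brute-force min distance from foreground to each of the six faces."""
    fg = np.argwhere(mask_values)
    out = []
    for a in range(3):
        out.append(fg[:, a].min())
        out.append(mask_values.shape[a] - 1 - fg[:, a].max())
    return out


class TestCropPad:
    def test_exact_margin_on_all_faces_random_block(self, rng):
        vals = rng.normal(size=(32, 32, 32))
        m = np.zeros((32, 32, 32), bool)
        m[5:11, 20:26, 12:18] = True
        vol = ScalarVolume(vals)
        out_vol, out_mask, record = crop_pad_to_margin(vol, LungMask(m), margin=4)
        assert _face_distances(out_mask.values) == [4] * 6
        # cropped values match the source region
        np.testing.assert_array_equal(out_vol.values[4:10, 4:10, 4:10],
                                      vals[5:11, 20:26, 12:18])

    def test_padding_inserted_when_lung_touches_face(self):
        vals = np.zeros((20, 20, 20))
        m = np.zeros((20, 20, 20), bool)
        m[5:12, 5:12, 0:6] = True  # flush against the inferior face
        vol = ScalarVolume(vals, unit="hu")
        out_vol, out_mask, _ = crop_pad_to_margin(vol, LungMask(m), margin=10)
        assert _face_distances(out_mask.values) == [10] * 6
        # padded slabs filled with air
        assert out_vol.values[:, :, 0].min() == -1000.0

    def test_fixed_point_when_margin_already_exact(self):
        vals = np.arange(24 ** 3, dtype=float).reshape(24, 24, 24)
        m = np.zeros((24, 24, 24), bool)
        m[10:14, 10:14, 10:14] = True
        vol = ScalarVolume(vals)
        out_vol, out_mask, _ = crop_pad_to_margin(vol, LungMask(m), margin=10)
        np.testing.assert_array_equal(out_vol.values, vals)
        np.testing.assert_array_equal(out_mask.values, m)

    def test_geometry_record_round_trips(self, rng):
        vals = rng.normal(size=(32, 32, 32))
        m = np.zeros((32, 32, 32), bool)
        m[3:9, 14:22, 25:30] = True
        _, _, record = crop_pad_to_margin(ScalarVolume(vals), LungMask(m), margin=6)
        pts = rng.uniform(0, 20, (50, 3))
        back = record.to_processed(record.to_original(pts))
        np.testing.assert_allclose(back, pts, atol=0.5)


class TestResample:
    def test_constant_preserved(self):
        vol = ScalarVolume(np.full((8, 8, 8), 3.5))
        out = resample_to_grid(vol, (16, 16, 16))
        assert out.shape == (16, 16, 16)
        np.testing.assert_allclose(out.values, 3.5)

    def test_linear_ramp_endpoints_preserved(self):
        ramp = np.broadcast_to(np.linspace(-10, 50, 16)[:, None, None], (16, 16, 16))
        out = resample_to_grid(ScalarVolume(np.array(ramp)), (32, 32, 32))
        np.testing.assert_allclose(out.values[0], -10.0, atol=1e-12)
        np.testing.assert_allclose(out.values[-1], 50.0, atol=1e-12)
        np.testing.assert_allclose(np.diff(out.values[:, 0, 0]),
                                   60 / 31, atol=1e-9)

    def test_smooth_blob_up_down_round_trip(self):
        x = np.linspace(-2, 2, 32)
        blob = np.exp(-(x[:, None, None] ** 2 + x[None, :, None] ** 2
                        + x[None, None, :] ** 2))
        vol = ScalarVolume(blob)
        up = resample_to_grid(vol, (64, 64, 64))
        back = resample_to_grid(up, (32, 32, 32))
        assert np.abs(back.values - blob).max() < 0.02

    def test_rejects_degenerate_target(self):
        with pytest.raises(ParameterError):
            resample_to_grid(ScalarVolume(np.zeros((4, 4, 4))), (1, 8, 8))


class TestNormalize:
    def test_two_point_map(self):
        vals = np.full((4, 4, 4), -1000.0)
        vals[0, 0, 0] = 0.0
        out = normalize_intensity(ScalarVolume(vals))
        assert out.values.min() == 0.0 and out.values.max() == 1.0
        assert out.values[0, 0, 0] == 1.0

    def test_idempotent_on_unit_range(self, rng):
        vals = rng.uniform(0, 1, (6, 6, 6))
        vals.flat[0], vals.flat[-1] = 0.0, 1.0
        out = normalize_intensity(ScalarVolume(vals))
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_intensity(ScalarVolume(np.full((4, 4, 4), 7.0)))

    @settings(max_examples=25, deadline=None)
    @given(hnp.arrays(np.float64, (5, 5, 5),
                      elements=st.floats(-1000, 1000, allow_nan=False)))
    def test_monotone(self, vals):
        if np.ptp(vals) == 0:
            return
        out = normalize_intensity(ScalarVolume(vals)).values
        a, b = vals.ravel(), out.ravel()
        order = np.argsort(a, kind="stable")
        sa, sb = a[order], b[order]
        # strict monotonicity is only resolvable above float precision
        strict = (sa[1:] - sa[:-1]) > 1e-9 * np.ptp(a)
        assert np.all(sb[1:][strict] > sb[:-1][strict])


class TestMedianFilter:
    def test_constant_unchanged(self):
        vol = ScalarVolume(np.full((6, 6, 6), 2.0))
        np.testing.assert_array_equal(median_filter(vol, 5).values, 2.0)

    def test_impulse_removed(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 100.0
        out = median_filter(ScalarVolume(vals), 5)
        assert out.values.max() == 0.0

    def test_matches_brute_force_neighborhood_median(self, rng):
        vals = rng.normal(size=(9, 9, 9))
        out = median_filter(ScalarVolume(vals), 3).values
        padded = np.pad(vals, 1, mode="edge")
        for idx in [(0, 0, 0), (4, 4, 4), (8, 8, 8), (2, 7, 5), (0, 8, 3)]:
            i, j, k = idx
            nb = padded[i:i + 3, j:j + 3, k:k + 3]
            assert out[idx] == pytest.approx(np.median(nb))

    def test_even_patch_rejected(self):
        with pytest.raises(ParameterError):
            median_filter(ScalarVolume(np.zeros((4, 4, 4))), 4)


class TestPreprocessPair:
    def test_pair_grid_margin_and_round_trip(self, small_case):
        pair = preprocess_pair(small_case.inhale, small_case.exhale,
                               small_case.inhale_mask, small_case.exhale_mask,
                               grid_size=48, margin=10)
        for member in (pair.inhale_norm, pair.exhale_norm, pair.exhale_hu,
                       pair.inhale_mask, pair.exhale_mask):
            assert member.shape == (48, 48, 48)
        assert min(_face_distances(pair.inhale_mask.values)) >= 10
        # normalized members span [0, 1]; HU copy keeps HU semantics
        assert pair.inhale_norm.values.min() == 0.0
        assert pair.inhale_norm.values.max() == 1.0
        assert pair.exhale_hu.values.min() < -500.0
        # geometry record inverts to within half a voxel
        pts = np.array([[0.0, 0.0, 0.0], [24.0, 30.0, 40.0]])
        np.testing.assert_allclose(
            pair.geometry.to_processed(pair.geometry.to_original(pts)), pts, atol=0.5)
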