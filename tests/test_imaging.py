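import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cootseg import (
    AUGMENTATIONS,
    BinaryMask,
    IntensityImage,
    NormalizationSpec,
    augment,
    load_image,
    load_mask,
    normalize,
    save_image,
    save_mask,
)
from cootseg.exceptions import ArgumentError, DomainError, FormatError, ShapeError
from cootseg.imaging import write_dicom_series


class TestContainers:
    def test_rejects_non_finite_values(self):
        with pytest.raises(DomainError):
            IntensityImage(np.array([[1.0, np.nan]]))

    def test_rejects_bad_ndim(self):
        with pytest.raises(DomainError):
            IntensityImage(np.arange(4.0))

    def test_mask_values_restricted(self):
        with pytest.raises(DomainError):
            BinaryMask(np.array([[0, 2]]))

    def test_mask_congruence_check(self):
        m = BinaryMask(np.zeros((3, 3), dtype=np.uint8))
        with pytest.raises(ShapeError):
            m.check_congruent(IntensityImage(np.zeros((4, 4))))

    def test_normalization_spec_ordering(self):
        with pytest.raises(DomainError):
            NormalizationSpec(1.0, 1.0)


class TestNormalize:
    @pytest.mark.parametrize(
        "values,spec,expected",
        [
            ([0.0, 5.0, 10.0], (0, 1), [0.0, 0.5, 1.0]),
            ([10.0, 20.0, 40.0], (-1, 1), [-1.0, -1.0 / 3.0, 1.0]),
            ([7.0, 7.0, 7.0], (0, 1), [0.0, 0.0, 0.0]),  # constant -> all ef1
        ],
    )
    def test_examples(self, values, spec, expected):
        img = IntensityImage(np.array([values]))
        out = normalize(img, NormalizationSpec(*spec))
        np.testing.assert_allclose(out.values, np.array([expected]))

    @given(
        arrays(
            np.float64,
            (5, 7),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_range_and_idempotence(self, data):
        img = IntensityImage(data)
        spec = NormalizationSpec(0.0, 1.0)
        out = normalize(img, spec)
        assert out.values.min() >= -1e-12 and out.values.max() <= 1 + 1e-12
        # image already spanning exactly [ef1, ef2] is a fixed point
        again = normalize(out, spec)
        if out.values.max() > out.values.min():
            np.testing.assert_allclose(again.values, out.values, atol=1e-12)


class TestAugment:
    def test_unknown_op(self):
        with pytest.raises(ArgumentError):
            augment(IntensityImage(np.zeros((2, 2))), "rot45")

    @pytest.mark.parametrize("op", sorted(AUGMENTATIONS))
    def test_histogram_preserved(self, op, rng):
        img = IntensityImage(rng.random((6, 9)))
        out = augment(img, op)
        assert np.array_equal(np.sort(out.values.ravel()), np.sort(img.values.ravel()))

    def test_hflip_involution(self, rng):
        img = IntensityImage(rng.random((5, 8)))
        assert np.array_equal(augment(augment(img, "hflip"), "hflip").values, img.values)

    def test_rot90_order_four(self, rng):
        img = IntensityImage(rng.random((5, 8)))
        out = img
        for _ in range(4):
            out = augment(out, "rot90")
        assert np.array_equal(out.values, img.values)

    def test_transpose_definition(self, rng):
        img = IntensityImage(rng.random((4, 6)))
        out = augment(img, "transpose")
        assert out.values.shape == (6, 4)
        assert np.array_equal(out.values, img.values.T)

    def test_3d_applies_per_slice(self, rng):
        vol = IntensityImage(rng.random((3, 4, 5)))
        out = augment(vol, "vflip")
        for k in range(3):
            assert np.array_equal(out.values[k], np.flipud(vol.values[k]))


class TestIO:
    def test_png_roundtrip(self, tmp_path, rng):
        img = IntensityImage(rng.integers(0, 256, (32, 32)).astype(np.float64))
        p = tmp_path / "img.png"
        save_image(img, p)
        back = load_image(p)
        assert back.ndim == 2
        np.testing.assert_array_equal(back.values, img.values)
        assert back.values.min() >= 0 and back.values.max() <= 255

    def test_nifti_roundtrip_preserves_spacing(self, tmp_path, rng):
        img = IntensityImage(rng.random((4, 8, 8)), spacing=(0.7, 0.7, 1.6))
        p = tmp_path / "vol.nii.gz"
        save_image(img, p)
        back = load_image(p)
        np.testing.assert_allclose(back.values, img.values)
        np.testing.assert_allclose(back.spacing, (0.7, 0.7, 1.6), rtol=1e-6)

    def test_dicom_series_roundtrip(self, tmp_path, rng):
        vol = IntensityImage(
            rng.integers(0, 1000, (4, 16, 16)).astype(np.float64), spacing=(1.6, 0.57, 0.57)
        )
        d = tmp_path / "series"
        write_dicom_series(vol, d)
        back = load_image(d)
        assert back.values.shape == (4, 16, 16)
        np.testing.assert_array_equal(back.values, vol.values)
        np.testing.assert_allclose(back.spacing, (1.6, 0.57, 0.57), rtol=1e-6)

    def test_missing_path_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_image(tmp_path / "nope.png")

    def test_mask_loading_binarizes(self, tmp_path):
        save_mask(BinaryMask(np.eye(8, dtype=np.uint8)), tmp_path / "m.png")
        m = load_mask(tmp_path / "m.png")
        assert set(np.unique(m.values)) <= {0, 1}
        np.testing.assert_array_equal(m.values, np.eye(8, dtype=np.uint8))
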