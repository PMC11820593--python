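import numpy as np
import pytest

from ecgfusion.imaging import (
    ImageTriplet,
    ImagingConfig,
    encode_segment,
    gadf,
    mtf,
    paa_compress,
    rp,
    stack_rgb,
)


class TestPAACompress:
    def test_constant_preserved(self):
        assert np.allclose(paa_compress(np.full(1800, 2.5), 100), 2.5)

    def test_1800_to_100(self):
        out = paa_compress(np.arange(1800.0), 100)
        assert out.shape == (100,)

    def test_ramp_frame_means(self):
        out = paa_compress(np.arange(1800.0), 100)
        assert out[0] == pytest.approx(8.5)
        assert out[1] == pytest.approx(26.5)
        assert np.allclose(out, 8.5 + 18.0 * np.arange(100))

    def test_indivisible_pads_last_frame_with_edge(self):
        out = paa_compress(np.array([0.0, 1.0, 2.0, 3.0, 4.0]), 2)
        # frames of ceil(5/2)=3: [0,1,2], [3,4,4(pad)]
        assert np.allclose(out, [1.0, 11.0 / 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paa_compress(np.arange(3.0), 5)


class TestGADF:
    def test_hand_computed_two_point_field(self):
        # phi = (0, 90) degrees for rescaled values (1, 0)
        out = gadf(np.array([1.0, 0.0]), rescale=False)
        assert np.allclose(out, [[0.0, -1.0], [1.0, 0.0]], atol=1e-12)

    def test_diagonal_exactly_zero(self, rng):
        out = gadf(rng.standard_normal(64))
        assert np.all(np.diag(out) == 0.0)

    def test_antisymmetry_exact(self, rng):
        for _ in range(20):
            out = gadf(rng.standard_normal(32))
            assert np.array_equal(out, -out.T)

    def test_values_within_unit_band(self, rng):
        out = gadf(rng.standard_normal(50))
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gadf(np.ones(10))


class TestMTF:
    def test_hand_counted_transitions(self):
        field, W = mtf(np.array([1.0, 1.0, 2.0, 2.0]), Q=2, return_transitions=True)
        assert np.allclose(W, [[0.5, 0.5], [0.0, 1.0]])
        assert field[0, 3] == pytest.approx(0.5)  # M(1,4): state 0 -> state 1

    def test_single_state_all_ones(self):
        field = mtf(np.array([3.0, 3.0, 3.0, 3.0]), Q=4)
        assert np.all(field == 1.0)

    def test_rows_of_transition_matrix_stochastic(self, rng):
        for _ in range(20):
            _, W = mtf(rng.standard_normal(40), Q=6, return_transitions=True)
            assert np.allclose(W.sum(axis=1), 1.0)

    def test_entries_are_probabilities(self, rng):
        field = mtf(rng.standard_normal(60), Q=8)
        assert field.min() >= 0.0 and field.max() <= 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mtf(np.array([1.0]), Q=2)


class TestRP:
    def test_far_points_not_recurrent_at_eps30(self):
        out = rp(np.array([0.0, 100.0]), epsilon=30.0, m=1, tau=1)
        assert np.array_equal(out, np.eye(2, dtype=np.uint8))

    def test_constant_series_all_ones(self):
        out = rp(np.full(5, 7.0), epsilon=30.0)
        assert np.all(out == 1)

    def test_symmetric_unit_diagonal(self, rng):
        for _ in range(20):
            out = rp(rng.standard_normal(30), epsilon=0.5)
            assert np.array_equal(out, out.T)
            assert np.all(np.diag(out) == 1)

    def test_delay_embedding_distance(self):
        # m=2, tau=1: vectors (0,10), (10,0), (0,10); d(v0,v2)=0, d(v0,v1)>eps
        x = np.array([0.0, 10.0, 0.0, 10.0])
        out = rp(x, epsilon=5.0, m=2, tau=1)
        assert out[0, 2] == 1 and out[0, 1] == 0

    def test_incompatible_embedding_rejected(self):
        with pytest.raises(ValueError, match="embedding"):
            rp(np.arange(4.0), epsilon=1.0, m=4, tau=2)


class TestStackRGB:
    def test_midpoint_rounding_half_up(self):
        t = ImageTriplet(
            gadf=np.zeros((2, 2)), mtf=np.full((2, 2), 0.5),
            rp=np.ones((2, 2), dtype=np.uint8),
        )
        rgb = stack_rgb(t)
        assert np.all(rgb[..., 0] == 128)  # (0+1)/2*255 = 127.5 -> 128
        assert np.all(rgb[..., 1] == 128)
        assert np.all(rgb[..., 2] == 255)

    def test_extremes(self):
        t = ImageTriplet(
            gadf=np.array([[-1.0, 1.0], [1.0, -1.0]]),
            mtf=np.array([[0.0, 1.0], [1.0, 0.0]]),
            rp=np.array([[0, 1], [1, 0]], dtype=np.uint8),
        )
        rgb = stack_rgb(t)
        assert rgb[0, 0].tolist() == [0, 0, 0]
        assert rgb[0, 1].tolist() == [255, 255, 255]

    def test_shape_mismatch_rejected(self):
        t = ImageTriplet(gadf=np.zeros((3, 3)), mtf=np.zeros((2, 2)),
                         rp=np.zeros((2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="shape"):
            stack_rgb(t)


class TestEncodeSegment:
    def test_default_shapes_100(self, rng):
        seg = rng.standard_normal(1800)
        triplet = encode_segment(seg)
        assert triplet.gadf.shape == (100, 100)
        assert triplet.mtf.shape == (100, 100)
        assert triplet.rp.shape == (100, 100)
        assert triplet.rgb.shape == (100, 100, 3)
        assert triplet.rgb.dtype == np.uint8

    def test_resize_mode_shapes(self, rng):
        seg = rng.standard_normal(400)
        cfg = ImagingConfig(image_size=50, compression="resize")
        triplet = encode_segment(seg, cfg)
        assert triplet.rgb.shape == (50, 50, 3)
        assert set(np.unique(triplet.rp)) <= {0, 1}

    def test_amplitude_gain_controls_rp(self, rng):
        seg = rng.standard_normal(1800) * 0.5  # physical-unit scale
        dense = encode_segment(seg, ImagingConfig(rp_amplitude_gain=1.0))
        sparse = encode_segment(seg, ImagingConfig(rp_amplitude_gain=200.0))
        assert dense.rp.mean() > sparse.rp.mean()

    def test_png_roundtrip(self, rng, tmp_path):
        from PIL import Image

        triplet = encode_segment(rng.standard_normal(1800))
        path = tmp_path / "seg.png"
        triplet.save_png(path)
        assert np.array_equal(np.asarray(Image.open(path)), triplet.rgb)
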