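import numpy as np
import pytest

from xrayenhance.nsst import (
    ConfigError,
    NsstConfig,
    SubbandSet,
    build_shear_filters,
    load_subbands,
    nsst_forward,
    nsst_inverse,
    pyramid_decompose,
    pyramid_reconstruct,
    save_subbands,
)


class TestConfig:
    def test_direction_counts_are_powers_of_two(self):
        cfg = NsstConfig(3, (2, 3, 4))
        assert cfg.directions == (4, 8, 16)

    @pytest.mark.parametrize("levels,shear", [(0, ()), (7, (1,) * 7), (2, (1,)), (2, (0, 1)), (2, (6, 1))])
    def test_invalid_configs_rejected(self, levels, shear):
        with pytest.raises(ConfigError):
            NsstConfig(levels, shear)


class TestShearFilters:
    @pytest.mark.parametrize("shape", [(64, 64), (33, 47), (100, 60)])
    @pytest.mark.parametrize("l", [1, 2, 3, 4])
    def test_partition_of_unity(self, shape, l):
        ws = build_shear_filters(shape, l)
        assert len(ws) == 2**l
        np.testing.assert_allclose(sum(ws), 1.0, atol=1e-10)
        assert all(w.min() >= 0 for w in ws)

    def test_wedge_centers_select_own_window(self):
        """Along a ray at each window's central orientation the window's
        value is maximal (≈1) among all windows of the level."""
        ws = build_shear_filters((64, 64), 2)
        # pseudo-polar wedge centers for l=2: horizontal, diagonal,
        # vertical, anti-diagonal frequency rays
        rays = {0: (0, 8), 1: (8, 8), 2: (8, 0), 3: (8, -8)}  # (row-freq idx, col-freq idx)
        for k, (fu, fv) in rays.items():
            vals = [w[fu % 64, fv % 64] for w in ws]
            assert int(np.argmax(vals)) == k
            assert vals[k] == pytest.approx(1.0, abs=1e-12)

    def test_real_filter_symmetry(self):
        """w(u, v) = w(−u, −v): the impulse response is real."""
        for w in build_shear_filters((64, 64), 2):
            flipped = np.roll(np.flip(w), shift=(1, 1), axis=(0, 1))
            np.testing.assert_allclose(w[1:, 1:], flipped[1:, 1:], atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ConfigError):
            build_shear_filters((4, 4), 2)


class TestPyramid:
    def test_impulse_additive_reconstruction(self):
        img = np.zeros((32, 32))
        img[16, 16] = 1.0
        low, bp = pyramid_decompose(img, 1)
        np.testing.assert_allclose(low + bp[0], img, atol=1e-8)

    def test_constant_passes_to_low(self):
        low, bp = pyramid_decompose(np.full((16, 16), 0.7), 3)
        for b in bp:
            assert np.abs(b).max() <= 1e-8
        np.testing.assert_allclose(low, 0.7, atol=1e-8)

    def test_random_additive_contract(self, rng):
        img = rng.random((32, 32))
        low, bp = pyramid_decompose(img, 2)
        assert np.abs(pyramid_reconstruct(low, bp) - img).max() <= 1e-8

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pyramid_decompose(np.array([[1.0, np.inf]]), 1)


class TestForwardInverse:
    def test_constant_image_all_high_bands_zero(self):
        bands = nsst_forward(np.full((32, 32), 0.4), NsstConfig(2, (2, 2)))
        for level in bands.high:
            for b in level:
                assert np.abs(b).max() <= 1e-8
        np.testing.assert_allclose(bands.low, 0.4, atol=1e-8)

    def test_band_counts_follow_shear_params(self, rng):
        bands = nsst_forward(rng.random((32, 32)), NsstConfig(3, (2, 3, 4)))
        assert [len(l) for l in bands.high] == [4, 8, 16]
        assert all(b.shape == (32, 32) for l in bands.high for b in l)

    def test_directional_sums_equal_bandpass(self, rng):
        img = rng.random((32, 32))
        bands = nsst_forward(img, NsstConfig(2, (2, 2)))
        _, bp = pyramid_decompose(img, 2)
        for k in range(2):
            np.testing.assert_allclose(sum(bands.high[k]), bp[k], atol=1e-8)

    @pytest.mark.parametrize("shape,j,l", [((64, 64), 4, 2), ((32, 32), 1, 1), ((100, 60), 3, 3)])
    def test_perfect_reconstruction(self, rng, shape, j, l):
        img = rng.random(shape)
        rec = nsst_inverse(nsst_forward(img, NsstConfig(j, (l,) * j)))
        assert np.abs(rec - img).max() <= 1e-6

    def test_zero_subbands_give_zero_image(self):
        cfg = NsstConfig(2, (1, 1))
        z = SubbandSet(
            low=np.zeros((16, 16)),
            high=[[np.zeros((16, 16)) for _ in range(2)] for _ in range(2)],
            config=cfg,
            shape=(16, 16),
        )
        np.testing.assert_array_equal(nsst_inverse(z), 0.0)

    def test_zeroed_high_bands_leave_low_band(self):
        img = np.zeros((32, 32))
        img[16, 16] = 1.0
        bands = nsst_forward(img, NsstConfig(2, (2, 2)))
        low = bands.low.copy()
        for level in bands.high:
            for i in range(len(level)):
                level[i] = np.zeros_like(level[i])
        np.testing.assert_allclose(nsst_inverse(bands), low, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        bands = nsst_forward(rng.random((16, 16)), NsstConfig(1, (1,)))
        bands.high[0][0] = np.zeros((8, 8))
        with pytest.raises(ValueError):
            nsst_inverse(bands)


class TestTransformProperties:
    def test_linearity(self, rng):
        x, y = rng.random((32, 32)), rng.random((32, 32))
        cfg = NsstConfig(2, (2, 2))
        bx, by, bxy = (nsst_forward(v, cfg) for v in (x, y, 2.0 * x + 3.0 * y))
        np.testing.assert_allclose(bxy.low, 2 * bx.low + 3 * by.low, atol=1e-10)
        for k in range(2):
            for d in range(4):
                np.testing.assert_allclose(
                    bxy.high[k][d], 2 * bx.high[k][d] + 3 * by.high[k][d], atol=1e-10
                )

    def test_circular_shift_covariance(self, rng):
        """Undecimated transform: shifting the input circularly shifts
        every band identically (no pseudo-Gibbs from decimation)."""
        x = rng.random((32, 32))
        cfg = NsstConfig(2, (1, 2))
        shift = (5, -7)
        b1 = nsst_forward(np.roll(x, shift, axis=(0, 1)), cfg)
        b0 = nsst_forward(x, cfg)
        np.testing.assert_allclose(b1.low, np.roll(b0.low, shift, axis=(0, 1)), atol=1e-10)
        for k in range(2):
            for d in range(len(b0.high[k])):
                np.testing.assert_allclose(
                    b1.high[k][d], np.roll(b0.high[k][d], shift, axis=(0, 1)), atol=1e-10
                )


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        bands = nsst_forward(rng.random((16, 16)), NsstConfig(2, (1, 2)))
        save_subbands(bands, tmp_path / "sb")
        back = load_subbands(tmp_path / "sb")
        assert back.config == bands.config
        np.testing.assert_allclose(back.low, bands.low, atol=1e-6)
        np.testing.assert_allclose(back.high[1][2], bands.high[1][2], atol=1e-6)
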