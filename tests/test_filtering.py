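"""4-D transforms, shrinkage operators, aggregation and the full denoiser."""

import numpy as np
import pytest
import scipy.fft

from gbm4d.filtering import (
    DenoiseConfig,
    FilteredGroup,
    aggregate,
    gbm4d_denoise,
    hard_threshold,
    ht_filter_group,
    inverse_transform_4d,
    transform_4d,
    wiener_filter_group,
)
from gbm4d.matching import (
    BlockGroup,
    GuideImage,
    GuidedMatcher,
    MatchConfig,
    MatchSet,
    reference_grid,
    stack_group,
)
from gbm4d.vst import StabilizedSinogram


def _group(stack, members=None):
    s = stack.shape[3]
    members = members or [(0, 0)] * s
    ms = MatchSet(reference=members[0], members=members, distances=np.arange(s, dtype=float))
    return BlockGroup(stack=stack, match=ms)


class TestTransform4d:
    def test_round_trip(self, rng):
        x = rng.normal(size=(8, 8, 8, 4))
        back = inverse_transform_4d(transform_4d(x))
        assert np.max(np.abs(back - x)) < 1e-10 * np.max(np.abs(x))

    def test_parseval(self, rng):
        x = rng.normal(size=(8, 8, 3, 5))
        assert np.linalg.norm(transform_4d(x)) == pytest.approx(
            np.linalg.norm(x), rel=1e-12
        )

    def test_constant_stack_concentrates_in_dc(self):
        c = 3.7
        x = np.full((8, 8, 4, 2), c)
        f = transform_4d(x)
        assert f[0, 0, 0, 0] == pytest.approx(c * np.sqrt(8 * 8 * 4 * 2), rel=1e-12)
        f[0, 0, 0, 0] = 0.0
        assert np.max(np.abs(f)) < 1e-10

    def test_rejects_wrong_dimensionality(self, rng):
        with pytest.raises(ValueError):
            transform_4d(rng.normal(size=(8, 8, 8)))

    def test_single_frame_reduces_to_3d_transform_bitwise(self, rng):
        """With |T| = 1 the 4-D transform equals the 3-D transform exactly."""
        x = rng.normal(size=(8, 8, 1, 6))
        via_4d = transform_4d(x)[:, :, 0, :]
        via_3d = scipy.fft.dctn(x[:, :, 0, :], type=2, norm="ortho", axes=(0, 1, 2))
        assert np.array_equal(via_4d, via_3d)


class TestHardThreshold:
    def test_boundary_is_inclusive(self):
        lam, sigma = 2.8, 1.0
        coeffs = np.array([lam * sigma, lam * sigma + 1e-9, -lam * sigma])
        out, n = hard_threshold(coeffs, sigma, lam)
        assert out[0] == 0.0 and out[2] == 0.0
        assert out[1] == coeffs[1]
        assert n == 1

    def test_all_zero(self):
        out, n = hard_threshold(np.zeros((4, 4)), 1.0, 2.8)
        assert not out.any() and n == 0

    def test_matches_scalar_loop(self, rng):
        coeffs = rng.normal(size=(6, 6, 3, 2)) * 4
        sigma, lam = 1.3, 2.8
        out, n = hard_threshold(coeffs, sigma, lam)
        expected = coeffs.copy()
        count = 0
        for idx in np.ndindex(coeffs.shape):
            if abs(coeffs[idx]) <= lam * sigma:
                expected[idx] = 0.0
            elif coeffs[idx] != 0.0:
                count += 1
        assert np.array_equal(out, expected)
        assert n == count


class TestHtFilterGroup:
    def test_bright_constant_group_is_preserved(self):
        cfg = DenoiseConfig()
        grp = _group(np.full((8, 8, 2, 2), 50.0))
        out = ht_filter_group(grp, cfg)
        assert np.allclose(out.stack, grp.stack, atol=1e-10)
        assert out.weight == pytest.approx(1.0 / cfg.sigma**2)

    def test_total_shrinkage_clamps_weight(self):
        cfg = DenoiseConfig(sigma=1.0, lambda_4d=2.8)
        grp = _group(np.full((8, 8, 2, 2), 1e-4))
        out = ht_filter_group(grp, cfg)
        assert np.allclose(out.stack, 0.0)
        assert out.weight == pytest.approx(1.0)  # n_retained clamped to 1

    def test_equals_composition_of_primitives(self, rng):
        cfg = DenoiseConfig(sigma=1.2)
        grp = _group(rng.normal(size=(8, 8, 4, 3)) * 5)
        out = ht_filter_group(grp, cfg)
        coeffs, n = hard_threshold(transform_4d(grp.stack), cfg.sigma, cfg.lambda_4d)
        assert np.array_equal(out.stack, inverse_transform_4d(coeffs))
        assert out.weight == pytest.approx(1.0 / (cfg.sigma**2 * max(n, 1)))

    def test_energy_contraction(self, rng):
        cfg = DenoiseConfig()
        for _ in range(5):
            grp = _group(rng.normal(size=(8, 8, 3, 4)) * 3)
            out = ht_filter_group(grp, cfg)
            assert np.linalg.norm(out.stack) <= np.linalg.norm(grp.stack) + 1e-9


class TestWienerFilterGroup:
    def test_zero_pilot_gives_zero_output(self, rng):
        noisy = _group(rng.normal(size=(8, 8, 2, 2)))
        basic = _group(np.zeros((8, 8, 2, 2)))
        out = wiener_filter_group(noisy, basic, sigma=1.0)
        assert np.allclose(out.stack, 0.0)

    def test_pilot_coefficient_equal_to_sigma_halves_it(self):
        sigma = 1.5
        coeffs = np.zeros((8, 8, 2, 2))
        coeffs[1, 2, 0, 1] = sigma
        stack = inverse_transform_4d(coeffs)
        out = wiener_filter_group(_group(stack), _group(stack), sigma=sigma)
        assert np.allclose(out.stack, 0.5 * stack, atol=1e-12)

    def test_vanishing_sigma_is_passthrough(self, rng):
        noisy = _group(rng.normal(size=(8, 8, 3, 2)) * 4)
        basic = _group(noisy.stack + rng.normal(size=noisy.stack.shape) * 0.01)
        out = wiener_filter_group(noisy, basic, sigma=1e-8)
        assert np.allclose(out.stack, noisy.stack, atol=1e-8)

    def test_energy_contraction(self, rng):
        noisy = _group(rng.normal(size=(8, 8, 3, 2)) * 2)
        basic = _group(rng.normal(size=(8, 8, 3, 2)) * 2)
        out = wiener_filter_group(noisy, basic, sigma=1.0)
        assert np.linalg.norm(out.stack) <= np.linalg.norm(noisy.stack) + 1e-9

    def test_shape_mismatch_rejected(self, rng):
        a = _group(rng.normal(size=(8, 8, 2, 2)))
        b = _group(rng.normal(size=(8, 8, 2, 3)))
        with pytest.raises(ValueError):
            wiener_filter_group(a, b, sigma=1.0)


class TestAggregate:
    def test_single_block_identity_with_flat_window(self, rng):
        stack = rng.random((8, 8, 2, 1))
        ms = MatchSet(reference=(4, 4), members=[(4, 4)], distances=[0.0])
        out = aggregate(
            [FilteredGroup(stack=stack, weight=1.0, match=ms)],
            (16, 16),
            kaiser_beta=2.0,
            require_coverage=False,
        )
        assert np.allclose(out[:, 4:12, 4:12], stack.transpose(2, 0, 1, 3)[:, :, :, 0])

    def test_overlapping_equal_blocks_keep_value(self):
        stack = np.full((8, 8, 1, 1), 7.0)
        groups = []
        for pos, w in (((0, 0), 1.0), ((4, 4), 9.0)):
            ms = MatchSet(reference=pos, members=[pos], distances=[0.0])
            groups.append(FilteredGroup(stack=stack, weight=w, match=ms))
        out = aggregate(groups, (12, 12), kaiser_beta=2.0, require_coverage=False)
        covered = out[0] != 0
        assert np.allclose(out[0][covered], 7.0)

    def test_matches_accumulation_loop(self, rng):
        n, shape = 8, (20, 20)
        kaiser = np.outer(np.kaiser(n, 2.0), np.kaiser(n, 2.0))
        groups = []
        num = np.zeros((3, *shape))
        den = np.zeros(shape)
        for _ in range(4):
            members = [
                (int(rng.integers(0, shape[0] - n)), int(rng.integers(0, shape[1] - n)))
                for _ in range(3)
            ]
            stack = rng.random((n, n, 3, 3))
            w = float(rng.random()) + 0.1
            ms = MatchSet(reference=members[0], members=members, distances=[0, 1, 2])
            groups.append(FilteredGroup(stack=stack, weight=w, match=ms))
            for m, (r, c) in enumerate(members):
                for t in range(3):
                    num[t, r : r + n, c : c + n] += w * kaiser * stack[:, :, t, m]
                den[r : r + n, c : c + n] += w * kaiser
        # tile low-weight background blocks over the grid for full coverage
        for r, c in reference_grid(shape, n, n):
            msb = MatchSet(reference=(r, c), members=[(r, c)], distances=[0.0])
            stack = rng.random((n, n, 3, 1))
            groups.append(FilteredGroup(stack=stack, weight=0.5, match=msb))
            for t in range(3):
                num[t, r : r + n, c : c + n] += 0.5 * kaiser * stack[:, :, t, 0]
            den[r : r + n, c : c + n] += 0.5 * kaiser
        out = aggregate(groups, shape, kaiser_beta=2.0)
        assert np.allclose(out, num / den[None], rtol=1e-12)

    def test_uncovered_voxels_raise(self, rng):
        ms = MatchSet(reference=(0, 0), members=[(0, 0)], distances=[0.0])
        grp = FilteredGroup(stack=rng.random((8, 8, 1, 1)), weight=1.0, match=ms)
        with pytest.raises(RuntimeError):
            aggregate([grp], (32, 32), kaiser_beta=2.0)

    def test_partition_of_unity_reproduces_input(self, rng):
        """Aggregating unfiltered stacks gives back the slice exactly."""
        plane = rng.random((2, 1, 24, 24)) * 10
        sino = StabilizedSinogram(plane, sigma=1.0)
        cfg = MatchConfig(window=15, max_group=4)
        guide = GuideImage(plane[:, 0].sum(axis=0))
        matcher = GuidedMatcher(guide, cfg, sigma_guide=np.sqrt(2))
        groups = []
        for pos in reference_grid((24, 24), cfg.block_size, cfg.step):
            ms = matcher.match(pos)
            grp = stack_group(sino, ms, cfg.block_size, 0)
            groups.append(FilteredGroup(stack=grp.stack, weight=1.0, match=ms))
        out = aggregate(groups, (24, 24), kaiser_beta=2.0)
        assert np.allclose(out, plane[:, 0], rtol=1e-10, atol=1e-10)


class TestGbm4dDenoise:
    def test_zero_sinogram_stays_zero(self):
        sino = StabilizedSinogram(np.zeros((2, 1, 24, 24)), sigma=1.0)
        out = gbm4d_denoise(sino, DenoiseConfig(match=MatchConfig(window=15)))
        assert np.allclose(out.data, 0.0)

    def test_near_noiseless_passthrough(self, small_stabilized):
        """With sigma ~ 0 the two-step filter is a near-identity."""
        cfg = DenoiseConfig(sigma=1e-6, match=MatchConfig(window=15))
        out = gbm4d_denoise(small_stabilized, cfg)
        rel = np.abs(out.data - small_stabilized.data) / np.abs(small_stabilized.data)
        assert rel.max() < 1e-4

    def test_preserves_shape_and_is_deterministic(self, small_stabilized):
        cfg = DenoiseConfig(match=MatchConfig(window=15))
        out1 = gbm4d_denoise(small_stabilized, cfg)
        out2 = gbm4d_denoise(small_stabilized, cfg)
        assert out1.data.shape == small_stabilized.data.shape
        assert np.array_equal(out1.data, out2.data)

    def test_denoising_gain_and_step2_improvement(self):
        """On noisy Shepp-Logan sinograms the filter raises PSNR over the
        noisy input, and the Wiener step improves on the basic estimate
        on average (10 seeded replicates)."""
        from skimage.data import shepp_logan_phantom
        from skimage.transform import radon, resize

        from gbm4d.vst import anscombe_forward

        img = resize(shepp_logan_phantom(), (64, 64), anti_aliasing=True)
        thetas = np.arange(0, 180, 180 / 64)
        clean = radon(img, theta=thetas, circle=True).T  # (angles, bins)
        clean4 = np.stack([clean * (1 - 0.03 * t) for t in range(4)])[:, None]
        clean4 *= 1e5 / clean4[0].sum()  # ~1e5 counts per frame
        target = anscombe_forward(clean4)
        cfg = DenoiseConfig(match=MatchConfig(window=19, block_size=4, step=2))

        def psnr(x):
            rmse = np.sqrt(np.mean((x - target) ** 2))
            return 20 * np.log10(target.max() / rmse)

        gains, step2_minus_step1 = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = anscombe_forward(rng.poisson(clean4))
            sino = StabilizedSinogram(noisy, sigma=1.0)
            final, basic = gbm4d_denoise(sino, cfg, return_basic=True)
            gains.append(psnr(final.data) - psnr(noisy))
            step2_minus_step1.append(psnr(final.data) - psnr(basic.data))
        assert min(gains) > 0
        assert np.mean(step2_minus_step1) >= 0
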