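"""Degradation operators against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusenhance.degrade import (
    AugmentConfig,
    DegradationSpec,
    augment,
    craft_depth_map,
    gamma_darken,
    gaussian_blur,
    gaussian_kernel,
    interpolate,
    rotate,
    synthesize_haze,
    transmission,
)
from fundusenhance.image import FundusImage, ImagePair


def _rand(rng, h=7, w=7):
    return rng.uniform(0.0, 1.0, size=(h, w, 3))


# ---------------------------------------------------------------------
# closed-form identities and limits
# ---------------------------------------------------------------------

class TestClosedForms:
    def test_interpolation_endpoints(self, rng):
        lq, hq = _rand(rng), _rand(rng)
        assert np.array_equal(interpolate(lq, hq, 0.0), lq)
        assert np.array_equal(interpolate(lq, hq, 1.0), hq)

    def test_interpolation_scalar(self):
        out = interpolate(np.full((7, 7, 3), 0.2), np.full((7, 7, 3), 0.6), 0.4)
        assert np.allclose(out, 0.36, atol=1e-12)

    def test_gamma_identity_and_scalar(self, rng):
        img = _rand(rng)
        assert np.allclose(gamma_darken(img, 1.0), img, atol=1e-15)
        assert np.allclose(gamma_darken(np.full((7, 7, 3), 0.25), 0.5), 0.0625, atol=1e-12)

    def test_gamma_never_brightens(self, rng):
        img = _rand(rng)
        assert np.all(gamma_darken(img, 0.5) <= img + 1e-15)

    def test_haze_zero_extinction_is_identity(self, rng):
        img = _rand(rng)
        depth = craft_depth_map((7, 7), "constant", {"value": 1.0})
        assert np.allclose(synthesize_haze(img, depth, 0.0), img, atol=1e-15)

    def test_haze_opaque_limit_is_airlight(self, rng):
        img = _rand(rng)
        depth = craft_depth_map((7, 7), "constant", {"value": 1.0})
        out = synthesize_haze(img, depth, 1e4, airlight=(0.9, 0.8, 0.7))
        assert np.allclose(out, np.array([0.9, 0.8, 0.7]), atol=1e-12)

    def test_haze_scalar_case(self):
        # transmission 0.5 and unit airlight: 0.8*0.5 + 0.5*1.0 = 0.9
        img = np.full((7, 7, 3), 0.8)
        depth = craft_depth_map((7, 7), "constant", {"value": 1.0})
        out = synthesize_haze(img, depth, np.log(2.0), airlight=(1.0, 1.0, 1.0))
        assert np.allclose(out, 0.9, atol=1e-12)

    def test_transmission_values(self):
        assert transmission(np.zeros((3, 3)), 5.0) == pytest.approx(1.0)
        assert np.allclose(transmission(np.ones((3, 3)), np.log(2.0)), 0.5, atol=1e-15)
        assert np.allclose(transmission(np.ones((3, 3)), 0.0), 1.0)

    def test_transmission_monotone_in_beta_and_depth(self):
        d = np.linspace(0.1, 2.0, 5)
        t1, t2 = transmission(d, 0.5), transmission(d, 1.5)
        assert np.all(t2 < t1)
        assert np.all(np.diff(transmission(d, 1.0)) < 0)

    def test_rotation_group_identities(self, rng):
        img = _rand(rng, 8, 8)
        out = img
        for _ in range(4):
            out = rotate(out, 90)
        assert np.array_equal(out, img)
        assert np.array_equal(rotate(rotate(img, 180), 180), img)

    def test_rotation_index_permutation(self):
        # 2x3 asymmetric array: counterclockwise 90 deg flips columns up
        arr = np.arange(6, dtype=float).reshape(2, 3, 1).repeat(3, axis=2) / 10.0
        out = rotate(arr, 90)
        assert out.shape[:2] == (3, 2)
        expected = np.transpose(arr, (1, 0, 2))[::-1]
        assert np.array_equal(out, expected)


# ---------------------------------------------------------------------
# brute-force loop oracles on random 7x7 inputs
# ---------------------------------------------------------------------

def _blur_oracle(img, k, sigma):
    """Direct double-sum convolution with reflected indexing."""
    kern = gaussian_kernel(k, sigma)
    r = k // 2
    h, w, _ = img.shape

    def refl(i, n):
        if i < 0:
            return -i
        if i >= n:
            return 2 * (n - 1) - i
        return i

    out = np.zeros_like(img)
    for y in range(h):
        for x in range(w):
            for i in range(-r, r + 1):
                for j in range(-r, r + 1):
                    out[y, x] += img[refl(y - i, h), refl(x - j, w)] * kern[i + r, j + r]
    return out


class TestLoopOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_blur_matches_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        img = _rand(rng)
        assert np.allclose(gaussian_blur(img, 5, 1.0), _blur_oracle(img, 5, 1.0), atol=1e-10)

    def test_interpolate_matches_loop(self, rng):
        lq, hq, lam = _rand(rng), _rand(rng), 0.37
        expected = np.empty_like(lq)
        for idx in np.ndindex(lq.shape):
            expected[idx] = (hq[idx] - lq[idx]) * lam + lq[idx]
        assert np.allclose(interpolate(lq, hq, lam), expected, atol=1e-12)

    def test_haze_matches_loop(self, rng):
        img = _rand(rng)
        depth = craft_depth_map((7, 7), "radial", {"peak": 2.0})
        beta, A = 0.8, np.array([0.9, 0.85, 0.8])
        out = synthesize_haze(img, depth, beta, A)
        expected = np.empty_like(img)
        for y in range(7):
            for x in range(7):
                t = np.exp(-beta * depth.values[y, x])
                for c in range(3):
                    expected[y, x, c] = img[y, x, c] * t + (1 - t) * A[c]
        assert np.allclose(out, expected, atol=1e-12)

    def test_gamma_matches_loop(self, rng):
        img, g = _rand(rng), 0.6
        expected = np.empty_like(img)
        for idx in np.ndindex(img.shape):
            expected[idx] = img[idx] ** (1.0 / g)
        assert np.allclose(gamma_darken(img, g), expected, atol=1e-12)


# ---------------------------------------------------------------------
# operator invariants
# ---------------------------------------------------------------------

class TestInvariants:
    def test_kernel_normalized(self):
        for k, s in [(3, 0.5), (5, 1.0), (7, 2.5)]:
            assert abs(gaussian_kernel(k, s).sum() - 1.0) < 1e-12

    def test_blur_fixes_constant_image(self):
        img = np.full((9, 9, 3), 0.7)
        assert np.allclose(gaussian_blur(img, 5, 1.0), 0.7, atol=1e-12)

    def test_blur_impulse_reproduces_kernel(self):
        img = np.zeros((11, 11, 3))
        img[5, 5] = 1.0
        out = gaussian_blur(img, 5, 1.0)
        assert np.allclose(out[3:8, 3:8, 0], gaussian_kernel(5, 1.0), atol=1e-12)

    def test_haze_with_self_airlight_is_identity(self, rng):
        # constant image equal to airlight: H*t + (1-t)*A = A for any t
        A = (0.3, 0.5, 0.7)
        img = np.broadcast_to(np.array(A), (7, 7, 3)).copy()
        depth = craft_depth_map((7, 7), "axial_ramp", {"peak": 3.0}, seed=1)
        assert np.allclose(synthesize_haze(img, depth, 1.3, A), img, atol=1e-12)

    @given(lam1=st.floats(0, 1), lam2=st.floats(0, 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_interpolation_monotone_in_lambda(self, lam1, lam2):
        rng = np.random.default_rng(5)
        lq = rng.uniform(0, 0.5, size=(5, 5, 3))
        hq = lq + rng.uniform(0, 0.5, size=(5, 5, 3))  # hq >= lq
        lo, hi = sorted([lam1, lam2])
        assert np.all(interpolate(lq, hq, lo) <= interpolate(lq, hq, hi) + 1e-12)

    @pytest.mark.parametrize("op", ["blur", "haze", "gamma"])
    def test_range_preserved(self, rng, op):
        img = _rand(rng, 16, 16)
        if op == "blur":
            out = gaussian_blur(img, 5, 2.0)
        elif op == "haze":
            out = synthesize_haze(img, craft_depth_map((16, 16), "radial"), 1.0)
        else:
            out = gamma_darken(img, 0.4)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestDepthMaps:
    def test_constant_gives_homogeneous_transmission(self):
        d = craft_depth_map((8, 8), "constant", {"value": 2.0})
        t = transmission(d, 0.7)
        assert np.allclose(t, np.exp(-0.7 * 2.0))

    def test_axial_ramp_touches_zero(self):
        d = craft_depth_map((32, 32), "axial_ramp", {"peak": 1.5}, seed=4)
        assert d.values.min() == pytest.approx(0.0)
        assert d.values.max() == pytest.approx(1.5)

    def test_radial_peak_at_radius(self):
        d = craft_depth_map((64, 64), "radial",
                            {"peak": 2.5, "center": (32.0, 32.0), "radius": 20.0})
        rho20 = d.values[32, 12]  # 20 px left of center
        assert rho20 == pytest.approx(2.5, rel=1e-6)

    def test_unknown_family_refused(self):
        with pytest.raises(ValueError, match="family"):
            craft_depth_map((8, 8), "spiral")


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(kind="nonsense"),
        dict(kind="gamma", gamma=0.0),
        dict(kind="gamma", gamma=1.5),
        dict(kind="interp", lam=1.2),
        dict(kind="haze", beta=-1.0, airlight=(1, 1, 1), depth_family="radial"),
        dict(kind="rotate", angle=45),
        dict(kind="blur", kernel_size=5, sigma=1.0, gamma=0.5),  # foreign field
    ])
    def test_invalid_specs_refused(self, kwargs):
        with pytest.raises(ValueError):
            DegradationSpec(**kwargs)

    def test_even_kernel_refused(self, rng):
        with pytest.raises(ValueError, match="odd"):
            gaussian_blur(_rand(rng), 4, 1.0)

    def test_bad_rotation_refused(self, rng):
        with pytest.raises(ValueError):
            rotate(_rand(rng), 45)

    def test_shape_mismatch_refused(self, rng):
        with pytest.raises(ValueError):
            interpolate(_rand(rng, 7, 7), _rand(rng, 8, 8), 0.5)


class TestAugment:
    def _pair(self, rng):
        pix = rng.uniform(0, 1, size=(64, 64, 3))
        hq = FundusImage(pix)
        lq = FundusImage(np.clip(pix * 0.5, 0, 1))
        return ImagePair(lq, hq)

    def test_rotations_only_quadruples(self, rng):
        cfg = AugmentConfig(rotations=True, interp_lams=(), blur=False, haze=False, gamma=False)
        assert len(augment([self._pair(rng)], cfg)) == 4

    def test_interpolation_only_gives_five(self, rng):
        cfg = AugmentConfig(rotations=False, interp_lams=(0.2, 0.4, 0.6, 0.8),
                            blur=False, haze=False, gamma=False)
        out = augment([self._pair(rng)], cfg)
        assert len(out) == 5

    def test_disabled_config_is_noop(self, rng):
        pairs = [self._pair(rng)]
        assert augment(pairs, AugmentConfig.none()) == pairs

    def test_full_config_counts_and_pairing(self, rng):
        pair = self._pair(rng)
        out = augment([pair], AugmentConfig(), seed=9)
        # 1 original + 3 rotations + 4 interpolations + blur + haze + gamma
        assert len(out) == 11
        for p in out[4:]:  # non-rotated entries keep the source HQ
            assert p.hq.pixels.shape == pair.hq.pixels.shape
        degraded = out[-3:]
        for p in degraded:
            assert np.array_equal(p.hq.pixels, pair.hq.pixels)
            assert not np.array_equal(p.lq.pixels, p.hq.pixels)
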