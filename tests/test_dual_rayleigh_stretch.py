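import math

import numpy as np
import pytest
from scipy import stats

from uie.dual_rayleigh_stretch import (
    DegenerateRegionError,
    RayleighParams,
    dual_stretch_channel,
    global_stretch,
    rayleigh_cdf,
    rayleigh_inverse_cdf,
    rayleigh_region_stretch,
    split_at_mean,
)


class TestGlobalStretch:
    def test_affine_endpoints_and_midpoint(self):
        ch = np.array([[50.0, 150.0, 100.0]])
        out = global_stretch(ch)
        np.testing.assert_allclose(out, [[0.0, 255.0, 127.5]])

    def test_full_range_identity(self):
        ch = np.array([[0.0, 100.0], [200.0, 255.0]])
        np.testing.assert_allclose(global_stretch(ch), ch)

    def test_elementwise_oracle(self, rng):
        ch = rng.uniform(20, 180, size=(3, 3))
        i_min, i_max = ch.min(), ch.max()
        expected = np.array(
            [
                [(v - i_min) * 255.0 / (i_max - i_min) for v in row]
                for row in ch
            ]
        )
        np.testing.assert_allclose(global_stretch(ch), expected, rtol=1e-12)

    def test_monotone(self, rng):
        ch = rng.uniform(0, 255, size=(1, 50))
        order = np.argsort(ch[0])
        out = global_stretch(ch)[0]
        assert np.all(np.diff(out[order]) >= 0)

    def test_constant_channel_warns_and_passes_through(self):
        ch = np.full((2, 2), 42.0)
        with pytest.warns(UserWarning, match="constant"):
            np.testing.assert_array_equal(global_stretch(ch), ch)


class TestRayleighClosedForms:
    def test_cdf_at_sigma(self):
        assert rayleigh_cdf(5.0, 5.0) == pytest.approx(1 - math.exp(-0.5))

    def test_inverse_at_zero(self):
        assert rayleigh_inverse_cdf(0.0, 3.0) == 0.0

    @pytest.mark.parametrize("x_factor", [0.1, 1.0, 3.0])
    def test_mutually_inverse(self, x_factor):
        sigma = 102.0
        x = x_factor * sigma
        assert rayleigh_inverse_cdf(rayleigh_cdf(x, sigma), sigma) == pytest.approx(
            x, rel=1e-12
        )

    def test_against_scipy(self, rng):
        """Independent cross-check of both closed forms against scipy.stats."""
        sigma = 77.0
        x = rng.uniform(0, 400, size=64)
        np.testing.assert_allclose(
            rayleigh_cdf(x, sigma), stats.rayleigh.cdf(x, scale=sigma), rtol=1e-12
        )
        u = rng.uniform(0, 0.999, size=64)
        np.testing.assert_allclose(
            rayleigh_inverse_cdf(u, sigma),
            stats.rayleigh.ppf(u, scale=sigma),
            rtol=1e-10,
        )

    def test_guards(self):
        with pytest.raises(ValueError):
            rayleigh_inverse_cdf(1.0, 5.0)
        with pytest.raises(ValueError):
            rayleigh_cdf(1.0, -1.0)
        with pytest.raises(ValueError):
            rayleigh_cdf(-0.1, 1.0)


class TestRegionStretch:
    def test_endpoints(self):
        ch = np.array([[10.0, 90.0]])
        out = rayleigh_region_stretch(ch, 10.0, 90.0)
        assert out[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert out[0, 1] == pytest.approx(255.0, rel=1e-12)

    def test_sigma_closed_form_inversion(self):
        # at alpha 0.4 (sigma = 102) the input fraction F(sigma)/F(255)
        # must map exactly onto 102
        sigma = 102.0
        u = (1 - math.exp(-0.5)) / (1 - math.exp(-(255**2) / (2 * sigma**2)))
        ch = np.array([[u * 100.0]])
        out = rayleigh_region_stretch(ch, 0.0, 100.0, RayleighParams(alpha=0.4))
        assert out[0, 0] == pytest.approx(102.0, rel=1e-12)

    def test_toy_channel_against_independent_oracle(self):
        ch = np.array([[0.0, 60.0, 128.0, 200.0, 255.0]])
        params = RayleighParams(alpha=0.4)
        out = rayleigh_region_stretch(ch, 0.0, 128.0, params)
        # independent evaluation of the truncated-inverse-CDF formula
        sigma = 0.4 * 255.0
        f_top = 1 - math.exp(-(255.0**2) / (2 * sigma**2))
        expected = []
        for v in ch[0]:
            u = min(max((v - 0.0) / 128.0, 0.0), 1.0)
            expected.append(sigma * math.sqrt(-2 * math.log(1 - u * f_top)))
        np.testing.assert_allclose(out[0], expected, rtol=1e-12)

    def test_saturation_outside_region(self):
        ch = np.array([[0.0, 255.0]])
        out = rayleigh_region_stretch(ch, 100.0, 200.0)
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(255.0)

    def test_monotone_in_input(self, rng):
        ch = np.sort(rng.uniform(0, 255, size=(1, 200)))
        out = rayleigh_region_stretch(ch, 40.0, 210.0)
        assert np.all(np.diff(out[0]) >= 0)

    def test_output_range(self, rng):
        out = rayleigh_region_stretch(rng.uniform(0, 255, (10, 10)), 50.0, 180.0)
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_degenerate_region_rejected(self):
        with pytest.raises(DegenerateRegionError):
            rayleigh_region_stretch(np.zeros((2, 2)), 5.0, 5.0)

    def test_literal_mode_range(self, rng):
        out = rayleigh_region_stretch(
            rng.uniform(0, 255, (8, 8)), 0.0, 255.0, RayleighParams(mode="literal")
        )
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(255.0)

    def test_truncated_rayleigh_distribution_ks(self):
        """100k uniform samples mapped through the quantile stretch follow the
        truncated Rayleigh distribution (KS distance < 0.02)."""
        rng = np.random.default_rng(12345)
        lo, hi = 30.0, 220.0
        sample = rng.uniform(lo, hi, size=(1, 100_000))
        params = RayleighParams(alpha=0.4)
        out = rayleigh_region_stretch(sample, lo, hi, params).ravel()
        sigma = params.sigma
        f_top = 1 - math.exp(-(255.0**2) / (2 * sigma**2))
        ks = stats.kstest(out, lambda y: stats.rayleigh.cdf(y, scale=sigma) / f_top)
        assert ks.statistic < 0.02


class TestSplitAndDual:
    def test_split_is_mean_of_values(self):
        ch = np.arange(256, dtype=float).reshape(16, 16)
        b = split_at_mean(ch)
        assert (b.lo, b.hi) == (0.0, 255.0)
        assert b.split == pytest.approx(127.5)

    def test_constant_channel_flagged(self):
        with pytest.warns(UserWarning):
            b = split_at_mean(np.full((3, 3), 9.0))
        assert b.degenerate and (b.lo, b.split, b.hi) == (9.0, 9.0, 9.0)

    def test_random_split_matches_summation_oracle(self, rng):
        ch = rng.uniform(0, 255, size=(7, 5))
        total = 0.0
        for row in ch:
            for v in row:
                total += v
        assert split_at_mean(ch).split == pytest.approx(total / 35, rel=1e-12)

    def test_saturation_rule(self, rng):
        ch = rng.uniform(0, 255, size=(6, 6))
        b = split_at_mean(ch)
        lower, upper = dual_stretch_channel(ch)
        assert np.all(lower[ch >= b.split] == pytest.approx(255.0))
        assert np.all(upper[ch <= b.split] == 0.0)

    def test_lower_dominates_upper(self, rng):
        ch = rng.uniform(0, 255, size=(6, 6))
        lower, upper = dual_stretch_channel(ch)
        assert np.all(lower >= upper)

    def test_dual_against_per_pixel_oracle(self, rng):
        ch = rng.uniform(10, 240, size=(4, 4))
        lower, upper = dual_stretch_channel(ch, RayleighParams(alpha=0.4))
        # independent scalar evaluation of both region maps
        sigma = 0.4 * 255.0
        f_top = 1 - math.exp(-(255.0**2) / (2 * sigma**2))

        def region_map(v, lo, hi):
            u = min(max((v - lo) / (hi - lo), 0.0), 1.0)
            return sigma * math.sqrt(-2 * math.log(1 - u * f_top))

        lo, hi, split = ch.min(), ch.max(), ch.mean()
        for i in range(4):
            for j in range(4):
                assert lower[i, j] == pytest.approx(
                    region_map(ch[i, j], lo, split), rel=1e-12
                )
                assert upper[i, j] == pytest.approx(
                    region_map(ch[i, j], split, hi), rel=1e-12
                )

    def test_constant_channel_passthrough(self):
        ch = np.full((3, 3), 7.0)
        with pytest.warns(UserWarning):
            lower, upper = dual_stretch_channel(ch)
        np.testing.assert_array_equal(lower, ch)
        np.testing.assert_array_equal(upper, ch)
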