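"""Background fitting, smoothing, Kalpha2 stripping and normalization."""

import numpy as np
import pytest

import powderid as pid
from powderid import preprocess as pre
from powderid.errors import GridMismatch, RangeError, WindowTooLarge, ZeroPattern


@pytest.fixture
def params():
    return pre.PreprocessParams()


def _ramp(n=100, start=5.0, step=0.019, a=2.0, b=3.0):
    t = start + step * np.arange(n)
    return pid.Pattern(t, a + b * t)


class TestResample:
    def test_identity_on_own_grid(self, small_pattern):
        p = small_pattern
        q = pre.resample(p, p.two_theta[0], p.two_theta[-1], p.step)
        np.testing.assert_allclose(q.intensity, p.intensity, rtol=1e-12)

    def test_halving_step_keeps_node_values(self, small_pattern):
        p = small_pattern
        q = pre.resample(p, p.two_theta[0], p.two_theta[-1], p.step / 2)
        np.testing.assert_allclose(q.intensity[::2], p.intensity, rtol=1e-12)

    def test_midpoint_of_linear_ramp_is_mean_of_neighbours(self):
        p = _ramp()
        q = pre.resample(p, p.two_theta[0] + p.step / 2, p.two_theta[-1], p.step)
        expected = 0.5 * (p.intensity[:-1] + p.intensity[1:])
        np.testing.assert_allclose(q.intensity, expected[: len(q)], rtol=1e-12)

    def test_range_error_beyond_one_step(self, small_pattern):
        p = small_pattern
        with pytest.raises(RangeError):
            pre.resample(p, p.two_theta[0] - 2 * p.step, p.two_theta[-1], p.step)


class TestBackground:
    def test_polynomial_input_is_fixed_point(self):
        t = 5.0 + 0.019 * np.arange(200)
        y = 10 + 0.5 * t - 0.02 * t**2 + 3e-4 * t**3
        p = pid.Pattern(t, y)
        bg = pre.fit_background(p, pre.PreprocessParams(bg_degree=3))
        assert np.max(np.abs(bg.intensity - y)) <= 1e-6 * np.max(np.abs(y))

    def test_zero_input_gives_zero_background(self, params):
        t = 5.0 + 0.019 * np.arange(64)
        bg = pre.fit_background(pid.Pattern(t, np.zeros(64)), params)
        np.testing.assert_allclose(bg.intensity, 0.0, atol=1e-9)

    def test_constant_plus_peak_recovered(self, params, single_peak_phase, clean_sim):
        cfg = clean_sim(bg_coeffs=(100.0,))
        p = pid.render(single_peak_phase(30.0), cfg)
        bg = pre.fit_background(p, params)
        rms = np.sqrt(np.mean((bg.intensity - 100.0) ** 2))
        assert rms < 2.0

    def test_subtract_clips_at_zero(self, small_pattern, params):
        bg = pre.fit_background(small_pattern, params)
        sub = pre.subtract_background(small_pattern, bg)
        assert sub.intensity.min() >= 0.0

    def test_subtract_self_gives_zero(self, small_pattern):
        out = pre.subtract_background(small_pattern, small_pattern)
        np.testing.assert_allclose(out.intensity, 0.0)

    def test_grid_mismatch(self, small_pattern):
        other = pid.Pattern(small_pattern.two_theta + 1.0, small_pattern.intensity)
        with pytest.raises(GridMismatch):
            pre.subtract_background(small_pattern, other)


class TestSmooth:
    @pytest.mark.parametrize("coeffs", [(2.0, 3.0), (1.0, -0.5, 0.25)])
    def test_low_order_polynomials_unchanged(self, params, coeffs):
        t = 5.0 + 0.019 * np.arange(150)
        y = np.polynomial.polynomial.polyval(t - t.mean(), coeffs)
        p = pid.Pattern(t, y)
        out = pre.smooth(p, params)
        assert np.max(np.abs(out.intensity - y)) <= 1e-9 * max(1.0, np.abs(y).max())

    def test_noise_variance_reduced(self, params):
        rng = np.random.default_rng(42)
        t = 5.0 + 0.019 * np.arange(2000)
        y = 100.0 + rng.normal(0, 10, len(t))
        out = pre.smooth(pid.Pattern(t, y), params)
        assert np.std(out.intensity) < 10.0

    def test_window_too_large(self, params):
        t = 5.0 + 0.019 * np.arange(9)
        with pytest.raises(WindowTooLarge):
            pre.smooth(pid.Pattern(t, np.ones(9)),
                       pre.PreprocessParams(smooth_window=11))


class TestStripKalpha2:
    def test_zero_ratio_is_identity(self, small_pattern):
        params = pre.PreprocessParams(kalpha=pre.KAlphaParams(ratio=0.0))
        out = pre.strip_kalpha2(small_pattern, params)
        np.testing.assert_array_equal(out.intensity, small_pattern.intensity)

    def test_zero_pattern_stays_zero(self, params):
        t = 5.0 + 0.019 * np.arange(64)
        out = pre.strip_kalpha2(pid.Pattern(t, np.zeros(64)), params)
        np.testing.assert_allclose(out.intensity, 0.0)

    @pytest.mark.parametrize("position", [15.0, 30.0, 50.0])
    def test_doublet_residual_under_5_percent(self, params, single_peak_phase,
                                              clean_sim, position):
        on = pid.render(single_peak_phase(position), clean_sim(doublet=True))
        off = pid.render(single_peak_phase(position), clean_sim(doublet=False))
        ka2 = float(pid.simulate.kalpha2_position(position))
        i2 = int(np.argmin(np.abs(on.two_theta - ka2)))
        original = on.intensity[i2] - off.intensity[i2]
        stripped = pre.strip_kalpha2(on, params)
        residual = abs(stripped.intensity[i2] - off.intensity[i2])
        assert residual < 0.05 * original

    def test_mass_reducing_and_removed_fraction(self, params, single_peak_phase,
                                                clean_sim):
        on = pid.render(single_peak_phase(30.0), clean_sim(doublet=True))
        stripped = pre.strip_kalpha2(on, params)
        assert stripped.intensity.sum() <= on.intensity.sum()
        removed = 1.0 - stripped.intensity.sum() / on.intensity.sum()
        r = params.kalpha.ratio
        assert removed == pytest.approx(r / (1.0 + r), abs=0.05)


class TestNormalize:
    def test_unit_max_idempotent(self, small_pattern, params):
        once = pre.normalize(small_pattern, params)
        twice = pre.normalize(once, params)
        np.testing.assert_array_equal(once.intensity, twice.intensity)
        assert once.intensity.max() == 1.0

    def test_scale_invariance(self, small_pattern, params):
        scaled = small_pattern.replace_intensity(7.0 * small_pattern.intensity)
        a = pre.normalize(small_pattern, params)
        b = pre.normalize(scaled, params)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_unit_area(self, small_pattern):
        out = pre.normalize(small_pattern, mode="unit_area")
        assert out.intensity.sum() * out.step == pytest.approx(1.0)

    def test_zero_pattern_raises(self, params):
        t = 5.0 + 0.019 * np.arange(64)
        with pytest.raises(ZeroPattern):
            pre.normalize(pid.Pattern(t, np.zeros(64)), params)


def test_pipeline_stages_share_grid(library6, params):
    p = pid.render(library6[0], pid.SimConfig(seed=9))
    out = pre.preprocess(p, params)
    assert out.same_grid(p)
    assert out.intensity.min() >= 0.0
    assert out.intensity.max() == pytest.approx(1.0)
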