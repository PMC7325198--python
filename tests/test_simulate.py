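"""Synthetic diffractogram generator: profiles, doublets, mixtures, fixtures."""

import numpy as np
import pytest

import powderid as pid
from powderid.errors import BadWeights, ReflectionOutOfRange
from powderid.simulate import kalpha2_position


class TestRender:
    def test_no_reflections_no_background_is_zero(self, clean_sim):
        ph = pid.Phase("empty", np.array([]), np.array([]))
        p = pid.render(ph, clean_sim())
        np.testing.assert_array_equal(p.intensity, 0.0)

    def test_gaussian_half_height_at_half_fwhm(self, single_peak_phase, clean_sim):
        cfg = clean_sim(eta=0.0, fwhm=0.1)
        p = pid.render(single_peak_phase(30.0), cfg)
        apex_idx = int(np.argmax(p.intensity))
        assert abs(p.two_theta[apex_idx] - 30.0) <= cfg.grid.step / 2
        # Gaussian closed form: value at +-fwhm/2 is half the apex value
        x = np.array([30.0 - 0.05, 30.0, 30.0 + 0.05])
        prof = pid.simulate.pseudo_voigt(x, 30.0, 0.1, eta=0.0)
        assert prof[0] == pytest.approx(prof[1] / 2, rel=1e-9)
        assert prof[2] == pytest.approx(prof[1] / 2, rel=1e-9)

    def test_doublet_companion_position_and_ratio(self, single_peak_phase, clean_sim):
        lam1, lam2 = pid.CU_KALPHA1, pid.CU_KALPHA2
        pos = 30.0
        expected = 2 * np.degrees(np.arcsin((lam2 / lam1) * np.sin(np.radians(15.0))))
        assert kalpha2_position(pos) == pytest.approx(expected, abs=1e-9)
        on = pid.render(single_peak_phase(pos), clean_sim(doublet=True))
        off = pid.render(single_peak_phase(pos), clean_sim(doublet=False))
        companion = on.intensity - off.intensity
        i2 = int(np.argmax(companion))
        assert on.two_theta[i2] == pytest.approx(expected, abs=on.step)
        assert companion[i2] / off.intensity.max() == pytest.approx(0.5, rel=0.02)

    def test_linearity_of_reflections(self, clean_sim):
        cfg = clean_sim()
        two = pid.Phase("two", np.array([20.0, 35.0]), np.array([100.0, 50.0]))
        a = pid.Phase("a", np.array([20.0]), np.array([100.0]))
        b = pid.Phase("b", np.array([35.0]), np.array([100.0]))
        # Phase rescales to max 100, so weight the singles back to 100/50 areas
        combo = pid.render(two, cfg).intensity
        parts = pid.render(a, cfg).intensity + 0.5 * pid.render(b, cfg).intensity
        np.testing.assert_allclose(combo, parts, atol=1e-9 * combo.max())

    def test_out_of_range_reflection_warns_and_skips(self, clean_sim):
        ph = pid.Phase("oob", np.array([2.0, 30.0]), np.array([50.0, 100.0]))
        with pytest.warns(ReflectionOutOfRange):
            p = pid.render(ph, clean_sim())
        assert p.intensity.max() > 0

    def test_determinism(self, library6):
        cfg = pid.SimConfig(seed=123)
        a = pid.render(library6[0], cfg)
        b = pid.render(library6[0], cfg)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_poisson_noise_variance(self):
        """With noise_scale s the variance at a flat clean level b is s*b."""
        s, b = 4.0, 50.0
        ph = pid.Phase("flat", np.array([]), np.array([]))
        cfg = pid.SimConfig(grid=pid.GridSpec(5, 60, 0.005), doublet=False,
                            bg_coeffs=(b,), noise_scale=s, seed=6)
        p = pid.render(ph, cfg)
        assert len(p) >= 10000
        assert np.var(p.intensity) == pytest.approx(s * b, rel=0.05)


class TestPerturbIntensities:
    def test_sigma_zero_identity(self, library6):
        out = pid.perturb_intensities(library6[0], 0.0, 1)
        np.testing.assert_array_equal(out.rel_intensities,
                                      library6[0].rel_intensities)

    def test_same_seed_reproducible(self, library6):
        a = pid.perturb_intensities(library6[0], 0.5, 7)
        b = pid.perturb_intensities(library6[0], 0.5, 7)
        np.testing.assert_array_equal(a.rel_intensities, b.rel_intensities)

    def test_positions_bitwise_unchanged(self, library6):
        out = pid.perturb_intensities(library6[0], 1.5, 3)
        np.testing.assert_array_equal(out.positions, library6[0].positions)
        assert out.rel_intensities.max() == pytest.approx(100.0)


class TestMixPatterns:
    def test_single_pattern_identity(self, small_pattern):
        out = pid.mix_patterns([small_pattern], [1.0])
        np.testing.assert_array_equal(out.intensity, small_pattern.intensity)

    def test_zero_mixture(self):
        t = 5.0 + 0.019 * np.arange(16)
        z = pid.Pattern(t, np.zeros(16))
        out = pid.mix_patterns([z, z], [0.4, 0.6])
        np.testing.assert_array_equal(out.intensity, 0.0)

    @pytest.mark.parametrize("weights", [[0.5, 0.6], [-0.1, 1.1], [1.0]])
    def test_bad_weights(self, small_pattern, weights):
        with pytest.raises(BadWeights):
            pid.mix_patterns([small_pattern, small_pattern], weights)

    def test_mixture_peaks_from_both_phases(self, clean_sim):
        lib = pid.fixture_library(4, seed=55)
        a, b = lib[2], lib[3]
        mix = pid.mix_patterns(
            [pid.render(a, clean_sim(seed=1)), pid.render(b, clean_sim(seed=2))],
            [0.3, 0.7],
        )
        proc = pid.preprocess_pattern(mix, background=False, kalpha2=False)
        pl = pid.detect_peaks(proc, 0.002, 0.001)
        for phase in (a, b):
            top = phase.positions[np.argmax(phase.rel_intensities)]
            assert np.min(np.abs(pl.positions - top)) <= 0.05


class TestFixtureLibrary:
    def test_same_seed_identical(self):
        a = pid.fixture_library(5, 9)
        b = pid.fixture_library(5, 9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.positions, y.positions)
            np.testing.assert_array_equal(x.rel_intensities, y.rel_intensities)

    def test_no_duplicate_phases(self, library6):
        for i in range(len(library6)):
            for j in range(i + 1, len(library6)):
                pi, pj = library6[i].positions, library6[j].positions
                shared = sum(np.min(np.abs(pj - x)) < 0.05 for x in pi)
                assert shared < len(pi)

    def test_similar_pair_shares_positions(self, library6):
        p0, p1 = library6[0].positions, library6[1].positions
        shared = sum(np.min(np.abs(p1 - x)) <= 0.05 for x in p0)
        assert shared >= 0.4 * len(p0)

    def test_reflection_counts_and_separation(self, library6):
        for ph in library6:
            assert 8 <= len(ph) <= 25
            assert np.min(np.diff(ph.positions)) >= 0.3 - 1e-12
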