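import numpy as np
import pytest

from patternspec.spectrum import (
    RadialSpectrum,
    amplitude_spectrum,
    bin_log_spectrum,
    cosine_taper,
    fit_spectral_slope,
    harmonize_species_range,
    measure_slope,
    rotational_average,
    select_frequency_range,
)
from patternspec.synthetic import PowerLawSpec, gen_powerlaw_image

from conftest import brute_force_rotational_average


class TestCosineTaper:
    def test_constant_image_unchanged(self):
        img = np.full((128, 128), 0.37)
        assert np.allclose(cosine_taper(img), img)

    def test_corners_equal_mean(self, rng):
        img = rng.random((100, 100))
        mean = img.mean()
        out = cosine_taper(img)
        for corner in [out[0, 0], out[0, -1], out[-1, 0], out[-1, -1]]:
            assert corner == pytest.approx(mean, abs=1e-9)

    def test_interior_unchanged(self, rng):
        img = rng.random((128, 128))
        out = cosine_taper(img, taper_frequency=4)
        # roll-off width is 128/8 = 16 px per edge
        assert np.allclose(out[20:-20, 20:-20], img[20:-20, 20:-20])

    def test_taper_changes_slope_little(self):
        # synthetic power-law images are periodic, so the taper may only
        # perturb the estimate slightly at beta = -1
        diffs = []
        for seed in range(20):
            img = gen_powerlaw_image(PowerLawSpec(beta=-1, size_px=512, seed=seed))
            with_t = measure_slope(img).slope
            without = measure_slope(img, taper_frequency=None).slope
            diffs.append(with_t - without)
        assert abs(np.mean(diffs)) < 0.05

    def test_rejects_bad_frequency(self):
        img = np.zeros((64, 64))
        with pytest.raises(ValueError):
            cosine_taper(img, taper_frequency=0)
        with pytest.raises(ValueError):
            cosine_taper(img, taper_frequency=32)  # roll-off < 2 px

    def test_rejects_rectangular(self):
        with pytest.raises(ValueError):
            cosine_taper(np.zeros((64, 65)))


class TestAmplitudeSpectrum:
    def test_constant_image_dc_only(self):
        img = np.full((64, 64), 3.0)
        amp = amplitude_spectrum(img)
        c = 64 // 2
        assert amp[c, c] == pytest.approx(3.0 * 64**2)
        off = amp.copy()
        off[c, c] = 0
        assert np.all(off <= 1e-9 * amp[c, c])

    def test_pure_sinusoid(self):
        n, k, a = 128, 8, 0.7
        x = np.arange(n)
        img = a * np.cos(2 * np.pi * k * x / n)[None, :] * np.ones((n, 1))
        amp = amplitude_spectrum(img)
        c = n // 2
        # two coefficients at radius k on the horizontal axis, each a*N^2/2
        assert amp[c, c + k] == pytest.approx(a * n**2 / 2, rel=1e-9)
        assert amp[c, c - k] == pytest.approx(a * n**2 / 2, rel=1e-9)
        amp[c, c + k] = amp[c, c - k] = 0
        assert amp.max() < 1e-6 * a * n**2

    def test_parseval(self, rng):
        img = rng.random((96, 96))
        amp = amplitude_spectrum(img)
        lhs = np.sum(amp**2)
        rhs = 96**2 * np.sum(img**2)
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestRotationalAverage:
    def test_constant_grid(self):
        grid = np.full((64, 64), 2.5)
        rs = rotational_average(grid)
        assert np.allclose(rs.amplitudes, 2.5)
        assert rs.freqs_cpi[0] == 1
        assert rs.freqs_cpi[-1] == 32

    def test_axis_coefficients_ring3(self):
        n = 32
        c = n // 2
        grid = np.zeros((n, n))
        v = 5.0
        for di, dj in [(3, 0), (-3, 0), (0, 3), (0, -3)]:
            grid[c + di, c + dj] = v
        # enumerate ring-3 membership independently
        count = 0
        for i in range(n):
            for j in range(n):
                d = np.hypot(i - c, j - c)
                if int(np.floor(d + 0.5)) == 3:
                    count += 1
        rs = rotational_average(grid)
        assert rs.amplitudes[2] == pytest.approx(v * 4 / count)
        assert rs.amplitudes[0] == 0 and rs.amplitudes[4] == 0

    @pytest.mark.parametrize("n", [8, 17, 32, 64])
    def test_matches_brute_force(self, n, rng):
        grid = rng.random((n, n))
        rs = rotational_average(grid)
        freqs, means = brute_force_rotational_average(grid)
        assert np.array_equal(rs.freqs_cpi, freqs)
        assert np.allclose(rs.amplitudes, means, atol=1e-12)

    def test_dc_excluded(self):
        grid = np.zeros((16, 16))
        grid[8, 8] = 100.0
        rs = rotational_average(grid)
        assert np.all(rs.amplitudes == 0)


class TestSelectFrequencyRange:
    def test_scene_crop(self):
        assert select_frequency_range(1036) == (5, 103)

    def test_mean_spider_crop(self):
        assert select_frequency_range(391) == (5, 39)

    def test_too_small(self):
        with pytest.raises(ValueError):
            select_frequency_range(50)

    def test_smallest_valid(self):
        assert select_frequency_range(60) == (5, 6)


class TestHarmonizeSpeciesRange:
    def test_intent_lower_bound(self):
        lo, hi, per = harmonize_species_range([(5, 20, 2.0), (5, 25, 2.5)])
        assert lo == pytest.approx(2.5)  # max(5/2.0, 5/2.5)
        assert per[0][0] == 5  # 2.5 c/mm * 2.0 mm = 5 cpi
        assert per[1][0] == 7  # ceil(2.5 * 2.5) = 7 cpi

    def test_literal_lower_bound_excludes_nothing(self):
        lo, _, per = harmonize_species_range(
            [(5, 20, 2.0), (5, 25, 2.5)], mode="literal"
        )
        assert lo == pytest.approx(2.0)
        assert per[0][0] == 5 and per[1][0] == 5

    def test_single_member_unchanged(self):
        lo, hi, per = harmonize_species_range([(5, 39, 2.0)])
        assert per == [(5, 39)]
        assert lo == pytest.approx(2.5)
        assert hi == pytest.approx(19.5)

    def test_cap_applies(self):
        # member with f_hi at 40 cycles/mm gets reduced to the 24.4 cap
        lo, hi, per = harmonize_species_range([(5, 40, 1.0)], cap_cpmm=24.4)
        assert hi == pytest.approx(24.4)
        assert per[0][1] == 24

    def test_empty_intersection(self):
        with pytest.raises(ValueError):
            harmonize_species_range([(5, 6, 1.0), (50, 60, 1.0)])


class TestBinAndFit:
    def test_identity_when_one_freq_per_bin(self):
        freqs = np.unique(np.round(np.logspace(np.log10(5), np.log10(103), 9))).astype(int)
        assert len(freqs) == 9
        amps = freqs.astype(float) ** -1.3
        rs = RadialSpectrum(freqs, amps)
        b = bin_log_spectrum(rs, 5, 103, 9)
        assert b.n_bins_used == 9
        assert np.allclose(np.sort(b.log10_freq), np.log10(freqs))
        assert np.allclose(np.sort(b.log10_amp)[::-1], np.log10(amps))

    def test_mean_then_log_convention(self):
        rs = RadialSpectrum(np.array([10, 11]), np.array([2.0, 4.0]))
        b = bin_log_spectrum(rs, 10, 11, 2)
        # both frequencies land in one bin -> y = log10(mean(2, 4)) = log10(3)
        assert len(b.log10_amp) in (1, 2)
        if len(b.log10_amp) == 1:
            assert b.log10_amp[0] == pytest.approx(np.log10(3.0))

    def test_pure_power_law_slope(self):
        # oracle-frozen: with the mean-amplitude-then-log convention the
        # binned fit of A = f^-1 over f = 5..103 gives -0.9999782 (a small
        # Jensen gap separates it from exactly -1)
        freqs = np.arange(5, 104)
        rs = RadialSpectrum(freqs, freqs.astype(float) ** -1.0)
        fit = fit_spectral_slope(bin_log_spectrum(rs, 5, 103, 9), 5, 103)
        assert fit.slope == pytest.approx(-1.0, abs=1e-4)
        assert fit.r2 > 0.999

    def test_exact_line(self):
        x = np.linspace(0.7, 2.0, 9)
        y = -1.2 * x + 3.0
        b = bin_log_spectrum(
            RadialSpectrum(np.round(10**x, 6), 10**y), 10**0.7, 10**2.0, 9
        )
        fit = fit_spectral_slope(b)
        assert fit.slope == pytest.approx(-1.2, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_too_few_bins(self):
        rs = RadialSpectrum(np.array([10, 11]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            bin_log_spectrum(rs, 10, 10.5, 9)


class TestSlopeInvariances:
    def test_log_base_invariance(self):
        freqs = np.arange(5, 104)
        amps = 2.7 * freqs.astype(float) ** -1.4
        rs = RadialSpectrum(freqs, amps)
        fit = fit_spectral_slope(bin_log_spectrum(rs, 5, 103, 9), 5, 103)
        # independent natural-log fit on the same binned points
        edges = np.logspace(np.log10(5), np.log10(103), 10)
        which = np.clip(np.searchsorted(edges, freqs.astype(float), "right") - 1, 0, 8)
        xs = [np.log(freqs[which == b].astype(float)).mean() for b in range(9)]
        ys = [np.log(amps[which == b].mean()) for b in range(9)]
        slope_ln = np.polyfit(xs, ys, 1)[0]
        assert fit.slope == pytest.approx(slope_ln, rel=1e-9)

    def test_amplitude_rescaling_shifts_intercept_only(self, rng):
        img = gen_powerlaw_image(PowerLawSpec(beta=-1, size_px=128, seed=11))
        f1 = measure_slope(img)
        f2 = measure_slope(img * 7.5)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-9)
        assert f2.intercept - f1.intercept == pytest.approx(np.log10(7.5), abs=1e-9)

    def test_r2_on_pure_power_law(self):
        for beta in (-2.0, -1.0, -0.5):
            freqs = np.arange(5, 104)
            rs = RadialSpectrum(freqs, freqs.astype(float) ** beta)
            fit = fit_spectral_slope(bin_log_spectrum(rs, 5, 103, 9), 5, 103)
            assert fit.r2 >= 0.999


class TestEndToEnd:
    @pytest.mark.parametrize("beta", [-1.0, -0.5, 0.0])
    def test_recovery_small(self, beta):
        # fast smoke version of the acceptance-scale recovery check
        est = [
            measure_slope(
                gen_powerlaw_image(PowerLawSpec(beta=beta, size_px=256, seed=s))
            ).slope
            for s in range(8)
        ]
        assert abs(np.mean(est) - beta) < 0.07

    def test_white_noise_flat(self):
        est = [
            measure_slope(
                gen_powerlaw_image(PowerLawSpec(beta=0.0, size_px=256, seed=s))
            ).slope
            for s in range(8)
        ]
        assert abs(np.mean(est)) < 0.05


def test_radial_spectrum_unit_consistency():
    rs = RadialSpectrum(np.arange(1, 10), np.ones(9), crop_mm=2.0)
    assert np.allclose(rs.freqs_cpmm * 2.0, rs.freqs_cpi, atol=1e-9)
    with pytest.raises(ValueError):
        RadialSpectrum(np.array([2, 1]), np.ones(2))
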