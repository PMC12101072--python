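import numpy as np
import pytest
from scipy import ndimage

from patternspec.cropping import largest_inscribed_square
from patternspec.spectrum import measure_slope, rotational_average
from patternspec.synthetic import (
    PowerLawSpec,
    SyntheticCohortSpec,
    ellipse_mask,
    gen_abdomen_mask,
    gen_cohort,
    gen_multispectral_stack,
    gen_powerlaw_image,
    make_filter_bank,
    make_receptor_curve,
)

from conftest import brute_force_inscribed_side


class TestPowerLawImage:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PowerLawSpec(beta=-1, size_px=32)
        with pytest.raises(ValueError):
            PowerLawSpec(beta=-1, mean_level=1.2)

    def test_flat_spectrum_for_beta_zero(self):
        img = gen_powerlaw_image(PowerLawSpec(beta=0.0, size_px=256, seed=1))
        rs = rotational_average(np.abs(np.fft.fftshift(np.fft.fft2(img))))
        band = rs.amplitudes[4:100]
        assert band.std() / band.mean() < 0.2
        assert abs(band[:20].mean() / band[-20:].mean() - 1) < 0.05

    def test_mean_is_exact(self):
        img = gen_powerlaw_image(PowerLawSpec(beta=-1, size_px=128, mean_level=0.61, seed=5))
        assert img.mean() == pytest.approx(0.61, abs=1e-6)

    def test_seed_determinism(self):
        spec = PowerLawSpec(beta=-1.2, size_px=128, seed=99)
        assert np.array_equal(gen_powerlaw_image(spec), gen_powerlaw_image(spec))

    def test_different_seeds_differ(self):
        a = gen_powerlaw_image(PowerLawSpec(beta=-1, size_px=128, seed=1))
        b = gen_powerlaw_image(PowerLawSpec(beta=-1, size_px=128, seed=2))
        assert not np.array_equal(a, b)

    def test_little_clipping_at_default_contrast(self):
        img = gen_powerlaw_image(PowerLawSpec(beta=-1.5, size_px=256, seed=3))
        clipped = np.mean((img <= 0) | (img >= 1))
        assert clipped < 0.01

    def test_excessive_contrast_rejected(self):
        with pytest.raises(ValueError, match="clip"):
            gen_powerlaw_image(
                PowerLawSpec(beta=-1, size_px=128, contrast=5.0, seed=0)
            )

    def test_pipeline_recovers_beta_minus_one(self):
        est = [
            measure_slope(
                gen_powerlaw_image(PowerLawSpec(beta=-1.0, size_px=512, seed=s))
            ).slope
            for s in range(20)
        ]
        assert abs(np.mean(est) + 1.0) <= 0.05


class TestAbdomenMask:
    @pytest.mark.parametrize("shape", ["ellipse", "fan"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_single_connected_component(self, shape, seed):
        mask = gen_abdomen_mask(128, shape=shape, seed=seed)
        _, n = ndimage.label(mask)  # 4-connectivity by default
        assert n == 1

    @pytest.mark.parametrize("shape", ["ellipse", "fan"])
    def test_area_fraction(self, shape):
        for seed in range(5):
            mask = gen_abdomen_mask(128, shape=shape, seed=seed)
            frac = mask.mean()
            assert 0.2 <= frac <= 0.8

    def test_seed_determinism(self):
        a = gen_abdomen_mask(96, "fan", seed=7)
        b = gen_abdomen_mask(96, "fan", seed=7)
        assert np.array_equal(a, b)

    def test_circle_inscribed_square(self):
        # semi-axes (a, a): largest inscribed square side is floor(a*sqrt(2)) +/- 1
        a = 50
        mask = ellipse_mask(128, semi_axes=(a, a))
        side = largest_inscribed_square(mask).side_px
        assert side == brute_force_inscribed_side(mask)
        assert abs(side - int(a * np.sqrt(2))) <= 1

    def test_size_validation(self):
        with pytest.raises(ValueError):
            gen_abdomen_mask(32)


class TestMultispectralStack:
    def setup_method(self):
        self.bank = make_filter_bank()
        self.receptor = make_receptor_curve()

    def test_dark_columns_match_offset(self):
        scene = np.zeros((64, 64))
        stack = gen_multispectral_stack(
            scene, self.bank, self.receptor, dark_offset=250.0,
            read_noise_sd=5.0, seed=1,
        )
        est = stack.dark_columns.mean()
        n = stack.dark_columns.size
        assert est == pytest.approx(250.0, abs=5 * 5 / np.sqrt(n) + 0.5)

    def test_no_saturation_when_fraction_zero(self):
        scene = np.full((32, 32), 0.5)
        stack = gen_multispectral_stack(
            scene, self.bank, self.receptor, saturate_fraction=0.0, seed=2
        )
        assert not stack.saturated.any()

    def test_saturation_count(self):
        scene = np.full((50, 50), 0.5)
        stack = gen_multispectral_stack(
            scene, self.bank, self.receptor, saturate_fraction=0.01, seed=3
        )
        forced = (stack.channels == stack.sensor_max).all(axis=0)
        assert forced.sum() == int(round(0.01 * 2500))

    def test_forward_model_proportional_to_scene(self):
        # noise-free channels minus dark are proportional to the scene with
        # factor gain * <reflectance, filter>
        rng = np.random.default_rng(0)
        scene = rng.random((16, 16))
        stack = gen_multispectral_stack(
            scene, self.bank, self.receptor, dark_offset=100.0,
            read_noise_sd=0.0, seed=0, gain=10.0,
        )
        wl = self.bank[0].wavelengths
        refl = self.receptor.interpolate(wl)
        for k, c in enumerate(self.bank):
            dot = np.trapezoid(refl * c.values, wl)
            assert np.allclose(
                stack.channels[k] - 100.0, 10.0 * dot * scene, atol=1e-6
            )

    def test_mismatched_grids_rejected(self):
        bad = make_filter_bank(wavelengths=np.arange(300.0, 701.0, 5.0))
        mixed = [self.bank[0]] + bad[1:]
        with pytest.raises(ValueError, match="common wavelength grid"):
            gen_multispectral_stack(np.zeros((8, 8)), mixed, self.receptor)

    def test_seed_determinism(self):
        scene = np.full((16, 16), 0.3)
        kw = dict(read_noise_sd=2.0, saturate_fraction=0.02, seed=11)
        s1 = gen_multispectral_stack(scene, self.bank, self.receptor, **kw)
        s2 = gen_multispectral_stack(scene, self.bank, self.receptor, **kw)
        assert np.array_equal(s1.channels, s2.channels)


class TestCohort:
    def test_zero_noise_is_deterministic_pattern(self):
        spec = SyntheticCohortSpec(
            sd_species=0, sd_species_sex=0, sd_resid=0,
            mu_female=-1.1, delta_sex=-0.3, seed=0,
        )
        df = gen_cohort(spec)
        females = df[(df.group == "spider") & (df.sex == "female")]["slope"]
        males = df[(df.group == "spider") & (df.sex == "male")]["slope"]
        assert np.allclose(females, -1.1)
        assert np.allclose(males, -1.4)

    def test_scene_mean_within_3_se(self):
        spec = SyntheticCohortSpec(n_scenes=41, mu_scene=-1.09, sd_scene=0.14, seed=12)
        df = gen_cohort(spec)
        scenes = df[df.group == "scene"]["slope"]
        se = 0.14 / np.sqrt(41)
        assert abs(scenes.mean() + 1.09) < 3 * se

    def test_structure(self):
        df = gen_cohort(SyntheticCohortSpec(n_species=4, n_per_sex=3, n_scenes=5, seed=1))
        spiders = df[df.group == "spider"]
        assert len(spiders) == 4 * 3 * 2
        assert len(df[df.group == "scene"]) == 5
        assert set(spiders.sex) == {"male", "female"}
        assert spiders.groupby("species").size().eq(6).all()

    def test_seed_determinism(self):
        spec = SyntheticCohortSpec(seed=3)
        assert gen_cohort(spec).equals(gen_cohort(spec))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n_species=0)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(sd_resid=-0.1)
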