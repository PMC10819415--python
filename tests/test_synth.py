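"""Phantom generation, forward rendering, and parameter-recovery loops."""

import math

import numpy as np
import pytest

import mpdeep as mp
from mpdeep.synth import DEFAULT_POWERS, MixedOrder


class TestFilamentScene:
    def test_fill_fraction_within_band(self):
        scene = mp.generate_filament_scene(seed=1)
        assert 0.08 <= scene.fill_fraction <= 0.12

    def test_deterministic_for_fixed_seed(self):
        a = mp.generate_filament_scene(seed=5)
        b = mp.generate_filament_scene(seed=5)
        assert np.array_equal(a.density, b.density)
        assert len(a.filaments) == len(b.filaments)

    def test_different_seed_differs(self):
        a = mp.generate_filament_scene(seed=5)
        b = mp.generate_filament_scene(seed=6)
        assert not np.array_equal(a.density, b.density)

    def test_doubling_target_roughly_doubles_occupancy(self):
        lo = mp.generate_filament_scene(fill_fraction_target=0.05, seed=2)
        hi = mp.generate_filament_scene(fill_fraction_target=0.10, seed=2)
        ratio = np.count_nonzero(hi.density) / np.count_nonzero(lo.density)
        assert 1.6 <= ratio <= 2.4

    def test_rejects_too_small_volume(self):
        with pytest.raises(ValueError):
            mp.generate_filament_scene(volume_um=(1.0, 10.0, 10.0), filament_radius_um=0.5)


class TestPowerSeries:
    def test_noiseless_pure_channels_exact(self):
        series = mp.generate_power_series(noise_cv=0.0, seed=0)
        assert mp.fit_power_exponent(series["blue"]).exponent == pytest.approx(3.09, abs=1e-9)
        assert mp.fit_power_exponent(series["red"]).exponent == pytest.approx(1.96, abs=1e-9)

    def test_green_mixture_calibrated_to_281(self):
        # weighted 2P+3P sum; least-squares slope over the default grid = 2.81
        series = mp.generate_power_series(noise_cv=0.0, seed=0)
        assert mp.fit_power_exponent(series["green"]).exponent == pytest.approx(2.81, abs=1e-4)

    def test_deterministic_and_channel_independent(self):
        full = mp.generate_power_series(noise_cv=0.05, seed=7)
        solo = mp.generate_power_series(
            responses={"blue": 3.09}, noise_cv=0.05, seed=7
        )
        assert np.array_equal(full["blue"].signals, solo["blue"].signals)
        again = mp.generate_power_series(noise_cv=0.05, seed=7)
        for ch in full:
            assert np.array_equal(full[ch].signals, again[ch].signals)

    def test_recovery_battery_across_seeds(self):
        """Exponent recovery coverage at default noise across 20 seeds."""
        truths = {"blue": 3.09, "green": 2.81, "red": 1.96}
        for seed in range(20):
            series = mp.generate_power_series(noise_cv=0.05, seed=seed)
            for ch, truth in truths.items():
                fit = mp.fit_power_exponent(series[ch])
                assert abs(fit.exponent - truth) <= max(3 * fit.stderr, 0.1)

    def test_mixed_order_signal_form(self):
        mix = MixedOrder(weights=((2, 0.5), (3, 0.5)))
        p = np.array([0.5, 1.0])
        assert np.allclose(mix.signal(p), 0.5 * p**2 + 0.5 * p**3)


class TestPowerSchedule:
    def test_noiseless_exact_recovery(self):
        schedule = mp.generate_power_schedule(le_um=170.0, noise_cv=0.0, seed=0)
        fit = mp.estimate_attenuation_length(schedule.depths_um, schedule.powers)
        assert fit.length_um == pytest.approx(170.0, rel=1e-9)

    def test_cap_flags_truncation(self):
        capped = mp.generate_power_schedule(le_um=100.0, noise_cv=0.0, seed=0, max_power=5.0)
        assert capped.truncated and capped.powers.max() == 5.0
        free = mp.generate_power_schedule(le_um=100.0, noise_cv=0.0, seed=0)
        assert not free.truncated

    def test_recovery_battery_across_seeds(self):
        for seed in range(20):
            schedule = mp.generate_power_schedule(le_um=170.0, noise_cv=0.05, seed=seed)
            fit = mp.estimate_attenuation_length(schedule.depths_um, schedule.powers)
            assert fit.length_um == pytest.approx(170.0, rel=0.10)


class TestBeadStacks:
    def test_noiseless_roundtrip_matches_convolved_psf(self, beam):
        stack = mp.generate_bead_stack(beam=beam, order=3, bead_diameter_um=0.5, noise=False)
        fit = mp.fit_psf_radii(stack)
        ref = mp.psf_with_bead(beam, 3, 0.5)
        assert fit.lateral_um == pytest.approx(ref.lateral_radius_um, rel=0.05)

    def test_point_source_limit_recovers_bare_psf(self, beam):
        stack = mp.generate_bead_stack(beam=beam, order=3, bead_diameter_um=0.0, noise=False)
        fit = mp.fit_psf_radii(stack)
        assert fit.lateral_um == pytest.approx(mp.psf_lateral_radius(beam, 3), rel=0.05)

    def test_two_photon_wider_than_three_photon(self, beam):
        fit3 = mp.fit_psf_radii(mp.generate_bead_stack(beam=beam, order=3, noise=False))
        fit2 = mp.fit_psf_radii(mp.generate_bead_stack(beam=beam, order=2, noise=False))
        assert fit2.lateral_um > fit3.lateral_um

    def test_axial_wider_than_lateral(self, beam):
        fit = mp.fit_psf_radii(mp.generate_bead_stack(beam=beam, order=3, noise=False))
        assert fit.axial_um > fit.lateral_um

    def test_noisy_roundtrip_battery(self, beam):
        ref = mp.psf_with_bead(beam, 3, 0.5)
        for seed in range(5):
            stack = mp.generate_bead_stack(beam=beam, order=3, bead_diameter_um=0.5, seed=seed)
            fit = mp.fit_psf_radii(stack)
            assert fit.lateral_um == pytest.approx(ref.lateral_radius_um, rel=0.05)

    def test_rejects_negative_diameter(self):
        with pytest.raises(ValueError):
            mp.generate_bead_stack(bead_diameter_um=-0.2)


class TestRenderStack:
    def test_zero_amplitude_scene_recovers_offset(self):
        scene = mp.generate_filament_scene(volume_um=(12.8, 12.8, 40.0), seed=3)
        scene.density[:] = 0.0
        cfg = mp.RenderConfig(z_step_um=8.0, detector_offset=120, seed=4)
        stacks = mp.render_stack(scene, cfg, channels=("blue",))
        for plane in stacks["blue"].voxels:
            assert mp.background_level(plane) == 120

    def test_deterministic_render(self):
        scene = mp.generate_filament_scene(volume_um=(12.8, 12.8, 40.0), seed=3)
        cfg = mp.RenderConfig(z_step_um=8.0, seed=4)
        a = mp.render_stack(scene, cfg)
        b = mp.render_stack(scene, cfg)
        for ch in a:
            assert np.array_equal(a[ch].voxels, b[ch].voxels)

    def test_lossless_render_signal_depth_independent(self):
        scene = mp.generate_filament_scene(volume_um=(19.2, 19.2, 80.0), seed=6)
        lossless = mp.MediumProperties(math.inf, math.inf, 0.10)
        cfg = mp.RenderConfig(medium=lossless, z_step_um=8.0, photon_scale=500.0, seed=7)
        stacks = mp.render_stack(scene, cfg, channels=("blue",))
        profile = mp.sbr_profile(stacks["blue"])
        sig = profile.signal[1:-1]  # end slices lose axial neighbours
        assert sig.max() / sig.min() < 1.6

    def test_rejects_wrong_schedule_length(self):
        scene = mp.generate_filament_scene(volume_um=(12.8, 12.8, 40.0), seed=3)
        cfg = mp.RenderConfig(z_step_um=8.0, surface_powers=np.ones(3), seed=0)
        with pytest.raises(ValueError):
            mp.render_stack(scene, cfg)


@pytest.fixture(scope="module")
def deep_stacks(beam):
    scene = mp.generate_filament_scene(volume_um=(38.4, 38.4, 800.0), seed=11)
    medium = mp.MediumProperties(scattering_length_um=120.0)
    depths = np.arange(40) * 20.0
    cfg = mp.RenderConfig(
        beam=beam,
        medium=medium,
        z_step_um=20.0,
        photon_scale=3000.0,
        surface_powers=np.exp(depths / 120.0),
        seed=5,
    )
    stacks = mp.render_stack(scene, cfg, channels=("blue", "red"))
    return stacks, medium, depths


class TestClosedLoop:
    """Render a deep stack and re-derive the model's SBR-vs-depth from it."""

    def model_curve(self, beam, medium, depths, m):
        return np.array(
            [mp.sbr(d, beam, medium, m).ratio if d > 0 else math.inf for d in depths]
        )

    @pytest.mark.parametrize("channel, order", [("blue", 3), ("red", 2)])
    def test_measured_sbr_within_factor_two_of_model(self, beam, deep_stacks, channel, order):
        stacks, medium, depths = deep_stacks
        profile = mp.sbr_profile(stacks[channel])
        model = self.model_curve(beam, medium, depths, order)
        # compare where the background is resolved (>= 5 counts) and the
        # model SBR >= 1 (below that the threshold measures texture, not signal)
        sel = (profile.background >= 5) & (model >= 1.0) & np.isfinite(model)
        assert sel.sum() >= 3
        ratio = profile.ratio[sel] / model[sel]
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_blue_background_stays_flat_while_red_overtakes(self, deep_stacks):
        stacks, _, _ = deep_stacks
        blue = mp.sbr_profile(stacks["blue"])
        red = mp.sbr_profile(stacks["red"])
        # 3P background stays within a few counts of the zero value
        assert blue.background.max() <= 25
        assert np.all(blue.signal > 10 * blue.background)
        # 2P background grows by orders of magnitude and overtakes the signal
        assert red.background[-1] > 100 * red.background[0]
        assert red.background[-1] > red.signal[-1]

    def test_sbr_curve_shape_battery(self, beam):
        """Measured and model SBR decay together across seeds (rank correlation)."""
        from scipy.stats import spearmanr

        medium = mp.MediumProperties(scattering_length_um=60.0)
        depths = np.arange(20) * 20.0
        for seed in range(5):
            scene = mp.generate_filament_scene(volume_um=(19.2, 19.2, 400.0), seed=seed)
            cfg = mp.RenderConfig(
                beam=beam,
                medium=medium,
                z_step_um=20.0,
                photon_scale=3000.0,
                surface_powers=np.exp(depths / 60.0),
                seed=seed,
            )
            stacks = mp.render_stack(scene, cfg, channels=("red",))
            profile = mp.sbr_profile(stacks["red"])
            model = self.model_curve(beam, medium, depths, 2)
            sel = np.isfinite(model) & (model >= 0.5)
            rho = spearmanr(profile.ratio[sel], model[sel]).statistic
            assert rho > 0.8
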