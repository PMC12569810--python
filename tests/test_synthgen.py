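"""Synthetic-data generators: ground-truth fidelity and determinism."""

import numpy as np
import pytest

from cochleametrics import fcs
from cochleametrics.synthgen import (
    BrightnessTableConfig,
    FcsSimConfig,
    MotionPhantomConfig,
    SectionPhantomConfig,
    TrajectorySpec,
    render_motion_sequence,
    render_section_phantom,
    simulate_fbm_paths,
    simulate_photon_trace,
    synth_brightness_table,
    synth_evoked_waveform,
)


def _msd_slope(paths, bin_width, lags=(1, 2, 4, 8, 16, 32)):
    x = paths[:, :, 0]
    msd = [((x[:, l:] - x[:, :-l]) ** 2).mean() for l in lags]
    return np.polyfit(np.log(np.array(lags) * bin_width), np.log(msd), 1)[0]


class TestFbmPaths:
    # huge box disables wrapping so the MSD is clean
    def _cfg(self, alpha, n=10_000, **kw):
        return FcsSimConfig(n_molecules=n, alpha=alpha, duration=64e-4, bin_width=1e-4,
                            box_size=1e9, seed=11, **kw)

    @pytest.mark.parametrize("alpha", [0.5, 0.75, 1.0])
    def test_msd_exponent_matches_alpha(self, alpha):
        paths = simulate_fbm_paths(self._cfg(alpha))
        assert _msd_slope(paths, 1e-4) == pytest.approx(alpha, abs=0.05)

    def test_brownian_msd_closed_form(self):
        cfg = self._cfg(1.0)
        paths = simulate_fbm_paths(cfg)
        # 1-D marginal MSD(t) = 2 D t
        d1 = ((paths[:, 1:, 0] - paths[:, :-1, 0]) ** 2).mean()
        assert d1 == pytest.approx(2 * cfg.diffusion_coefficient * cfg.bin_width, rel=0.05)

    def test_zero_diffusion_paths_constant(self):
        cfg = FcsSimConfig(n_molecules=50, diffusion_coefficient=0.0, duration=1e-2,
                           bin_width=1e-4, seed=3)
        paths = simulate_fbm_paths(cfg)
        assert np.all(paths == paths[:, :1, :])

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            FcsSimConfig(alpha=1.5)
        with pytest.raises(ValueError, match="alpha"):
            FcsSimConfig(alpha=0.0)

    def test_step_overflow_rejected(self):
        cfg = FcsSimConfig(duration=1e9, bin_width=1e-4, seed=0)
        with pytest.raises(ValueError, match="limit"):
            simulate_fbm_paths(cfg)

    def test_small_box_rejected(self):
        with pytest.raises(ValueError, match="box_size"):
            FcsSimConfig(box_size=1.0, beam_waist_xy=0.3)


class TestPhotonTrace:
    def test_pure_background_is_flat_100khz(self):
        # background-only trace at the ~100 kHz count-rate scale
        cfg = FcsSimConfig(n_molecules=1, brightness_true=0.0, background_rate=1e5,
                           duration=2.0, bin_width=1e-4, seed=5)
        trace = simulate_photon_trace(cfg)
        assert trace.mean_count_rate == pytest.approx(1e5, rel=0.01)
        curve = fcs.autocorrelate(trace, "multi_tau")
        assert np.abs(curve.G).max() < 5e-3  # flat: no concentration fluctuations

    def test_immobile_center_molecule_poisson(self):
        cfg = FcsSimConfig(n_molecules=1, diffusion_coefficient=0.0, brightness_true=2e4,
                           background_rate=0.0, duration=4.0, bin_width=1e-3, seed=6)
        trace = simulate_photon_trace(cfg)
        # molecule sits at a random spot; counts are Poisson => var ~= mean
        m, v = trace.counts.mean(), trace.counts.var()
        if m > 0.5:  # skip unlucky placement far outside the beam
            assert v / m == pytest.approx(1.0, abs=0.15)

    def test_mean_rate_matches_analytic_expectation(self):
        # dense, fast tracers average the detection volume well within 10 s
        cfg = FcsSimConfig(n_molecules=3600, diffusion_coefficient=5.0, duration=10.0,
                           bin_width=1e-3, brightness_true=500.0, seed=8)
        trace = simulate_photon_trace(cfg)
        assert trace.mean_count_rate == pytest.approx(
            trace.ground_truth["mean_rate_expected"], rel=0.02)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            simulate_photon_trace(FcsSimConfig(duration=1e-5, bin_width=1e-4, seed=0))

    def test_seed_determinism(self):
        cfg = FcsSimConfig(duration=0.1, bin_width=1e-4, seed=9)
        a = simulate_photon_trace(cfg)
        b = simulate_photon_trace(cfg)
        assert np.array_equal(a.counts, b.counts)


class TestSectionPhantom:
    def test_rasterized_gap_matches_configured(self):
        cfg = SectionPhantomConfig(gap_true=6.0, seed=2)
        _, geom, truth = render_section_phantom(cfg)
        tm_pix = np.argwhere(truth["tm_mask"]).astype(float)
        ooc_pix = np.argwhere(truth["ooc_mask"]).astype(float)
        # brute-force pixel-pair minimum distance on the masks
        from scipy.spatial import cKDTree

        d = cKDTree(tm_pix).query(ooc_pix)[0].min() * cfg.pixel_size
        assert abs(d - cfg.gap_true) <= np.sqrt(2) * cfg.pixel_size

    def test_zero_gap_touches(self):
        _, geom, _ = render_section_phantom(SectionPhantomConfig(gap_true=0.0, seed=2))
        from cochleametrics.morphometry import min_gap

        assert min_gap(geom.tm_roi, geom.reticular_lamina, geom.pixel_size) == 0.0

    def test_determinism(self):
        cfg = SectionPhantomConfig(seed=4)
        img1, _, _ = render_section_phantom(cfg)
        img2, _, _ = render_section_phantom(cfg)
        assert np.array_equal(img1, img2)

    def test_oversized_structure_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            render_section_phantom(SectionPhantomConfig(image_shape=(64, 64), seed=0))


class TestMotionPhantom:
    def test_trajectories_periodic_and_zero_mean(self):
        _, truth = render_motion_sequence(MotionPhantomConfig(seed=1))
        for key in ("base_displacement_nm", "tip_displacement_nm"):
            assert np.allclose(truth[key].mean(axis=0), 0.0, atol=1e-9)

    def test_phase_bins_cover_cycle(self):
        stream, _ = render_motion_sequence(MotionPhantomConfig(seed=1))
        assert stream.phase.min() >= 0 and stream.phase.max() < 2 * np.pi

    def test_fig3h_programmed_deflection(self):
        # base 65 nm inclined, tip vertical: programmed difference ~33 nm
        _, truth = render_motion_sequence(MotionPhantomConfig(seed=1))
        full_amp = np.linalg.norm(
            truth["tip_displacement_nm"] - truth["base_displacement_nm"], axis=1).max()
        assert truth["deflection_amplitude_nm"] == pytest.approx(full_amp)
        assert 28 < truth["deflection_amplitude_nm"] < 36

    def test_amplitude_exceeding_frame_rejected(self):
        cfg = MotionPhantomConfig(
            base_trajectory=TrajectorySpec(amplitude=5000.0, direction=0.0), seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            render_motion_sequence(cfg)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="phase bins"):
            MotionPhantomConfig(n_phase_bins=4)


class TestEvokedWaveform:
    def test_noiseless_components_exact(self):
        t, w, _ = synth_evoked_waveform(200, 50.0, 10.0, 0.0, 0.5, 10_000, seed=0)
        from cochleametrics.evoked import cm_component

        amp, _ = cm_component(w, 10_000, 200)
        assert amp == pytest.approx(50.0)
        assert w.mean() == pytest.approx(10.0, abs=1e-9)

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            synth_evoked_waveform(200, 1.0, 0.0, 0.0, 1.0, 300, seed=0)

    def test_waveform_and_motion_determinism(self):
        _, w1, _ = synth_evoked_waveform(200, 5.0, 1.0, 2.0, 0.1, 10_000, seed=4)
        _, w2, _ = synth_evoked_waveform(200, 5.0, 1.0, 2.0, 0.1, 10_000, seed=4)
        assert np.array_equal(w1, w2)
        from cochleametrics.synthgen import MotionPhantomConfig, render_motion_sequence

        cfg = MotionPhantomConfig(seed=4, frame_shape=(48, 48), noise_sd=5.0,
                                  base_anchor=(24.0, 31.0), tip_anchor=(24.0, 17.0))
        s1, _ = render_motion_sequence(cfg)
        s2, _ = render_motion_sequence(cfg)
        assert np.array_equal(s1.intensity, s2.intensity)


class TestBrightnessTable:
    def test_within_animal_correlation_approaches_rho(self):
        cfg = BrightnessTableConfig(n_animals_per_group=200, dose_levels=(0.0,),
                                    intra_animal_correlation=0.5, seed=10)
        tab = synth_brightness_table(cfg)
        wide = tab.pivot(index="animal", columns="site", values="brightness")
        corr = wide.corr().to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.mean(off) == pytest.approx(0.5, abs=0.05)

    def test_marginal_means(self):
        cfg = BrightnessTableConfig(
            n_animals_per_group=400, dose_levels=(0.0, 2.0), intercept=800.0,
            dose_slope=-61.0, site_offsets={"TM1": 30.0}, residual_sd=20.0, seed=11)
        tab = synth_brightness_table(cfg)
        m0 = tab[(tab.dose == 0) & (tab.site == "EndoL")]["brightness"].mean()
        m2 = tab[(tab.dose == 2) & (tab.site == "EndoL")]["brightness"].mean()
        mt = tab[(tab.dose == 0) & (tab.site == "TM1")]["brightness"].mean()
        assert m0 == pytest.approx(800.0, abs=3)
        assert m2 == pytest.approx(800.0 - 122.0, abs=3)
        assert mt - m0 == pytest.approx(30.0, abs=3)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            BrightnessTableConfig(intra_animal_correlation=-0.2)

    def test_determinism(self):
        cfg = BrightnessTableConfig(seed=12)
        assert synth_brightness_table(cfg).equals(synth_brightness_table(cfg))
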