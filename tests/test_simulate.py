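"""Unit and property tests for the synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy import ndimage, stats

from ddrquant.massphot import MixtureModel, SkewComponent
from ddrquant.motility import MicrotubulePath
from ddrquant.simulate import (BindingParams, LabelingModel, MotilityParams,
                               SimulationConfig, draw_dye_count, render_frame,
                               random_microtubule_paths, sample_masses,
                               simulate_binding_movie, simulate_binding_truth,
                               simulate_motility_movie, simulate_motility_truth,
                               truth_to_tracks)


class TestSimulationConfig:
    def test_defaults_match_assay_geometry(self):
        cfg = SimulationConfig()
        assert cfg.pixel_size_nm == 160.0
        assert cfg.shape_px == (250, 250)          # 40 um / 160 nm
        assert cfg.duration_s == pytest.approx(300.0)

    @pytest.mark.parametrize("kwargs", [
        {"pixel_size_nm": -1}, {"frame_interval_s": 0}, {"n_frames": 0},
        {"psf_sigma_nm": 0}, {"em_gain": 0}, {"bleach_tau_s": -2},
        {"field_size_um": (40.013, 40.0)},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestLabeling:
    def test_snap_dimer_fraction_with_at_least_one_dye(self, rng):
        # p = 0.65 per monomer -> 0.88 of dimers carry signal
        label = LabelingModel(p=0.65, n=2)
        draws = draw_dye_count(label, rng, size=100_000)
        assert np.mean(draws >= 1) == pytest.approx(0.88, abs=0.005)
        assert label.prob_at_least_one_dye == pytest.approx(0.8775)

    def test_p_zero_always_dark(self, rng):
        assert np.all(draw_dye_count(LabelingModel(p=0.0, n=5), rng, size=1000) == 0)

    def test_p_one_always_full(self, rng):
        assert np.all(draw_dye_count(LabelingModel(p=1.0, n=2), rng, size=1000) == 2)

    @pytest.mark.parametrize("p,n", [(-0.1, 2), (1.1, 2), (0.5, 0)])
    def test_invalid_model(self, p, n):
        with pytest.raises(ValueError):
            LabelingModel(p=p, n=n)


class TestRenderFrame:
    def test_noiseless_integral_equals_photons(self, small_cfg):
        img = render_frame([(4000.0, 4000.0, 1234.0)], small_cfg, noise=False)
        above_bg = img.sum() - small_cfg.background_photons * img.size
        # integrated Gaussian sums to the photon budget (= peak * 2 pi sigma_px^2)
        assert above_bg == pytest.approx(1234.0, rel=1e-6)

    def test_peak_pixel_matches_erf_integral(self, small_cfg):
        # emitter centered on a pixel: the brightest pixel holds
        # photons * erf(px / (2 sqrt(2) sigma))^2 (separable erf integral)
        photons = 5000.0
        img = render_frame([(4080.0, 4080.0, photons)], small_cfg, noise=False)
        half = small_cfg.pixel_size_nm / 2
        expected = photons * math.erf(half / (math.sqrt(2) * small_cfg.psf_sigma_nm)) ** 2
        assert img.max() - small_cfg.background_photons == pytest.approx(expected,
                                                                         rel=1e-9)

    def test_dark_complex_contributes_nothing(self, small_cfg):
        blank = render_frame([], small_cfg, noise=False)
        with_dark = render_frame([(4000.0, 4000.0, 0.0)], small_cfg, noise=False)
        np.testing.assert_array_equal(blank, with_dark)

    def test_em_gain_linearity(self, small_cfg):
        # doubling em_gain doubles the expected mean above background
        means = []
        for gain in (2.0, 4.0):
            cfg = SimulationConfig(field_size_um=(8, 8), n_frames=20,
                                   em_gain=gain, read_noise_sd=0.0,
                                   background_photons=0.0)
            rng = np.random.default_rng(3)
            acc = [render_frame([(4000.0, 4000.0, 500.0)], cfg, rng=rng).sum()
                   for _ in range(300)]
            means.append(np.mean(acc))
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.02)

    def test_out_of_field_emitter_contributes_tail(self, small_cfg):
        img = render_frame([(-100.0, 4000.0, 1000.0)], small_cfg, noise=False)
        above = img.sum() - small_cfg.background_photons * img.size
        assert 0 < above < 1000.0

    def test_noise_values_finite_nonnegative(self, small_cfg, rng):
        img = render_frame([(4000.0, 4000.0, 1000.0)], small_cfg, rng=rng)
        assert np.all(np.isfinite(img)) and np.all(img >= 0)

    def test_translation_equivariance_subpixel(self, small_cfg):
        """Shift theorem: moving the emitter equals shifting the image."""
        base = render_frame([(4000.0, 4000.0, 1000.0)], small_cfg, noise=False)
        dx_px = 0.37
        moved = render_frame([(4000.0 + dx_px * 160.0, 4000.0, 1000.0)],
                             small_cfg, noise=False)
        shifted = np.fft.ifftn(ndimage.fourier_shift(
            np.fft.fftn(base), (0, dx_px))).real
        resid = np.linalg.norm(moved - shifted) / np.linalg.norm(moved)
        assert resid < 0.01


class TestMotilityTruth:
    def test_zero_rate_background_only(self, small_cfg, diagonal_path):
        params = MotilityParams(landing_rate_per_um_s=0.0)
        movie, truth = simulate_motility_movie(small_cfg, params, [diagonal_path],
                                               noise=False)
        assert truth.runs == []
        assert movie.frames.std() == pytest.approx(0.0)

    def test_poisson_mean_run_count(self, full_cfg):
        # f * L * T = 2e-3 * 25 um * 300 s = 15 expected runs
        path = MicrotubulePath(np.array([[1000.0, 1000.0], [26000.0, 1000.0]]), id=0)
        params = MotilityParams(landing_rate_per_um_s=2e-3)
        counts = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            truth = simulate_motility_truth(full_cfg, params, [path], rng)
            counts.append(len(truth.runs))
        counts = np.array(counts)
        expected = 2e-3 * 25.0 * 300.0
        assert counts.mean() == pytest.approx(expected, abs=3 * math.sqrt(expected / 200))
        # Poisson dispersion: variance/mean near 1
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.35)

    def test_poisson_count_distribution_chi2(self, full_cfg):
        """Truth counts over 500 seeds pass a chi-square GoF vs Poisson."""
        path = MicrotubulePath(np.array([[2000.0, 2000.0], [17000.0, 2000.0]]), id=0)
        params = MotilityParams(landing_rate_per_um_s=1e-3)
        mean = 1e-3 * 15.0 * 300.0  # 4.5
        counts = np.array([len(simulate_motility_truth(
            full_cfg, params, [path], np.random.default_rng(10_000 + s)).runs)
            for s in range(500)])
        kmax = int(stats.poisson.ppf(0.999, mean))
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax + 1), mean)
        probs[-1] = 1.0 - probs[:-1].sum()
        # pool bins with small expectation
        keep = probs * 500 >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(probs[keep], probs[~keep].sum()) * 500
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.01

    def test_degenerate_velocity(self, full_cfg):
        params = MotilityParams(landing_rate_per_um_s=5e-3, velocity_sd_nm_s=0.0,
                                velocity_mean_nm_s=450.0)
        path = MicrotubulePath(np.array([[1000.0, 1000.0], [26000.0, 1000.0]]), id=0)
        truth = simulate_motility_truth(full_cfg, params, [path],
                                        np.random.default_rng(0))
        assert len(truth.runs) > 0
        assert all(r.velocity_nm_s == 450.0 for r in truth.runs)

    def test_runs_stay_on_polyline(self, full_cfg):
        path = MicrotubulePath(np.array([[1000.0, 1000.0], [26000.0, 1000.0]]), id=0)
        params = MotilityParams(landing_rate_per_um_s=5e-3)
        truth = simulate_motility_truth(full_cfg, params, [path],
                                        np.random.default_rng(5))
        for r in truth.runs:
            for s in (r.s_on_nm, r.s_off_nm):
                assert -1e-9 <= s <= path.length_nm + 1e-9
            assert 0.0 <= r.t_on_s <= r.t_off_s <= full_cfg.duration_s + 1e-9

    def test_path_outside_field_rejected(self, small_cfg):
        bad = MicrotubulePath(np.array([[1000.0, 1000.0], [9000.0, 1000.0]]), id=0)
        with pytest.raises(ValueError, match="outside"):
            simulate_motility_truth(small_cfg, MotilityParams(1e-3), [bad])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            MotilityParams(landing_rate_per_um_s=-1e-3)

    def test_seed_reproducibility_byte_identical(self, small_cfg, diagonal_path):
        params = MotilityParams(landing_rate_per_um_s=2e-2)
        m1, t1 = simulate_motility_movie(small_cfg, params, [diagonal_path],
                                         np.random.default_rng(9))
        m2, t2 = simulate_motility_movie(small_cfg, params, [diagonal_path],
                                         np.random.default_rng(9))
        assert m1.frames.tobytes() == m2.frames.tobytes()
        assert t1.runs == t2.runs


class TestBindingTruth:
    def test_dwell_sample_mean_lln(self, full_cfg):
        """1e4 exponential draws at mean 21 s land within 3 s.e. of 21."""
        rng = np.random.default_rng(11)
        draws = rng.exponential(21.0, 10_000)  # oracle for the generator below
        se = 21.0 / math.sqrt(10_000)
        assert abs(draws.mean() - 21.0) < 3 * se

        cfg = SimulationConfig(n_frames=40_000, frame_interval_s=0.5)
        params = BindingParams(n_baits=30, dwell_mean_s=21.0, arrival_rate_per_s=0.05)
        truth = simulate_binding_truth(cfg, params, np.random.default_rng(12))
        durations = np.array([e.duration_s for e in truth.events if not e.censored])
        assert len(durations) > 5_000
        assert abs(durations.mean() - 21.0) < 3 * 21.0 / math.sqrt(len(durations))

    def test_dwell_distribution_ks(self):
        cfg = SimulationConfig(n_frames=60_000, frame_interval_s=0.5)
        params = BindingParams(n_baits=20, dwell_mean_s=10.0, arrival_rate_per_s=0.05)
        truth = simulate_binding_truth(cfg, params, np.random.default_rng(13))
        d = np.array([e.duration_s for e in truth.events if not e.censored])[:10_000]
        assert len(d) == 10_000
        assert stats.kstest(d, "expon", args=(0, 10.0)).pvalue > 0.01

    def test_everlasting_dwell_all_censored(self, full_cfg):
        params = BindingParams(n_baits=25, dwell_mean_s=1e9, arrival_rate_per_s=0.05)
        truth = simulate_binding_truth(full_cfg, params, np.random.default_rng(2))
        assert len(truth.events) > 0
        assert all(e.censored for e in truth.events)
        assert all(e.t_off_s == full_cfg.duration_s for e in truth.events)

    def test_zero_baits(self, small_cfg):
        params = BindingParams(n_baits=0, dwell_mean_s=5.0)
        movies, truth = simulate_binding_movie(small_cfg, params,
                                               np.random.default_rng(1), noise=False)
        assert truth.events == []
        prey = movies["prey"].frames
        assert prey.max() == pytest.approx(small_cfg.background_photons)

    def test_events_non_overlapping_per_bait(self, full_cfg):
        params = BindingParams(n_baits=10, dwell_mean_s=30.0, arrival_rate_per_s=0.1)
        truth = simulate_binding_truth(full_cfg, params, np.random.default_rng(3))
        for b in range(10):
            ev = sorted(truth.events_on(b), key=lambda e: e.t_on_s)
            for a, c in zip(ev, ev[1:]):
                assert c.t_on_s >= a.t_off_s

    def test_negative_dwell_rejected(self):
        with pytest.raises(ValueError):
            BindingParams(n_baits=5, dwell_mean_s=-1.0)

    def test_dense_baits_warn(self, small_cfg):
        with pytest.warns(UserWarning, match="density"):
            simulate_binding_truth(small_cfg,
                                   BindingParams(n_baits=3000, dwell_mean_s=5.0),
                                   np.random.default_rng(0))

    def test_bait_channel_static_prey_dynamic(self, small_cfg):
        params = BindingParams(n_baits=3, dwell_mean_s=3.0, arrival_rate_per_s=0.2)
        movies, truth = simulate_binding_movie(small_cfg, params,
                                               np.random.default_rng(8), noise=False)
        bait = movies["bait"].frames
        assert np.ptp(bait, axis=0).max() == pytest.approx(0.0)  # static
        if truth.events:
            assert np.ptp(movies["prey"].frames, axis=0).max() > 0


class TestSampleMasses:
    def test_single_symmetric_component_moments(self, rng):
        model = MixtureModel([SkewComponent(200.0, 20.0, 0.0, 1.0)])
        x = sample_masses(model, 20_000, rng)
        assert x.mean() == pytest.approx(200.0, abs=3 * 20.0 / math.sqrt(20_000))
        assert x.std() == pytest.approx(20.0, rel=0.03)
        assert abs(stats.skew(x)) < 0.06

    def test_zero_weight_component_never_sampled(self, rng):
        model = MixtureModel([SkewComponent(100.0, 5.0, 0.0, 1.0),
                              SkewComponent(900.0, 5.0, 0.0, 0.0)])
        x = sample_masses(model, 5000, rng)
        assert x.max() < 200.0

    def test_skewed_component_mean_matches_formula(self, rng):
        comp = SkewComponent(100.0, 30.0, 4.0, 1.0)
        model = MixtureModel([comp])
        x = sample_masses(model, 50_000, rng)
        assert x.mean() == pytest.approx(comp.mean, abs=0.5)

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError):
            MixtureModel([])


class TestTruthToTracks:
    def test_tracks_follow_truth(self, full_cfg):
        path = MicrotubulePath(np.array([[1000.0, 1000.0], [26000.0, 1000.0]]), id=0)
        params = MotilityParams(landing_rate_per_um_s=2e-3, velocity_sd_nm_s=0.0)
        truth = simulate_motility_truth(full_cfg, params, [path],
                                        np.random.default_rng(21))
        tracks = truth_to_tracks(truth, full_cfg, localization_noise_nm=0.0,
                                 rng=np.random.default_rng(22))
        labeled = [r for r in truth.runs if r.dye_count > 0]
        assert len(tracks) == len(labeled)
        for tr, r in zip(tracks, labeled):
            xy = tr.xy_nm
            t = tr.times()
            expect = r.arc_position_at(t) + 1000.0  # path starts at x = 1000 nm
            np.testing.assert_allclose(xy[:, 0], expect, atol=1e-6)


class TestRandomPaths:
    def test_paths_fit_field_and_length_range(self, full_cfg, rng):
        paths = random_microtubule_paths(full_cfg, 20, 12.0, 25.0, rng)
        assert len(paths) == 20
        for p in paths:
            assert 12.0 <= p.length_um <= 25.0
            assert p.vertices.min() >= 0
            assert p.vertices.max() <= 40_000.0
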