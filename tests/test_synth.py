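"""Generator correctness: geometry, event statistics, rendering, noise."""

from dataclasses import replace

import numpy as np
import pytest

from patchdyn.core import Movie
from patchdyn.metrics import relative_amplitude
from patchdyn.synth import (
    GroundTruthEvent,
    SyntheticSpec,
    amplitude_for_relative,
    apply_noise_and_bleach,
    make_geometry,
    nested_event_streams,
    pixel_mode_movie,
    render_movie,
    sample_events,
    simulate_movie,
)
from patchdyn.tracking import detect_movie, link_tracks
from patchdyn.core import DetectionParams, TrackingParams


class TestGeometry:
    def test_single_disc_area_matches_analytic(self):
        spec = SyntheticSpec(n_boutons=1, bouton_radius_um=2.0, pixel_size_um=0.1)
        mask = make_geometry(spec)
        assert mask.area_um2 == pytest.approx(np.pi * 4.0, rel=0.02)

    def test_zero_boutons_rejected(self):
        with pytest.raises(ValueError):
            make_geometry(SyntheticSpec(n_boutons=0))

    def test_disjoint_discs_additive(self):
        spec = SyntheticSpec(
            n_boutons=2, bouton_radius_um=1.0, bouton_spacing_um=5.0, pixel_size_um=0.05
        )
        single = SyntheticSpec(n_boutons=1, bouton_radius_um=1.0, pixel_size_um=0.05)
        assert make_geometry(spec).area_um2 == pytest.approx(
            2 * make_geometry(single).area_um2, rel=0.01
        )


class TestSampleEvents:
    def test_zero_frequency_always_empty(self):
        spec = SyntheticSpec(event_frequency=0.0)
        mask = make_geometry(spec)
        for seed in range(5):
            assert sample_events(replace(spec, rng_seed=seed), mask) == []

    def test_event_count_unbiased(self):
        # lambda = f * (area/10) * minutes; empirical mean within 3 SE
        spec = SyntheticSpec(n_boutons=1, bouton_radius_um=1.5, margin_um=0.5, n_frames=30)
        mask = make_geometry(spec)
        lam = spec.event_frequency * mask.area_um2 / 10.0 * (30 * 4.0 / 60.0)
        n_draws = 400
        counts = [
            len(sample_events(replace(spec, rng_seed=s), mask)) for s in range(n_draws)
        ]
        se = np.sqrt(lam / n_draws)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_durations_at_least_one_frame(self):
        spec = SyntheticSpec(duration_mean_s=16.0, duration_sd_s=20.0, rng_seed=3)
        mask = make_geometry(spec)
        events = sample_events(spec, mask)
        assert events and all(e.n_frames >= 1 for e in events)

    def test_positions_inside_mask(self):
        spec = SyntheticSpec(rng_seed=9)
        mask = make_geometry(spec)
        for e in sample_events(spec, mask):
            col = int(e.x_um / spec.pixel_size_um)
            row = int(e.y_um / spec.pixel_size_um)
            assert mask.pixels[row, col]


class TestRender:
    def test_no_events_is_constant_baseline(self):
        spec = SyntheticSpec(rng_seed=0, baseline_blur_um=0.0)
        mask = make_geometry(spec)
        movie = render_movie([], mask, spec)
        assert np.all(movie.data[:, mask.pixels] == spec.baseline_intensity)
        assert np.all(movie.data[:, ~mask.pixels] == 0.0)

    def test_rect_event_doubles_baseline_at_peak(self):
        spec = replace(
            SyntheticSpec(), temporal_profile="rect", noise_sigma=0.0, baseline_blur_um=0.0
        )
        mask = make_geometry(spec)
        col, row = 30, 23
        x = (col + 0.5) * spec.pixel_size_um  # event centred on a pixel
        y = (row + 0.5) * spec.pixel_size_um
        ev = GroundTruthEvent(x, y, 3, 4, amplitude=spec.baseline_intensity)  # a = 1
        movie = render_movie([ev], mask, spec)
        trace = movie.data[:, row, col]
        assert trace[3:7] == pytest.approx(2 * spec.baseline_intensity, rel=1e-6)
        # rectangular profile: frames outside the lifetime are exactly baseline
        assert np.all(trace[:3] == spec.baseline_intensity)
        assert np.all(trace[7:] == spec.baseline_intensity)

    def test_overlapping_events_superpose_additively(self):
        spec = replace(SyntheticSpec(), temporal_profile="rect")
        mask = make_geometry(spec)
        ev = GroundTruthEvent(4.0, 3.0, 3, 4, amplitude=100.0)
        one = render_movie([ev], mask, spec)
        two = render_movie([ev, ev], mask, spec)
        np.testing.assert_allclose(
            two.data[4] - one.data[4], one.data[4] - render_movie([], mask, spec).data[4]
        )

    def test_noiseless_event_amplitude_recovered_by_track_metric(self):
        """Generator-to-metric tie-in: an isolated noiseless event built for a
        0.68 relative amplitude is recovered within 5% by the track metric."""
        k = 12
        a = amplitude_for_relative(0.68, k, "hann")
        spec = replace(
            SyntheticSpec(),
            noise_sigma=0.0,
            shot_noise=False,
            amplitude_ratio=a,
            event_frequency=0.0,
            baseline_blur_um=0.0,
        )
        mask = make_geometry(spec)
        ev = GroundTruthEvent(4.0, 3.0, 20, k, amplitude=a * spec.baseline_intensity)
        movie = render_movie([ev], mask, spec)
        spots = detect_movie(movie, mask, DetectionParams())
        tracks = link_tracks(spots, spec.pixel_size_um, TrackingParams(), n_frames=spec.n_frames)
        # select the event's track (mask-edge LoG ridge artifacts are static
        # and far from the event position)
        near = [
            t
            for t in tracks
            if t.n_spots >= 4
            and np.hypot(*(t.positions_um().mean(axis=0) - np.array([4.0, 3.0]))) < 0.3
        ]
        assert len(near) == 1
        assert relative_amplitude(near[0]) == pytest.approx(0.68, rel=0.05)


class TestPixelMode:
    def test_zero_fraction_is_constant(self):
        spec = SyntheticSpec(
            pixel_mode=True,
            dynamic_pixel_fraction=0.0,
            noise_sigma=0.0,
            shot_noise=False,
            baseline_blur_um=0.0,
        )
        movie, mask, dyn = pixel_mode_movie(spec)
        assert dyn.sum() == 0
        assert np.all(movie.data[:, mask.pixels] == spec.baseline_intensity)

    def test_time_mean_matches_duty_cycle(self):
        # union of Poisson on-intervals: stationary on-fraction 1 - exp(-rate*dur);
        # rate*dur = ln 2 gives a 50% duty cycle, so the long-run time mean of
        # every dynamic pixel tends to B*(1 + a/2)
        dur = 24.0
        rate_per_min = 60.0 * np.log(2.0) / dur
        spec = SyntheticSpec(
            n_boutons=1,
            bouton_radius_um=0.5,
            margin_um=0.3,
            pixel_mode=True,
            dynamic_pixel_fraction=1.0,
            pixel_event_rate_per_min=rate_per_min,
            duration_mean_s=dur,
            duration_sd_s=1e-6,
            n_frames=2000,
            frame_interval_s=4.0,
            noise_sigma=0.0,
            baseline_blur_um=0.0,
            shot_noise=False,
            amplitude_ratio=1.0,
            rng_seed=11,
        )
        movie, mask, dyn = pixel_mode_movie(spec)
        B = spec.baseline_intensity
        time_means = movie.data[:, mask.pixels].mean(axis=0)
        assert time_means.mean() == pytest.approx(B * 1.5, rel=0.03)

    def test_seed_determinism(self):
        spec = SyntheticSpec(pixel_mode=True, n_frames=20, rng_seed=5)
        m1, _, d1 = pixel_mode_movie(spec)
        m2, _, d2 = pixel_mode_movie(spec)
        np.testing.assert_array_equal(m1.data, m2.data)
        np.testing.assert_array_equal(d1, d2)


class TestNoiseAndBleach:
    def test_identity_when_disabled(self, flat_movie):
        spec = SyntheticSpec(noise_sigma=0.0, shot_noise=False, bleach_rate=0.0)
        out = apply_noise_and_bleach(flat_movie, spec)
        np.testing.assert_array_equal(out.data, flat_movie.data)

    def test_bleach_half_life(self):
        n, dt = 21, 4.0
        movie = Movie(np.full((n, 8, 8), 100.0), 0.13, dt)
        half_t = (n - 1) * dt
        k = np.log(2.0) / half_t
        spec = SyntheticSpec(noise_sigma=0.0, shot_noise=False, bleach_rate=k)
        out = apply_noise_and_bleach(movie, spec)
        assert out.data[-1].mean() == pytest.approx(out.data[0].mean() / 2.0, rel=1e-6)

    def test_shot_noise_poisson_variance(self):
        movie = Movie(np.full((2000, 6, 6), 100.0), 0.13, 1.0)
        spec = SyntheticSpec(noise_sigma=0.0, shot_noise=True, rng_seed=2)
        out = apply_noise_and_bleach(movie, spec)
        var = out.data.var(axis=0).mean()
        assert var == pytest.approx(100.0, rel=0.05)

    def test_negative_noise_sigma_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(noise_sigma=-1.0).validate()


class TestDeterminismAndCoupling:
    def test_full_simulation_seed_determinism(self):
        a = simulate_movie(SyntheticSpec(rng_seed=21))
        b = simulate_movie(SyntheticSpec(rng_seed=21))
        np.testing.assert_array_equal(a.movie.data, b.movie.data)
        assert len(a.events) == len(b.events)

    def test_nested_streams_are_nested_with_correct_rates(self):
        spec = SyntheticSpec(rng_seed=4)
        mask = make_geometry(spec)
        mults = (0.5, 1.0, 2.0)
        streams = nested_event_streams(spec, mask, mults, np.random.default_rng(0))
        ids = {m: {id(e) for e in evs} for m, evs in streams.items()}
        assert ids[0.5] <= ids[1.0] <= ids[2.0]
        # thinning ratio approximately proportional to multiplier
        assert len(streams[1.0]) < len(streams[2.0])
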