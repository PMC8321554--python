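"""Spot detection, LAP linking (vs brute-force oracle), track filtering."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchdyn.core import DetectionParams, Mask, Spot, Track, TrackingParams
from patchdyn.synth import (
    GroundTruthEvent,
    SyntheticSpec,
    make_geometry,
    render_movie,
    simulate_movie,
)
from patchdyn.tracking import (
    _assignment,
    detect_movie,
    detect_spots,
    filter_tracks,
    link_tracks,
    track_movie,
)


def _flat_mask(shape=(40, 40), px=0.13):
    return Mask(np.ones(shape, dtype=bool), px)


def _gaussian_frame(shape, centers, amplitude, baseline=10.0, sigma_px=1.96):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, baseline)
    for cy, cx in centers:
        img = img + amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2))
    return img


class TestDetection:
    def test_flat_frame_yields_no_spots(self, detection_params):
        mask = _flat_mask()
        assert detect_spots(np.full((40, 40), 7.0), mask, 0.13, detection_params) == []

    def test_single_spot_localized_subpixel(self, detection_params):
        mask = _flat_mask((50, 50))
        # true centre between pixels: (20.3, 24.6) in pixel units
        yy, xx = np.mgrid[:50, :50]
        img = 10.0 + 40.0 * np.exp(-((yy - 20.3) ** 2 + (xx - 24.6) ** 2) / (2 * 1.96**2))
        spots = detect_spots(img, mask, 0.13, detection_params)
        assert len(spots) == 1
        s = spots[0]
        assert abs(s.x_um / 0.13 - 0.5 - 24.6) <= 0.2
        assert abs(s.y_um / 0.13 - 0.5 - 20.3) <= 0.2

    def test_peak_below_probe_mean_threshold_rejected(self, detection_params):
        mask = _flat_mask((50, 50))
        img = _gaussian_frame((50, 50), [(25, 25)], amplitude=20.0, baseline=10.0)
        peak = img.max()
        # probe-mean rule: keep iff raw peak >= 0.32 * probe mean
        kept = detect_spots(img, mask, 0.13, detection_params, probe_mean_value=peak / 0.33)
        rejected = detect_spots(img, mask, 0.13, detection_params, probe_mean_value=peak / 0.31)
        assert len(kept) == 1
        assert rejected == []

    def test_spot_count_monotone_in_threshold_factor(self):
        sim = simulate_movie(SyntheticSpec(rng_seed=8, baseline_blur_um=0.0))
        frame = sim.movie.data[40]
        counts = []
        for tf in (0.1, 0.32, 1.0, 1.5, 2.0):
            params = DetectionParams(threshold_factor=tf)
            counts.append(len(detect_spots(frame, sim.mask, 0.13, params)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_mask_rejected(self, detection_params):
        with pytest.raises(ValueError):
            detect_spots(
                np.zeros((10, 10)), Mask(np.zeros((10, 10), bool), 0.13), 0.13, detection_params
            )


def _spot(frame, x, y, q=1.0):
    return Spot(frame, x, y, peak_intensity=100.0, quality=q)


def _brute_force_links(prev_xy, next_xy, max_dist):
    """Exhaustive minimum of sum(d^2) + b * (#unmatched) over partial matchings."""
    b = max_dist**2 * (1.0 + 1e-9) + 1e-12
    n, m = len(prev_xy), len(next_xy)
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(-1)
    best_cost, best = np.inf, []
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                pairs = list(zip(rows, cols))
                if any(d2[i, j] > max_dist**2 for i, j in pairs):
                    continue
                cost = sum(d2[i, j] for i, j in pairs) + b * ((n - k) + (m - k))
                if cost < best_cost - 1e-12:
                    best_cost, best = cost, pairs
    return best_cost, best


class TestLinking:
    def test_nearby_spots_link(self, tracking_params):
        spots = {0: [_spot(0, 1.0, 1.0)], 1: [_spot(1, 1.3, 1.0)]}
        tracks = link_tracks(spots, 0.13, tracking_params, n_frames=5)
        assert len(tracks) == 1 and tracks[0].n_spots == 2

    def test_spots_beyond_linking_distance_stay_separate(self, tracking_params):
        spots = {0: [_spot(0, 1.0, 1.0)], 1: [_spot(1, 1.6, 1.0)]}
        tracks = link_tracks(spots, 0.13, tracking_params, n_frames=5)
        assert sorted(t.n_spots for t in tracks) == [1, 1]

    def test_crossing_pairs_match_exhaustive_assignment(self):
        prev = np.array([[1.0, 1.0], [1.2, 1.0]])
        nxt = np.array([[1.15, 1.0], [1.05, 1.0]])
        links = _assignment(prev, nxt, 0.5)
        cost = sum(((prev[i] - nxt[j]) ** 2).sum() for i, j in links)
        best_cost, best = _brute_force_links(prev, nxt, 0.5)
        b = 0.5**2 * (1.0 + 1e-9) + 1e-12
        assert cost + b * (2 * (2 - len(links))) == pytest.approx(best_cost)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4), st.integers(1, 4))
    def test_assignment_matches_brute_force(self, seed, n, m):
        rng = np.random.default_rng(seed)
        prev = rng.uniform(0, 2.0, size=(n, 2))
        nxt = rng.uniform(0, 2.0, size=(m, 2))
        links = _assignment(prev, nxt, 0.5)
        b = 0.5**2 * (1.0 + 1e-9) + 1e-12
        cost = sum(((prev[i] - nxt[j]) ** 2).sum() for i, j in links) + b * (
            (n - len(links)) + (m - len(links))
        )
        best_cost, _ = _brute_force_links(prev, nxt, 0.5)
        assert cost == pytest.approx(best_cost, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linking_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        spots = {
            f: [
                _spot(f, x, y)
                for x, y in rng.uniform(0, 3.0, size=(rng.integers(0, 5), 2))
            ]
            for f in range(4)
        }
        params = TrackingParams()
        base = link_tracks(spots, 0.13, params, n_frames=4)
        shuffled = {
            f: [lst[i] for i in rng.permutation(len(lst))] for f, lst in spots.items()
        }
        perm = link_tracks(shuffled, 0.13, params, n_frames=4)
        canon = lambda tracks: sorted(
            tuple((s.frame, round(s.x_um, 9), round(s.y_um, 9)) for s in t.spots)
            for t in tracks
        )
        assert canon(base) == canon(perm)

    def test_frame_gap_terminates_tracks(self, tracking_params):
        spots = {0: [_spot(0, 1.0, 1.0)], 2: [_spot(2, 1.0, 1.0)]}
        tracks = link_tracks(spots, 0.13, tracking_params, n_frames=5)
        assert sorted(t.n_spots for t in tracks) == [1, 1]  # no gap closing


class TestFiltering:
    def _track(self, start, n, x=1.0, y=1.0, q=10.0):
        return Track([_spot(start + i, x, y, q) for i in range(n)])

    def test_short_track_rejected(self, tracking_params):
        accepted, report = filter_tracks([self._track(2, 3)], tracking_params)
        assert accepted == []
        assert report.counts == {"too_short": 1, "overlap": 0}

    def test_overlapping_concurrent_tracks_drop_shorter(self, tracking_params):
        long = self._track(0, 8, x=1.0)
        short = self._track(2, 5, x=1.3)  # within 0.5 um of `long` while concurrent
        accepted, report = filter_tracks([long, short], tracking_params)
        assert accepted == [long]
        assert report.overlap == [short]

    def test_overlap_policy_both(self):
        params = TrackingParams(overlap_policy="both")
        a = self._track(0, 8, x=1.0)
        b = self._track(2, 5, x=1.3)
        accepted, report = filter_tracks([a, b], params)
        assert accepted == []
        assert set(map(id, report.overlap)) == {id(a), id(b)}

    def test_distant_or_nonconcurrent_tracks_kept(self, tracking_params):
        a = self._track(0, 10, x=1.0)
        far = self._track(0, 5, x=2.0)
        later = self._track(11, 5, x=1.0)
        accepted, report = filter_tracks([a, far, later], tracking_params)
        assert len(accepted) == 3 and report.all_rejected == []

    def test_equal_length_tie_broken_by_quality(self, tracking_params):
        lo = self._track(0, 5, x=1.0, q=1.0)
        hi = self._track(0, 5, x=1.3, q=9.0)
        accepted, report = filter_tracks([lo, hi], tracking_params)
        assert accepted == [hi] and report.overlap == [lo]


class TestEndToEndTruth:
    def test_isolated_rect_events_tracked_bijectively(self):
        """Noiseless movie with well-separated rectangular events: accepted
        tracks correspond 1:1 to events with exact spot counts."""
        spec = replace(
            SyntheticSpec(),
            noise_sigma=0.0,
            shot_noise=False,
            temporal_profile="rect",
            event_frequency=0.0,
            amplitude_ratio=1.9,
        )
        mask = make_geometry(spec)
        amp = spec.amplitude_ratio * spec.baseline_intensity
        events = [
            GroundTruthEvent(2.5, 3.0, 5, 6, amp),
            GroundTruthEvent(5.0, 2.0, 20, 4, amp),
            GroundTruthEvent(8.0, 4.0, 40, 12, amp),
            GroundTruthEvent(10.5, 3.0, 60, 8, amp),
        ]
        movie = render_movie(events, mask, spec)
        accepted, report, _ = track_movie(movie, mask, DetectionParams(), TrackingParams())
        assert len(accepted) == len(events)
        by_pos = {
            (round(t.positions_um().mean(0)[0], 1), round(t.positions_um().mean(0)[1], 1)): t
            for t in accepted
        }
        for ev in events:
            track = by_pos[(round(ev.x_um, 1), round(ev.y_um, 1))]
            assert track.n_spots == ev.n_frames
            assert track.start_frame == ev.start_frame
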