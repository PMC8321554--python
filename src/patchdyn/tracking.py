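"""LoG spot detection and LAP frame-to-frame linking of actin patches.

Detection: candidates are local maxima of a scale-normalized
Laplacian-of-Gaussian response at sigma = diameter / (2*sqrt(2)) inside the
presynaptic mask, localized to sub-pixel precision by quadratic
interpolation.  A candidate is retained when its raw peak intensity is at
least ``threshold_factor`` times the probe mean (the movie-wide mean masked
intensity) — one global threshold per movie — and its filter response
clears a robust noise floor so that flat or noise-only regions yield no
spots.

Linking: per consecutive frame pair, the assignment minimizing the summed
squared displacement over all feasible links (global linear assignment,
links beyond ``linking_max_um`` forbidden).  Unlinked spots start new
tracks; a track with no link terminates — no gap closing, splitting or
merging.  Tracks touching the first/last movie frame carry censored flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .core import DetectionParams, Mask, Movie, Spot, Track, TrackingParams

logger = logging.getLogger("patchdyn")


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def log_sigma_px(params: DetectionParams, pixel_size_um: float) -> float:
    """Blob scale: sigma = diameter / (2*sqrt(2)), in pixels."""
    return params.diameter_um / (2.0 * math.sqrt(2.0)) / pixel_size_um


def log_response(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized LoG response; positive on bright blobs.

    The wide truncation keeps the kernel's DC leakage (response to a
    constant image) below float noise, so flat regions yield no candidates.
    """
    return -sigma_px**2 * ndi.gaussian_laplace(
        np.asarray(image, dtype=float), sigma_px, truncate=8.0
    )


def probe_mean(movie: Movie, mask: Mask) -> float:
    """Mean probe intensity in the presynaptic area over all frames."""
    mask.require_nonempty()
    return float(movie.data[:, mask.pixels].mean())


def _noise_region(mask: Mask, sigma_px: float) -> np.ndarray:
    """Mask interior for noise estimation: the boundary band carries the
    LoG step-edge ridge (signal structure, not noise), so it is eroded away.
    Falls back to the full mask when erosion would empty it."""
    margin = max(1, int(math.ceil(4 * sigma_px)))
    interior = ndi.binary_erosion(mask.pixels, iterations=margin)
    return interior if interior.any() else mask.pixels


def _mad_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def _subpixel_offset(resp: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Per-axis parabolic vertex of the 3x3 response neighbourhood, clamped to +-0.5."""
    offs = []
    for (a, b, cc) in (
        (resp[r - 1, c], resp[r, c], resp[r + 1, c]),
        (resp[r, c - 1], resp[r, c], resp[r, c + 1]),
    ):
        denom = a - 2 * b + cc
        off = 0.5 * (a - cc) / denom if denom < 0 else 0.0
        offs.append(float(np.clip(off, -0.5, 0.5)))
    return offs[0], offs[1]  # (dr, dc)


def detect_spots(
    frame_image: np.ndarray,
    mask: Mask,
    pixel_size_um: float,
    params: DetectionParams,
    probe_mean_value: float | None = None,
    frame_index: int = 0,
    noise_region: np.ndarray | None = None,
) -> list[Spot]:
    """Detect sub-pixel spots in one frame.

    ``probe_mean_value`` is the movie-wide probe mean; when omitted (single
    frame use) it falls back to this frame's masked mean.  ``noise_region``
    is the pixel set used for the noise-floor estimate (default: the mask
    interior, away from the boundary ridge).
    """
    params.validate()
    mask.require_nonempty()
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    frame_image = np.asarray(frame_image, dtype=float)
    if frame_image.shape != mask.pixels.shape:
        raise ValueError("frame and mask shapes differ")
    if params.median_filter:
        frame_image = ndi.median_filter(frame_image, size=3)
    if probe_mean_value is None:
        probe_mean_value = float(frame_image[mask.pixels].mean())

    sigma = log_sigma_px(params, pixel_size_um)
    resp = log_response(frame_image, sigma)
    if noise_region is None:
        noise_region = _noise_region(mask, sigma)
    noise_floor = params.noise_quality_k * _mad_sigma(resp[noise_region])
    span = float(np.ptp(frame_image[mask.pixels]))
    floor = max(noise_floor, 1e-9 * span, 1e-12)

    min_dist = max(1, int(round(params.diameter_um / 2.0 / pixel_size_um)))
    peaks = peak_local_max(
        resp,
        min_distance=min_dist,
        threshold_abs=floor,
        exclude_border=False,
        labels=mask.pixels.astype(int),
    )
    threshold = params.threshold_factor * probe_mean_value
    spots: list[Spot] = []
    n_rows, n_cols = frame_image.shape
    for r, c in peaks:
        raw = float(frame_image[r, c])
        quality = float(resp[r, c])
        score = raw if params.threshold_on == "intensity" else quality
        if score < threshold:
            continue
        dr = dc = 0.0
        if params.subpixel and 0 < r < n_rows - 1 and 0 < c < n_cols - 1:
            dr, dc = _subpixel_offset(resp, r, c)
        spots.append(
            Spot(
                frame=frame_index,
                x_um=(c + dc + 0.5) * pixel_size_um,
                y_um=(r + dr + 0.5) * pixel_size_um,
                peak_intensity=raw,
                quality=quality,
            )
        )
    return spots


def detect_movie(
    movie: Movie, mask: Mask, params: DetectionParams
) -> dict[int, list[Spot]]:
    """Detect spots in every frame against one movie-wide probe-mean threshold."""
    pm = probe_mean(movie, mask)
    region = _noise_region(mask, log_sigma_px(params, movie.pixel_size_um))
    return {
        t: detect_spots(
            movie.data[t], mask, movie.pixel_size_um, params, pm,
            frame_index=t, noise_region=region,
        )
        for t in range(movie.n_frames)
    }


def movie_noise_sigma(movie: Movie, mask: Mask, params: DetectionParams) -> float:
    """Robust LoG-response noise SD of a movie: median over frames of the
    MAD-based estimate within the mask interior."""
    mask.require_nonempty()
    sigma = log_sigma_px(params, movie.pixel_size_um)
    region = _noise_region(mask, sigma)
    per_frame = [
        _mad_sigma(log_response(movie.data[t], sigma)[region])
        for t in range(movie.n_frames)
    ]
    return float(np.median(per_frame))


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------


def _assignment(prev_xy: np.ndarray, next_xy: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """Optimal feasible links between two point sets.

    Minimizes ``sum(d^2 over links) + b * (#unmatched)`` with the
    no-link alternative ``b`` just above ``max_dist**2``, so every feasible
    link is preferred to leaving both ends unmatched and the chosen links
    minimize total squared displacement.
    """
    n, m = len(prev_xy), len(next_xy)
    if n == 0 or m == 0:
        return []
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(-1)
    b = max_dist**2 * (1.0 + 1e-9) + 1e-12
    big = 1e9 * max(b, 1.0)
    size = n + m
    cost = np.full((size, size), big)
    cost[:n, :m] = np.where(d2 <= max_dist**2, d2, big)
    cost[np.arange(n), m + np.arange(n)] = b  # unmatched old spot
    cost[n + np.arange(m), np.arange(m)] = b  # unmatched new spot
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and d2[i, j] <= max_dist**2
    ]


def link_tracks(
    spots_by_frame: dict[int, list[Spot]],
    pixel_size_um: float,
    params: TrackingParams,
    n_frames: int | None = None,
) -> list[Track]:
    """Link per-frame detections into tracks (no gap closing).

    A jump in the frame index terminates all active tracks.  ``n_frames``
    (default: one past the largest frame index seen) sets the movie extent
    used for the censored-end flag.
    """
    params.validate()
    frames = sorted(spots_by_frame)
    if not frames:
        return []
    if n_frames is None:
        n_frames = frames[-1] + 1
    last_frame = n_frames - 1

    finished: list[list[Spot]] = []
    active: list[list[Spot]] = []
    prev_frame: int | None = None
    for f in frames:
        spots = list(spots_by_frame[f])
        if prev_frame is not None and f == prev_frame + 1 and active:
            prev_xy = np.array([[tr[-1].x_um, tr[-1].y_um] for tr in active])
            next_xy = np.array([[s.x_um, s.y_um] for s in spots]) if spots else np.empty((0, 2))
            links = _assignment(prev_xy, next_xy, params.linking_max_um)
            linked_prev = {i for i, _ in links}
            linked_next = {j for _, j in links}
            new_active: list[list[Spot]] = []
            for i, j in sorted(links):
                active[i].append(spots[j])
                new_active.append(active[i])
            for i, tr in enumerate(active):
                if i not in linked_prev:
                    finished.append(tr)
            for j, s in enumerate(spots):
                if j not in linked_next:
                    new_active.append([s])
            active = new_active
        else:
            finished.extend(active)
            active = [[s] for s in spots]
        prev_frame = f
    finished.extend(active)

    tracks = []
    for spot_list in finished:
        tracks.append(
            Track(
                spot_list,
                censored_start=spot_list[0].frame == 0,
                censored_end=spot_list[-1].frame == last_frame,
            )
        )
    tracks.sort(key=lambda tr: (tr.start_frame, tr.spots[0].x_um, tr.spots[0].y_um))
    return tracks


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


@dataclass
class RejectionReport:
    """Rejected tracks by reason, kept for the upper-bound frequency correction."""

    too_short: list[Track] = field(default_factory=list)
    overlap: list[Track] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {"too_short": len(self.too_short), "overlap": len(self.overlap)}

    @property
    def all_rejected(self) -> list[Track]:
        return self.too_short + self.overlap


def _tracks_conflict(a: Track, b: Track, max_dist: float) -> bool:
    lo = max(a.start_frame, b.start_frame)
    hi = min(a.end_frame, b.end_frame)
    if lo > hi:
        return False
    pa = {s.frame: (s.x_um, s.y_um) for s in a.spots}
    pb = {s.frame: (s.x_um, s.y_um) for s in b.spots}
    for f in range(lo, hi + 1):
        (xa, ya), (xb, yb) = pa[f], pb[f]
        if (xa - xb) ** 2 + (ya - yb) ** 2 <= max_dist**2:
            return True
    return False


def filter_tracks(
    tracks: list[Track], params: TrackingParams
) -> tuple[list[Track], RejectionReport]:
    """Reject too-short tracks and overlapping track paths.

    Tracks with fewer than ``min_spots`` detections are rejected
    (``too_short``).  When two concurrent tracks ever come within
    ``linking_max_um`` of each other the shorter (fewer spots; tie broken
    by lower mean quality) is rejected (``overlap``); the ``both`` policy
    rejects both members of the pair.
    """
    params.validate()
    report = RejectionReport()
    long_enough = []
    for tr in tracks:
        if tr.n_spots < params.min_spots:
            report.too_short.append(tr)
        else:
            long_enough.append(tr)

    rejected = set()
    n = len(long_enough)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = long_enough[i], long_enough[j]
            if not _tracks_conflict(a, b, params.linking_max_um):
                continue
            if params.overlap_policy == "both":
                rejected.update((i, j))
            else:
                key_a = (a.n_spots, a.mean_quality)
                key_b = (b.n_spots, b.mean_quality)
                rejected.add(i if key_a < key_b else j)
    accepted = [tr for i, tr in enumerate(long_enough) if i not in rejected]
    report.overlap.extend(tr for i, tr in enumerate(long_enough) if i in rejected)
    return accepted, report


def track_movie(
    movie: Movie,
    mask: Mask,
    detection: DetectionParams,
    tracking: TrackingParams,
) -> tuple[list[Track], RejectionReport, dict[int, list[Spot]]]:
    """Detect, link, seed-filter and patch-filter in one call.

    Between linking and the track filters, tracks whose best spot never
    clears ``seed_quality_k`` noise SDs of LoG response are discarded as
    noise chains (hysteresis; they are detector artifacts, not rejected
    patches, so they do not enter the rejection report).
    """
    spots = detect_movie(movie, mask, detection)
    tracks = link_tracks(spots, movie.pixel_size_um, tracking, n_frames=movie.n_frames)
    if tracking.seed_quality_k > 0:
        seed_floor = tracking.seed_quality_k * movie_noise_sigma(movie, mask, detection)
        n_before = len(tracks)
        tracks = [tr for tr in tracks if max(s.quality for s in tr.spots) >= seed_floor]
        if n_before - len(tracks):
            logger.debug("discarded %d noise chains below seed floor", n_before - len(tracks))
    accepted, report = filter_tracks(tracks, tracking)
    return accepted, report, spots
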