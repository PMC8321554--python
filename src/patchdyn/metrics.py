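"""Patch statistics: frequency, duration distribution, amplitude, and the
two-sampling-rate merged frequency estimate with correction bounds.

Duration convention: ``duration_s = n_spots * frame_interval_s`` (spot
count, not frame span) — at 0.25 Hz a 4-detection track is 16 s and an
89-detection track 356 s, matching the detection ranges the tracker can
observe; at 1 Hz the floor is 4 s and the ceiling 139 s.

The merged estimator combines a low-rate (0.25 Hz) and a high-rate (1 Hz)
duration census: frequencies over the shared detection range (20–150 s)
are averaged, and each regime contributes the durations only it can see
(<20 s for 1 Hz, 150–360 s for 0.25 Hz).  The accepted-track value is the
lower bound ("corrected merged frequency of detection"); adding every
rejected track back gives the upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Mask, Movie, Track

# Duration brackets (seconds, half-open) for the two-regime merge.  The
# 16-20 s sliver between the 0.25 Hz detection floor and the shared range
# is carried by the high-rate-only term.
SHARED_RANGE = (20.0, 150.0)
LOW_ONLY_RANGE = (150.0, 360.0)   # visible only at 0.25 Hz
HIGH_ONLY_RANGE = (4.0, 20.0)     # visible only at 1 Hz


def track_duration(track: Track, frame_interval_s: float) -> float:
    """Track lifetime in seconds (spot-count convention)."""
    return track.n_spots * frame_interval_s


def relative_amplitude(track: Track, movie: Movie | None = None) -> float:
    """(Imax - Imin) / Imean over the track's per-frame peak intensities.

    Uses the stored spot peak intensities; pass ``movie`` to re-read raw
    values at the rounded spot positions instead.
    """
    if track.n_spots < 2:
        raise ValueError("relative amplitude needs >= 2 spots")
    if movie is None:
        vals = track.peak_intensities
    else:
        px = movie.pixel_size_um
        vals = np.array(
            [
                movie.data[
                    s.frame,
                    int(round(s.y_um / px - 0.5)),
                    int(round(s.x_um / px - 0.5)),
                ]
                for s in track.spots
            ]
        )
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("non-positive mean intensity")
    return float((vals.max() - vals.min()) / mean)


def patch_frequency(n_tracks: int, mask_area_um2: float, movie_duration_min: float) -> float:
    """Events per 10 µm² per minute."""
    if mask_area_um2 <= 0:
        raise ValueError("mask area must be positive")
    if movie_duration_min <= 0:
        raise ValueError("movie duration must be positive")
    return n_tracks / (mask_area_um2 / 10.0) / movie_duration_min


@dataclass(frozen=True)
class DurationHistogram:
    """Half-open 20-s binning of durations, centers at 10, 30, 50, ... s."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def duration_histogram(durations_s, bin_width: float = 20.0) -> DurationHistogram:
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    durations_s = np.asarray(durations_s, dtype=float)
    if durations_s.size and durations_s.min() < 0:
        raise ValueError("durations must be >= 0")
    n_bins = int(durations_s.max() // bin_width) + 1 if durations_s.size else 1
    idx = (durations_s // bin_width).astype(int) if durations_s.size else np.array([], int)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return DurationHistogram(edges, counts)


@dataclass(frozen=True)
class PatchStats:
    """Per-movie patch statistics.

    ``n_tracks`` counts all accepted tracks (censored included, as they are
    real events for the frequency); ``durations_s`` and the histogram hold
    uncensored tracks only, whose durations are fully observed.
    """

    n_tracks: int
    frequency_per10um2_min: float
    durations_s: np.ndarray
    duration_hist: DurationHistogram
    rel_amplitudes: np.ndarray
    mask_area_um2: float
    movie_duration_min: float
    frame_interval_s: float

    @property
    def mean_duration_s(self) -> float:
        return float(self.durations_s.mean()) if self.durations_s.size else float("nan")

    @property
    def sd_duration_s(self) -> float:
        return float(self.durations_s.std()) if self.durations_s.size else float("nan")

    @property
    def mean_rel_amplitude(self) -> float:
        return float(self.rel_amplitudes.mean()) if self.rel_amplitudes.size else float("nan")

    @property
    def event_weight(self) -> float:
        """Frequency contribution of a single track (per 10 µm² per min)."""
        return 1.0 / (self.mask_area_um2 / 10.0) / self.movie_duration_min

    def to_dict(self) -> dict:
        return {
            "n_tracks": self.n_tracks,
            "frequency_per10um2_min": self.frequency_per10um2_min,
            "mean_duration_s": self.mean_duration_s,
            "sd_duration_s": self.sd_duration_s,
            "mean_rel_amplitude": self.mean_rel_amplitude,
            "mask_area_um2": self.mask_area_um2,
            "movie_duration_min": self.movie_duration_min,
            "duration_hist_centers": self.duration_hist.centers.tolist(),
            "duration_hist_counts": self.duration_hist.counts.tolist(),
            "durations_s": self.durations_s.tolist(),
        }


def compute_patch_stats(tracks: list[Track], mask: Mask, movie: Movie) -> PatchStats:
    """Summarize accepted tracks into the per-movie statistics table."""
    mask.require_nonempty()
    dt = movie.frame_interval_s
    uncensored = [tr for tr in tracks if not (tr.censored_start or tr.censored_end)]
    durations = np.array([track_duration(tr, dt) for tr in uncensored])
    amps = np.array([relative_amplitude(tr) for tr in uncensored if tr.n_spots >= 2])
    return PatchStats(
        n_tracks=len(tracks),
        frequency_per10um2_min=patch_frequency(len(tracks), mask.area_um2, movie.duration_min),
        durations_s=durations,
        duration_hist=duration_histogram(durations),
        rel_amplitudes=amps,
        mask_area_um2=mask.area_um2,
        movie_duration_min=movie.duration_min,
        frame_interval_s=dt,
    )


# ---------------------------------------------------------------------------
# Two-regime merged frequency estimate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegimeDurations:
    """Duration census of one imaging regime in frequency units.

    ``weight`` converts a track count into events / 10 µm² / min
    (``1 / (area/10) / minutes``, summed over the regime's movies).
    """

    durations_s: np.ndarray
    weight: float
    rejected_durations_s: np.ndarray = field(default_factory=lambda: np.array([]))

    @classmethod
    def from_stats(cls, stats: PatchStats, rejected_durations_s=()) -> "RegimeDurations":
        return cls(
            np.asarray(stats.durations_s, dtype=float),
            stats.event_weight,
            np.asarray(rejected_durations_s, dtype=float),
        )


def _bracket_freq(durations: np.ndarray, weight: float, lo: float, hi: float) -> float:
    d = np.asarray(durations, dtype=float)
    return float(((d >= lo) & (d < hi)).sum() * weight)


@dataclass(frozen=True)
class FrequencyEstimate:
    """Merged two-regime frequency with correction bounds (per 10 µm² per min)."""

    merged_frequency: float
    lower_bound: float
    upper_bound: float
    components: dict

    @classmethod
    def from_components(
        cls,
        shared_low: float,
        shared_high: float,
        high_only: float,
        low_only: float,
        upper_extra: float = 0.0,
    ) -> "FrequencyEstimate":
        merged = (shared_low + shared_high) / 2.0 + high_only + low_only
        return cls(
            merged_frequency=merged,
            lower_bound=merged,
            upper_bound=merged + upper_extra,
            components={
                "shared_low": shared_low,
                "shared_high": shared_high,
                "high_only": high_only,
                "low_only": low_only,
            },
        )


def merged_frequency_estimate(low: RegimeDurations, high: RegimeDurations) -> FrequencyEstimate:
    """Merge 0.25 Hz ("low") and 1 Hz ("high") duration censuses.

    merged = mean(shared-range frequencies) + high-only + low-only, from
    accepted tracks; the upper bound recomputes the same formula with every
    rejected track added back (at its measured duration), plus the rejected
    mass falling outside each regime's detectable brackets.
    """
    shared_lo, shared_hi = SHARED_RANGE
    merged = FrequencyEstimate.from_components(
        _bracket_freq(low.durations_s, low.weight, shared_lo, shared_hi),
        _bracket_freq(high.durations_s, high.weight, shared_lo, shared_hi),
        _bracket_freq(high.durations_s, high.weight, *HIGH_ONLY_RANGE),
        _bracket_freq(low.durations_s, low.weight, *LOW_ONLY_RANGE),
    )

    low_all = np.concatenate([low.durations_s, low.rejected_durations_s])
    high_all = np.concatenate([high.durations_s, high.rejected_durations_s])
    in_low_brackets = lambda d: (d >= shared_lo) & (d < LOW_ONLY_RANGE[1])
    in_high_brackets = lambda d: (d >= HIGH_ONLY_RANGE[0]) & (d < shared_hi)
    extra_low = float((~in_low_brackets(low.rejected_durations_s)).sum() * low.weight)
    extra_high = float((~in_high_brackets(high.rejected_durations_s)).sum() * high.weight)
    upper = (
        (
            _bracket_freq(low_all, low.weight, shared_lo, shared_hi)
            + _bracket_freq(high_all, high.weight, shared_lo, shared_hi)
        )
        / 2.0
        + _bracket_freq(high_all, high.weight, *HIGH_ONLY_RANGE)
        + _bracket_freq(low_all, low.weight, *LOW_ONLY_RANGE)
        + extra_low
        + extra_high
    )
    return FrequencyEstimate(
        merged_frequency=merged.merged_frequency,
        lower_bound=merged.merged_frequency,
        upper_bound=upper,
        components=merged.components,
    )
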