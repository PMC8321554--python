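"""Shared domain types, movie and track table I/O, and run configuration.

The central container is :class:`Movie`, a calibrated ``(frames, rows, cols)``
float intensity stack.  All spatial quantities downstream are expressed in
micrometres (``pixel_size_um``) and all temporal ones in seconds
(``frame_interval_s``); both calibrations are supplied explicitly by the
caller or a config file, never read from TIFF tags.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("patchdyn")


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Movie:
    """Calibrated intensity timelapse.

    Parameters
    ----------
    data:
        Float array indexed ``[frame, row, col]`` in detector units.
    pixel_size_um:
        Lateral pixel size in micrometres per pixel.
    frame_interval_s:
        Time between consecutive frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (T, Y, X); got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not np.all(np.isfinite(data)):
            raise ValueError("movie intensities must be finite (no NaN/inf)")
        if data.min() < 0:
            raise ValueError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        """Total observation time, ``n_frames * frame_interval_s``."""
        return self.n_frames * self.frame_interval_s

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def frame(self, i: int) -> np.ndarray:
        return self.data[i]


@dataclass(frozen=True)
class Mask:
    """Boolean presynaptic region with its physical area."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size_um**2

    def require_nonempty(self) -> None:
        if self.n_pixels == 0:
            raise ValueError("mask is empty")


@dataclass(frozen=True)
class Spot:
    """A single sub-pixel detection in one frame."""

    frame: int
    x_um: float
    y_um: float
    peak_intensity: float
    quality: float


@dataclass
class Track:
    """An ordered run of spots in strictly consecutive frames — one actin patch."""

    spots: list[Spot]
    censored_start: bool = False
    censored_end: bool = False

    def __post_init__(self) -> None:
        if not self.spots:
            raise ValueError("track must contain at least one spot")
        frames = [s.frame for s in self.spots]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly consecutive")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def start_frame(self) -> int:
        return self.spots[0].frame

    @property
    def end_frame(self) -> int:
        return self.spots[-1].frame

    @property
    def peak_intensities(self) -> np.ndarray:
        return np.array([s.peak_intensity for s in self.spots], dtype=float)

    @property
    def mean_quality(self) -> float:
        return float(np.mean([s.quality for s in self.spots]))

    def positions_um(self) -> np.ndarray:
        """``(n_spots, 2)`` array of (x, y) positions in µm."""
        return np.array([[s.x_um, s.y_um] for s in self.spots], dtype=float)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DetectionParams:
    """LoG spot-detection parameters.

    ``threshold_factor`` multiplies the movie-wide mean masked intensity
    ("probe mean") to give the retention threshold.  ``threshold_on``
    selects whether that threshold is compared against the raw peak
    intensity (default) or the LoG filter response ("quality").
    ``noise_quality_k`` sets the LoG-response noise floor in robust
    (MAD-based) standard deviations.
    """

    diameter_um: float = 0.6
    threshold_factor: float = 0.32
    median_filter: bool = False
    subpixel: bool = True
    threshold_on: str = "intensity"
    noise_quality_k: float = 3.0

    def validate(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        if self.threshold_on not in ("intensity", "quality"):
            raise ValueError("threshold_on must be 'intensity' or 'quality'")
        if self.noise_quality_k < 0:
            raise ValueError("noise_quality_k must be >= 0")


@dataclass
class TrackingParams:
    """Frame-to-frame linking and track-filtering parameters.

    ``seed_quality_k`` implements hysteresis detection at the track level:
    candidate spots only need to clear the low noise floor (so dim patch
    tails stay trackable), but a track is kept only if at least one of its
    spots exceeds ``seed_quality_k`` robust noise SDs of LoG response,
    which removes chains built purely from noise ripples.
    """

    linking_max_um: float = 0.5
    gap_closing_um: float = 0.5
    gap_frames: int = 0
    min_spots: int = 4
    overlap_policy: str = "shorter"
    seed_quality_k: float = 6.0

    def validate(self) -> None:
        if self.linking_max_um <= 0:
            raise ValueError("linking_max_um must be positive")
        if self.gap_frames != 0:
            raise ValueError("gap closing is disabled; gap_frames must be 0")
        if self.min_spots < 1:
            raise ValueError("min_spots must be >= 1")
        if self.overlap_policy not in ("shorter", "both"):
            raise ValueError("overlap_policy must be 'shorter' or 'both'")
        if self.seed_quality_k < 0:
            raise ValueError("seed_quality_k must be >= 0")


@dataclass
class PreprocessParams:
    register: bool = True
    max_shift_px: float = 10.0
    rolling_ball_radius_px: int = 50
    subtract_background: bool = False
    mask_blur_sigma_px: float = 2.0
    mask_method: str = "otsu"
    mask_keep_largest: bool = False

    def validate(self) -> None:
        if self.max_shift_px <= 0:
            raise ValueError("max_shift_px must be positive")
        if self.rolling_ball_radius_px <= 0:
            raise ValueError("rolling_ball_radius_px must be positive")
        if self.mask_blur_sigma_px < 0:
            raise ValueError("mask_blur_sigma_px must be >= 0")


@dataclass
class CovParams:
    n_bins: int = 256
    use_background_subtracted: bool = False

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class CalibrationParams:
    multipliers: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5, 2.0)
    n_reps: int = 10
    statistic: str = "mean_cov"

    def validate(self) -> None:
        if len(self.multipliers) < 3:
            raise ValueError("need >= 3 multipliers")
        if self.n_reps < 3:
            raise ValueError("n_reps must be >= 3")
        if self.statistic not in ("mean_cov", "variant_fraction_li", "variant_fraction_moments"):
            raise ValueError(f"unknown calibration statistic {self.statistic!r}")


@dataclass
class RunConfig:
    """Full analysis configuration; every stochastic step derives from ``rng_seed``."""

    pixel_size_um: float = 0.13
    frame_interval_s: float = 4.0
    rng_seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cov: CovParams = field(default_factory=CovParams)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        for block in (self.detection, self.tracking, self.preprocess, self.cov, self.calibration):
            block.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BLOCKS = {
    "detection": DetectionParams,
    "tracking": TrackingParams,
    "preprocess": PreprocessParams,
    "cov": CovParams,
    "calibration": CalibrationParams,
}


def _apply_block(obj, values: dict, context: str) -> None:
    known = {f.name for f in dataclasses.fields(obj)}
    for key, val in values.items():
        if key not in known:
            logger.warning("unknown config key %s.%s ignored", context, key)
            continue
        if key == "multipliers":
            val = tuple(float(v) for v in val)
        setattr(obj, key, val)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config, applying package defaults for absent keys.

    Unknown keys produce a warning; invalid values raise ``ValueError``.
    ``path=None`` (or an empty file) returns the defaults, which mirror the
    standard parameterization: 0.6 µm patch diameter, 0.32 threshold factor,
    0.5 µm linking distance, frame gap 0, 4-detection track floor, 50 px
    rolling-ball radius, 256-bin CoV histograms.
    """
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        for key, val in raw.items():
            if key in _BLOCKS:
                if not isinstance(val, dict):
                    raise ValueError(f"config block {key!r} must be a mapping")
                _apply_block(getattr(cfg, key), val, key)
            elif key in ("pixel_size_um", "frame_interval_s", "rng_seed"):
                setattr(cfg, key, val)
            else:
                logger.warning("unknown config key %s ignored", key)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Movie I/O
# ---------------------------------------------------------------------------


def read_movie(path: str | Path, pixel_size_um: float, frame_interval_s: float) -> Movie:
    """Read a multi-page grayscale TIFF as a :class:`Movie`.

    4-D stacks ``(T, Z, Y, X)`` are reduced by a per-frame maximum intensity
    projection over Z.  Intensities are promoted to float; no rescaling is
    applied, so the pixel sum is conserved by ingest.
    """
    try:
        data = tifffile.imread(str(path))
    except (FileNotFoundError, IsADirectoryError):
        raise
    except Exception as exc:  # noqa: BLE001 - normalize tifffile failure modes
        raise ValueError(f"unreadable TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == object:
        raise ValueError("TIFF pages have mixed shapes")
    if data.ndim == 4:
        data = data.max(axis=1)
    if data.ndim == 2:
        raise ValueError("movie must have at least 2 frames (single-page file)")
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D or 4-D stack; got shape {data.shape}")
    if data.shape[0] < 2:
        raise ValueError("movie must have at least 2 frames")
    return Movie(data.astype(float), pixel_size_um, frame_interval_s)


def write_movie(movie: Movie, path: str | Path) -> None:
    tifffile.imwrite(str(path), movie.data.astype(np.float32))


# ---------------------------------------------------------------------------
# Track table I/O
# ---------------------------------------------------------------------------

SPOT_COLUMNS = ["track_id", "frame", "x_um", "y_um", "peak_intensity", "quality"]
SUMMARY_COLUMNS = [
    "track_id",
    "n_spots",
    "duration_s",
    "rel_amplitude",
    "censored_start",
    "censored_end",
]


def _track_rel_amplitude(track: Track) -> float:
    vals = track.peak_intensities
    if len(vals) < 2:
        return float("nan")
    mean = vals.mean()
    if mean <= 0:
        return float("nan")
    return float((vals.max() - vals.min()) / mean)


def summary_path_for(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".summary.csv")


def write_tracks(
    tracks: Sequence[Track],
    path: str | Path,
    frame_interval_s: float,
    summary_path: str | Path | None = None,
) -> None:
    """Write per-spot and per-track summary CSVs (6-decimal round trip).

    The spot table goes to ``path``; the summary to ``summary_path``
    (default: ``<stem>.summary.csv`` next to the spot table).
    """
    spot_rows = []
    summary_rows = []
    for tid, track in enumerate(tracks):
        for s in track.spots:
            spot_rows.append((tid, s.frame, s.x_um, s.y_um, s.peak_intensity, s.quality))
        summary_rows.append(
            (
                tid,
                track.n_spots,
                track.n_spots * frame_interval_s,
                _track_rel_amplitude(track),
                track.censored_start,
                track.censored_end,
            )
        )
    spots_df = pd.DataFrame(spot_rows, columns=SPOT_COLUMNS)
    summary_df = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    if summary_path is None:
        summary_path = summary_path_for(path)
    spots_df.to_csv(path, index=False, float_format="%.6f")
    summary_df.to_csv(summary_path, index=False, float_format="%.6f")


def read_tracks(path: str | Path, summary_path: str | Path | None = None) -> list[Track]:
    """Rebuild tracks from the CSV pair written by :func:`write_tracks`."""
    spots_df = pd.read_csv(path)
    if summary_path is None:
        summary_path = summary_path_for(path)
    summary_df = pd.read_csv(summary_path).set_index("track_id") if Path(summary_path).exists() else None
    tracks: list[Track] = []
    for tid, group in spots_df.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        spots = [
            Spot(int(r.frame), float(r.x_um), float(r.y_um), float(r.peak_intensity), float(r.quality))
            for r in group.itertuples()
        ]
        censored_start = censored_end = False
        if summary_df is not None and tid in summary_df.index:
            censored_start = bool(summary_df.loc[tid, "censored_start"])
            censored_end = bool(summary_df.loc[tid, "censored_end"])
        tracks.append(Track(spots, censored_start, censored_end))
    return tracks
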