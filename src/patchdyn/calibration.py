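"""Simulation-based calibration of the CoV statistic to patch-frequency
change, plus the tracking-parameter robustness sweep.

The calibration forward-simulates movies from a base generative spec with
the event frequency scaled by a grid of multipliers, computes the chosen
CoV statistic per movie, fits an isotonic-then-piecewise-linear map from
multiplier to statistic, and inverts it to translate a measured statistic
difference (e.g. control vs mutant) into an inferred percent change in
patch frequency.  The base spec must match the experiment's imaging regime
(frame interval, movie length, noise); a curve is never valid across
regimes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .core import DetectionParams, Mask, Movie, RunConfig, TrackingParams
from .cov import cov_map, variant_area_fraction
from .metrics import patch_frequency
from .synth import (
    SyntheticSpec,
    apply_noise_and_bleach,
    make_geometry,
    nested_event_streams,
    render_movie,
    sample_events,
    simulate_movie,
)
from .tracking import detect_movie, filter_tracks, link_tracks

logger = logging.getLogger("patchdyn")


class CalibrationError(RuntimeError):
    pass


def child_seed(seed_seq: np.random.SeedSequence) -> int:
    """A 31-bit integer seed derived from a SeedSequence."""
    return int(seed_seq.generate_state(1)[0] % (2**31))


def _statistic(movie: Movie, mask: Mask, statistic: str) -> float:
    result = cov_map(movie, mask)
    if statistic == "mean_cov":
        return result.mean_cov
    if statistic == "variant_fraction_li":
        return variant_area_fraction(result, "li")
    if statistic == "variant_fraction_moments":
        return variant_area_fraction(result, "moments")
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map between frequency multiplier and CoV statistic."""

    multipliers: np.ndarray
    stat_mean: np.ndarray
    stat_se: np.ndarray
    fitted: np.ndarray  # isotonic-adjusted means, strictly increasing
    statistic: str

    def evaluate(self, multiplier: float) -> float:
        return float(np.interp(multiplier, self.multipliers, self.fitted))

    def invert(self, stat: float, clamp: bool = True) -> float:
        lo, hi = self.fitted[0], self.fitted[-1]
        if stat < lo or stat > hi:
            if not clamp:
                raise CalibrationError(
                    f"statistic {stat:.4g} outside calibrated range [{lo:.4g}, {hi:.4g}]"
                )
            logger.warning(
                "statistic %.4g outside calibrated range [%.4g, %.4g]; clamping", stat, lo, hi
            )
            stat = float(np.clip(stat, lo, hi))
        return float(np.interp(stat, self.fitted, self.multipliers))


def evaluate_statistic(spec: SyntheticSpec, statistic: str = "mean_cov") -> float:
    """Simulate one movie from ``spec`` and compute the CoV statistic on its
    ground-truth geometry mask."""
    sim = simulate_movie(spec)
    return _statistic(sim.movie, sim.mask, statistic)


def build_calibration_curve(
    base_spec: SyntheticSpec,
    multipliers=(0.5, 0.75, 1.0, 1.25, 1.5, 2.0),
    n_reps: int = 10,
    seed: int = 0,
    statistic: str = "mean_cov",
) -> CalibrationCurve:
    """Forward-simulate the statistic across a frequency-multiplier grid.

    For each multiplier, ``n_reps`` seeded movies are generated from
    ``base_spec`` with the event frequency scaled, and the statistic is
    recorded.  The mean curve is made monotone by isotonic regression; a
    non-strict (tied) fit signals a degenerate base spec (noise-dominated)
    and raises :class:`CalibrationError`.
    """
    multipliers = np.asarray(sorted(float(m) for m in multipliers))
    if len(multipliers) < 3:
        raise ValueError("need >= 3 multipliers")
    if not np.any(np.isclose(multipliers, 1.0)):
        raise ValueError("multipliers must include 1.0")
    if n_reps < 3:
        raise ValueError("n_reps must be >= 3")
    mask = make_geometry(base_spec)
    stats = np.empty((len(multipliers), n_reps))
    for j in range(n_reps):
        rng = np.random.default_rng(
            child_seed(np.random.SeedSequence([seed, j, 0x5CA1E]))
        )
        # one thinned master event stream per replicate couples the
        # multiplier grid (common random numbers); marginals are unchanged
        streams = nested_event_streams(base_spec, mask, multipliers, rng)
        for i, m in enumerate(multipliers):
            clean = render_movie(streams[float(m)], mask, base_spec)
            movie = apply_noise_and_bleach(clean, base_spec, rng)
            stats[i, j] = _statistic(movie, mask, statistic)
    means = stats.mean(axis=1)
    ses = stats.std(axis=1, ddof=1) / np.sqrt(n_reps)
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(multipliers, means)
    if np.any(np.diff(fitted) <= 0):
        raise CalibrationError(
            "statistic not strictly increasing in frequency after isotonic fit; "
            "base spec appears noise-dominated over this multiplier range"
        )
    return CalibrationCurve(multipliers, means, ses, fitted, statistic)


def evaluate_paired_statistic(
    spec: SyntheticSpec,
    test_multiplier: float,
    n_movies: int = 16,
    seed: int = 0,
    statistic: str = "mean_cov",
) -> tuple[float, float]:
    """Group-mean statistics for a coupled control / test experiment.

    Each pair shares its base event stream: the test movie carries the
    control events plus an independent extra stream at
    ``(test_multiplier - 1) * event_frequency`` (Poisson superposition), so
    the test group's frequency is exactly ``test_multiplier`` times the
    control's while the shared events cancel most between-pair variance.
    Returns ``(mean_stat_control, mean_stat_test)``.
    """
    if test_multiplier <= 1.0:
        raise ValueError("test_multiplier must exceed 1")
    mask = make_geometry(spec)
    stats_c, stats_t = [], []
    for i in range(n_movies):
        rng = np.random.default_rng(child_seed(np.random.SeedSequence([seed, i, 0xA17])))
        base_events = sample_events(spec, mask, rng)
        extra = sample_events(
            replace(spec, event_frequency=spec.event_frequency * (test_multiplier - 1.0)),
            mask,
            rng,
        )
        movie_c = apply_noise_and_bleach(render_movie(base_events, mask, spec), spec, rng)
        movie_t = apply_noise_and_bleach(
            render_movie(base_events + extra, mask, spec), spec, rng
        )
        stats_c.append(_statistic(movie_c, mask, statistic))
        stats_t.append(_statistic(movie_t, mask, statistic))
    return float(np.mean(stats_c)), float(np.mean(stats_t))


def infer_frequency_change(
    curve: CalibrationCurve, stat_control: float, stat_test: float, clamp: bool = True
) -> float:
    """Percent change in patch frequency implied by two statistic values.

    Inverts the calibration curve at both statistics and returns
    ``100 * (m_test / m_control - 1)``.
    """
    m_control = curve.invert(stat_control, clamp=clamp)
    m_test = curve.invert(stat_test, clamp=clamp)
    return 100.0 * (m_test / m_control - 1.0)


# ---------------------------------------------------------------------------
# Tracking-parameter robustness sweep
# ---------------------------------------------------------------------------


def parameter_robustness_sweep(
    movie: Movie,
    mask: Mask,
    threshold_factors,
    link_distances_um,
    config: RunConfig | None = None,
) -> np.ndarray:
    """Accepted-patch frequency over a (threshold, linking-distance) grid.

    Each cell reruns detection, linking and filtering with the modified
    parameters; returns a matrix of shape
    ``(len(threshold_factors), len(link_distances_um))``.
    """
    threshold_factors = list(threshold_factors)
    link_distances_um = list(link_distances_um)
    if not threshold_factors or not link_distances_um:
        raise ValueError("parameter grids must be non-empty")
    config = config or RunConfig(
        pixel_size_um=movie.pixel_size_um, frame_interval_s=movie.frame_interval_s
    )
    freq = np.empty((len(threshold_factors), len(link_distances_um)))
    for i, tf in enumerate(threshold_factors):
        det = replace_detection(config.detection, threshold_factor=float(tf))
        spots = detect_movie(movie, mask, det)
        for j, ld in enumerate(link_distances_um):
            trk = replace_tracking(config.tracking, linking_max_um=float(ld))
            tracks = link_tracks(spots, movie.pixel_size_um, trk, n_frames=movie.n_frames)
            accepted, _ = filter_tracks(tracks, trk)
            freq[i, j] = patch_frequency(len(accepted), mask.area_um2, movie.duration_min)
    return freq


def replace_detection(params: DetectionParams, **kw) -> DetectionParams:
    return replace(params, **kw)


def replace_tracking(params: TrackingParams, **kw) -> TrackingParams:
    return replace(params, **kw)


def sweep_percent_difference(freq_control: np.ndarray, freq_test: np.ndarray) -> np.ndarray:
    """Cellwise percent difference between paired sweep matrices."""
    if freq_control.shape != freq_test.shape:
        raise ValueError("sweep matrices must have the same shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        return 100.0 * (freq_test / freq_control - 1.0)
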