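"""Tracking-free dynamics statistic: per-pixel coefficient of variation.

For every masked pixel the temporal CoV (population SD over time divided
by mean over time) summarizes how strongly intensity fluctuates relative
to its level; transient patches raise it, static structure does not.  Two
classic histogram auto-thresholds — Li's minimum cross-entropy and Tsai's
moment-preserving cut — split the pooled CoV values of a movie into
"highly variant" and quiet pixels, giving a variant-area fraction that is
insensitive to global intensity scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Mask, Movie

logger = logging.getLogger("patchdyn")


@dataclass(frozen=True)
class CoVResult:
    """Per-pixel CoV map (zero outside the mask) and summary statistics."""

    cov_map: np.ndarray
    mask: Mask
    mean_cov: float
    n_invalid: int  # masked pixels with non-positive temporal mean

    @property
    def masked_values(self) -> np.ndarray:
        return self.cov_map[self.mask.pixels]


def cov_map(movie: Movie, mask: Mask) -> CoVResult:
    """Temporal CoV (population SD / mean) for every masked pixel.

    Pixels whose temporal mean is <= 0 get CoV 0 and are flagged; they are
    excluded from ``mean_cov``.
    """
    mask.require_nonempty()
    if movie.frame_shape != mask.pixels.shape:
        raise ValueError("movie and mask shapes differ")
    traces = movie.data[:, mask.pixels]  # (T, N)
    mean = traces.mean(axis=0)
    sd = traces.std(axis=0)  # population (ddof=0) by contract
    valid = mean > 0
    cov = np.zeros_like(mean)
    cov[valid] = sd[valid] / mean[valid]
    full = np.zeros(mask.pixels.shape, dtype=float)
    full[mask.pixels] = cov
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.debug("%d masked pixels had non-positive temporal mean", n_invalid)
    mean_cov = float(cov[valid].mean()) if valid.any() else 0.0
    return CoVResult(full, mask, mean_cov, n_invalid)


# ---------------------------------------------------------------------------
# Histogram auto-thresholds
# ---------------------------------------------------------------------------


def _histogram(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray, float]:
    """256-bin histogram over the data range, shifted so values start at 0.

    Returns (counts, bin centers of the shifted data, offset to add back).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        raise ValueError("all values identical; threshold undefined")
    shifted = values - vmin
    counts, edges = np.histogram(shifted, bins=n_bins, range=(0.0, vmax - vmin))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers, vmin


def threshold_li(values: np.ndarray, n_bins: int = 256, max_iter: int = 200) -> float:
    """Li & Lee minimum cross-entropy threshold.

    Operates on an ``n_bins``-bin histogram spanning the data range (data
    shifted to start at 0, so the log-means are well defined).  The
    cross-entropy criterion is scanned over every cut point to locate the
    global minimum basin — the Li–Tam fixed-point iteration alone can stall
    in a secondary minimum on multimodal histograms — and the iteration
    ``t' = (mu_below - mu_above) / (ln mu_below - ln mu_above)`` then
    refines the cut to sub-bin precision.  Returned in data units.
    """
    counts, centers, offset = _histogram(values, n_bins)
    bw = centers[1] - centers[0]
    tol = bw * 1e-3
    # exhaustive criterion scan over the cut points
    S = counts * centers
    cum_w = np.cumsum(counts)
    cum_s = np.cumsum(S)
    total_w, total_s = cum_w[-1], cum_s[-1]
    wb, sb = cum_w[:-1], cum_s[:-1]
    wf, sf = total_w - wb, total_s - sb
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_b = np.where(wb > 0, sb / np.maximum(wb, 1), np.nan)
        mu_f = np.where(wf > 0, sf / np.maximum(wf, 1), np.nan)
        eta = -(sb * np.log(mu_b) + sf * np.log(mu_f))
    eta[~np.isfinite(eta)] = np.inf
    # empty bins between modes make the criterion exactly flat there; take
    # the middle of the minimal plateau as the deterministic cut
    eta_min = eta.min()
    plateau = np.flatnonzero(eta <= eta_min + 1e-9 * abs(eta_min) + 1e-300)
    t_scan = float(centers[int(np.median(plateau))] + bw / 2.0)
    t = t_scan
    for _ in range(max_iter):
        below = centers <= t
        wb, wf = counts[below].sum(), counts[~below].sum()
        if wb == 0 or wf == 0:
            # all mass on one side: nudge toward the interior
            t = float(np.clip(t, centers[1], centers[-2]))
            below = centers <= t
            wb, wf = counts[below].sum(), counts[~below].sum()
            if wb == 0 or wf == 0:
                break
        mu_b = (counts[below] * centers[below]).sum() / wb
        mu_f = (counts[~below] * centers[~below]).sum() / wf
        if mu_b <= 0:
            mu_b = bw / 2.0
        t_new = (mu_b - mu_f) / (np.log(mu_b) - np.log(mu_f))
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    # the fixed-point map can jump to a secondary basin on multimodal
    # histograms; keep its sub-bin refinement only if it stayed local
    if abs(t - t_scan) > bw:
        t = t_scan
    return float(t + offset)


def threshold_moments(values: np.ndarray, n_bins: int = 256) -> float:
    """Tsai moment-preserving threshold.

    Finds the binary split whose two representative levels and mixing
    fraction preserve the first three moments of the histogram (closed-form
    quadratic), then converts the preserved fraction to a cut point by a
    cumulative-histogram percentile lookup.  Returned in data units.
    """
    counts, centers, offset = _histogram(values, n_bins)
    p = counts / counts.sum()
    m1 = float((p * centers).sum())
    m2 = float((p * centers**2).sum())
    m3 = float((p * centers**3).sum())
    cd = m2 - m1 * m1
    if cd <= 1e-15 * max(m2, 1.0):
        raise ValueError("degenerate histogram: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise ValueError("degenerate histogram: moment equations have no real roots")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate histogram: coincident representative levels")
    p0 = (z1 - m1) / (z1 - z0)
    cdf = np.cumsum(p)
    idx = int(np.searchsorted(cdf, p0))
    idx = min(idx, len(centers) - 1)
    return float(centers[idx] + offset)


_THRESHOLDS = {"li": threshold_li, "moments": threshold_moments}


def variant_area_fraction(result: CoVResult, method: str = "li", n_bins: int = 256) -> float:
    """Fraction of masked pixels whose CoV exceeds the auto-threshold."""
    if method not in _THRESHOLDS:
        raise ValueError(f"unknown threshold method {method!r}")
    vals = result.masked_values
    thr = _THRESHOLDS[method](vals, n_bins=n_bins)
    return float((vals > thr).mean())


def cov_summary(movie: Movie, mask: Mask, n_bins: int = 256) -> dict:
    """CoV map plus both variant-area fractions, as a JSON-friendly dict."""
    result = cov_map(movie, mask)
    return {
        "mean_cov": result.mean_cov,
        "n_masked_pixels": mask.n_pixels,
        "n_invalid_pixels": result.n_invalid,
        "variant_fraction_li": variant_area_fraction(result, "li", n_bins),
        "variant_fraction_moments": variant_area_fraction(result, "moments", n_bins),
    }
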