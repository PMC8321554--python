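"""Registration, background subtraction, and presynaptic mask generation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import filters, measure
from skimage.registration import phase_cross_correlation
from skimage.restoration import rolling_ball

from .core import Mask, Movie
from .cov import threshold_li, threshold_moments

logger = logging.getLogger("patchdyn")


@dataclass(frozen=True)
class RegistrationResult:
    shifts: np.ndarray  # (n_frames, 2) of (dy, dx) in pixels; frame 0 = (0, 0)
    movie: Movie


def register_translation(
    movie: Movie, max_shift_px: float = 10.0, upsample: int = 20
) -> RegistrationResult:
    """Translation-only registration of every frame to the first.

    Shifts are estimated by upsampled cross-correlation (integer peak then
    sub-pixel refinement), clamped at ``max_shift_px`` with a warning, and
    applied by linear interpolation with out-of-field pixels filled by the
    frame median.  The specimen is assumed rigid; no rotation/affine.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to register")
    ref = movie.data[0]
    shifts = np.zeros((movie.n_frames, 2))
    out = np.empty_like(movie.data)
    out[0] = ref
    for t in range(1, movie.n_frames):
        frame = movie.data[t]
        if np.array_equal(frame, ref):
            out[t] = frame
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample, normalization=None
        )
        if np.any(np.abs(shift) > max_shift_px):
            logger.warning(
                "frame %d shift %s exceeds max_shift_px=%g; clamping", t, shift, max_shift_px
            )
            shift = np.clip(shift, -max_shift_px, max_shift_px)
        shifts[t] = shift
        out[t] = ndi.shift(frame, shift, order=1, mode="constant", cval=float(np.median(frame)))
    registered = Movie(np.clip(out, 0.0, None), movie.pixel_size_um, movie.frame_interval_s)
    return RegistrationResult(shifts, registered)


def rolling_ball_subtract(image: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction of a 2-D image.

    The background is the surface traced by a ball of the given radius
    rolled under the intensity landscape; features much smaller than the
    ball are preserved, flat regions go to ~0, and the output never exceeds
    the input.  Output is floored at 0.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("rolling_ball_subtract expects a 2-D image")
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    background = rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0.0, None)


def subtract_movie_background(movie: Movie, radius_px: int = 50) -> Movie:
    """Per-frame rolling-ball subtraction of a whole movie."""
    data = np.stack([rolling_ball_subtract(f, radius_px) for f in movie.data])
    return Movie(data, movie.pixel_size_um, movie.frame_interval_s)


def make_presynaptic_mask(
    movie: Movie,
    blur_sigma_px: float = 2.0,
    method: str = "otsu",
    keep_largest: bool = False,
) -> Mask:
    """Threshold the blurred time-max projection into a presynaptic mask.

    The mask is computed once from the maximum-over-time projection so that
    transient patches cannot move it; the frequency normalization needs one
    stable area per movie.  ``method`` is one of ``otsu``, ``li``,
    ``moments`` or ``fixed:<value>``.
    """
    proj = movie.data.max(axis=0)
    smooth = ndi.gaussian_filter(proj, blur_sigma_px) if blur_sigma_px > 0 else proj
    if smooth.min() == smooth.max() and not method.startswith("fixed:"):
        raise ValueError("empty mask: projection is constant, nothing to threshold")
    if method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    elif method == "otsu":
        thr = filters.threshold_otsu(smooth)
    elif method == "li":
        thr = threshold_li(smooth.ravel())
    elif method == "moments":
        thr = threshold_moments(smooth.ravel())
    else:
        raise ValueError(f"unknown mask method {method!r}")
    pixels = smooth > thr
    if not pixels.any():
        raise ValueError("empty mask after thresholding")
    if keep_largest:
        labels = measure.label(pixels)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        pixels = labels == counts.argmax()
    return Mask(pixels, movie.pixel_size_um)
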