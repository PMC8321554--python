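"""Masked Pearson colocalization and FRAP double-normalization / recovery fitting."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger("patchdyn")


def pearson_colocalization(channel_a: np.ndarray, channel_b: np.ndarray, mask) -> float:
    """Pearson correlation of voxel intensities within a (2-D or 3-D) mask.

    Background subtraction (rolling ball) is expected upstream.  Invariant
    under independent affine intensity transforms of each channel.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != m.shape:
        raise ValueError("channel and mask shapes must match")
    if not m.any():
        raise ValueError("mask is empty")
    va, vb = a[m], b[m]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance within mask")
    return float(np.corrcoef(va, vb)[0, 1])


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapTrace:
    """Raw ROI intensity traces for one bleach experiment."""

    times_s: np.ndarray
    bleach: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_frame_index: int

    def __post_init__(self) -> None:
        arrays = {
            "times_s": self.times_s,
            "bleach": self.bleach,
            "reference": self.reference,
            "background": self.background,
        }
        n = len(self.times_s)
        for name, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            object.__setattr__(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
        if self.bleach_frame_index < 1:
            raise ValueError("need at least one prebleach frame")
        if np.mean(self.reference - self.background) <= 0:
            raise ValueError("reference must exceed background on average")

    @classmethod
    def from_csv(cls, path, bleach_frame_index: int) -> "FrapTrace":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["bleach"].to_numpy(),
            df["reference"].to_numpy(),
            df["background"].to_numpy(),
            bleach_frame_index,
        )


def frap_normalize(trace: FrapTrace) -> np.ndarray:
    """Double normalization of the bleached ROI.

    ``r(t) = (bleach - bg) / (reference - bg)`` cancels imaging-induced
    photobleaching shared by the two ROIs; dividing by the prebleach mean
    of ``r`` scales the prebleach level to ~1.
    """
    denom = trace.reference - trace.background
    if np.any(denom <= 0):
        raise ValueError("reference - background must be positive at every frame")
    r = (trace.bleach - trace.background) / denom
    pre = r[: trace.bleach_frame_index].mean()
    if pre <= 0:
        raise ValueError("non-positive prebleach level")
    return r / pre


@dataclass(frozen=True)
class FrapFit:
    """Single-exponential recovery fit of a normalized FRAP curve."""

    tau_s: float
    mobile_fraction: float
    plateau: float
    n0: float
    residual_rms: float
    flagged: bool
    message: str = ""


def _recovery(t, n0, plateau, tau):
    return n0 + (plateau - n0) * (1.0 - np.exp(-t / tau))


def frap_fit(
    times_s: np.ndarray,
    normalized: np.ndarray,
    bleach_frame_index: int,
    model: str = "single",
) -> FrapFit:
    """Least-squares fit of ``N(t) = N0 + (M - N0)(1 - exp(-(t - t0)/tau))``.

    Fitted on postbleach points only; ``mobile_fraction = (M - N0)/(1 - N0)``
    with the prebleach level normalized to 1.  Unidentifiable or at-bound
    fits are flagged rather than silently returned.
    """
    if model != "single":
        raise NotImplementedError("only the single-exponential model is implemented")
    times_s = np.asarray(times_s, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    post_t = times_s[bleach_frame_index:] - times_s[bleach_frame_index]
    post_n = normalized[bleach_frame_index:]
    if len(post_t) < 10:
        raise ValueError("need >= 10 postbleach points")
    n0_guess = float(post_n[0])
    m_guess = float(post_n[-5:].mean())
    span = max(post_t[-1], 1e-6)
    flagged = False
    message = ""
    if m_guess - n0_guess < 1e-6:
        # no recovery: tau unidentifiable
        return FrapFit(
            tau_s=float("nan"),
            mobile_fraction=0.0,
            plateau=m_guess,
            n0=n0_guess,
            residual_rms=float(np.sqrt(np.mean((post_n - post_n.mean()) ** 2))),
            flagged=True,
            message="no recovery detected; tau unidentifiable",
        )
    tau_guess = max(span / 5.0, 1e-3)
    bounds = ([-0.5, -0.5, 1e-6], [2.0, 2.0, 100.0 * span])
    try:
        popt, _ = curve_fit(
            _recovery,
            post_t,
            post_n,
            p0=[n0_guess, m_guess, tau_guess],
            bounds=bounds,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"FRAP fit failed: {exc}") from exc
    n0, plateau, tau = (float(v) for v in popt)
    if tau >= 0.99 * 100.0 * span or tau <= 1.01e-6:
        flagged = True
        message = "tau at bound"
    if n0 >= 1.0 - 1e-9:
        flagged = True
        message = (message + "; " if message else "") + "no bleach depth"
        mobile = float("nan")
    else:
        mobile = (plateau - n0) / (1.0 - n0)
    resid = post_n - _recovery(post_t, *popt)
    return FrapFit(
        tau_s=tau,
        mobile_fraction=mobile,
        plateau=plateau,
        n0=n0,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        flagged=flagged,
        message=message,
    )
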