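"""Intensity-based measurements: line profiles, two-ROI centriole ratio,
and FRAP normalization and fitting.

The line profile reproduces a Fiji-style plot profile along the centriolar
axis with tail normalization; the centrosome intensity ratio compares two
0.35-um circular ROIs centered on the centrioles in a summed z-projection,
always dividing by the larger value; FRAP curves are background-subtracted,
normalized to an unbleached in-cell reference, and optionally fit with a
single-exponential recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "LineProfile",
    "FrapCurve",
    "FrapFitError",
    "line_profile",
    "normalize_profile",
    "centrosome_intensity_ratio",
    "frap_normalize",
    "frap_halftime",
]


class FrapFitError(RuntimeError):
    """Raised when the FRAP recovery fit cannot converge."""


@dataclass
class LineProfile:
    """Fluorescence profile along a straight segment.

    ``positions`` are micrometers along the line (strictly increasing,
    spanning its length); ``normalized`` is filled by
    :func:`normalize_profile`.
    """

    positions: np.ndarray
    raw: np.ndarray
    normalized: Optional[np.ndarray] = None


@dataclass
class FrapCurve:
    """A normalized FRAP recovery curve; pre-bleach mean is 1 by construction."""

    times: np.ndarray  # s
    raw_bleached: np.ndarray
    raw_reference: np.ndarray
    background: float
    normalized: np.ndarray
    bleach_frame: int  # index of the first post-bleach sample


def line_profile(
    image: np.ndarray,
    point_a: Sequence[float],
    point_b: Sequence[float],
    pixel_size: float,
    step: float = 0.1,
    expected_length: Optional[float] = None,
    length_tol: float = 0.05,
) -> LineProfile:
    """Bilinear intensity profile from A to B (um coordinates, um step)."""
    a = np.asarray(point_a, dtype=float)
    b = np.asarray(point_b, dtype=float)
    length = float(np.linalg.norm(b - a))
    if length <= 0:
        raise ValueError("endpoints coincide")
    if expected_length is not None and abs(length - expected_length) > length_tol * expected_length:
        raise ValueError(
            f"segment length {length:.3f} um differs from expected {expected_length} um"
        )
    n = int(round(length / step)) + 1
    s = np.linspace(0.0, length, n)
    pts = a[None, :] + (b - a)[None, :] * (s / length)[:, None]
    cols = pts[:, 0] / pixel_size
    rows = pts[:, 1] / pixel_size
    h, w = image.shape
    if (rows.min() < 0) or (rows.max() > h - 1) or (cols.min() < 0) or (cols.max() > w - 1):
        raise ValueError("profile line exits image bounds")
    vals = ndimage.map_coordinates(
        np.asarray(image, dtype=float), np.vstack([rows, cols]), order=1
    )
    return LineProfile(positions=s, raw=vals)


def normalize_profile(
    profile: LineProfile, tail_count: int = 4, pooled: bool = True
) -> LineProfile:
    """Normalize a profile to its flank intensity.

    Default: divide by the single pooled mean of the first and last
    ``tail_count`` raw samples. With ``pooled=False`` each half of the
    profile is divided by its own end's tail mean instead.
    """
    raw = np.asarray(profile.raw, dtype=float)
    if len(raw) < 2 * tail_count:
        raise ValueError(
            f"profile has {len(raw)} samples; need >= {2 * tail_count} for "
            f"tail_count={tail_count}"
        )
    head = raw[:tail_count]
    tail = raw[-tail_count:]
    if pooled:
        denom = float(np.concatenate([head, tail]).mean())
        if denom <= 0:
            raise ValueError("pooled tail mean is not positive")
        norm = raw / denom
    else:
        d1, d2 = float(head.mean()), float(tail.mean())
        if d1 <= 0 or d2 <= 0:
            raise ValueError("tail mean is not positive")
        half = len(raw) // 2
        norm = np.concatenate([raw[:half] / d1, raw[half:] / d2])
    return LineProfile(positions=profile.positions, raw=raw, normalized=norm)


def _roi_mean(image: np.ndarray, center: Sequence[float], radius: float, pixel_size: float):
    """Mean over pixels whose centers lie within radius (um) of center (um)."""
    h, w = image.shape
    cx, cy = center
    r_px = radius / pixel_size
    cx_px, cy_px = cx / pixel_size, cy / pixel_size
    if (
        cx_px - r_px < -0.5
        or cy_px - r_px < -0.5
        or cx_px + r_px > w - 0.5
        or cy_px + r_px > h - 0.5
    ):
        raise ValueError("ROI extends outside the image")
    rr, cc = np.mgrid[0:h, 0:w]
    member = (cc - cx_px) ** 2 + (rr - cy_px) ** 2 <= r_px**2
    if not member.any():
        raise ValueError("ROI contains no pixel centers; radius under-sampled")
    return float(image[member].mean()), member


def centrosome_intensity_ratio(
    image: np.ndarray,
    center1: Sequence[float],
    center2: Sequence[float],
    pixel_size: float,
    roi_radius: float = 0.35,
) -> float:
    """Intactness ratio of a centriole pair from a summed z-projection.

    Mean intensities of two circular ROIs (default radius 0.35 um) centered
    on the two centrioles; the ratio takes the higher value as divisor, so
    it lies in (0, 1] and 1 means equal signal on both centrioles.
    """
    if roi_radius <= 0:
        raise ValueError("roi_radius must be > 0")
    img = np.asarray(image, dtype=float)
    m1, mask1 = _roi_mean(img, center1, roi_radius, pixel_size)
    m2, mask2 = _roi_mean(img, center2, roi_radius, pixel_size)
    if (mask1 & mask2).any():
        warnings.warn("centriole ROIs overlap", stacklevel=2)
    lo, hi = min(m1, m2), max(m1, m2)
    if lo <= 0:
        raise ValueError("an ROI has nonpositive mean intensity")
    return lo / hi


def frap_normalize(
    bleached: Sequence[float],
    reference: Sequence[float],
    background: float,
    pre_bleach_count: int = 5,
    times: Optional[Sequence[float]] = None,
) -> FrapCurve:
    """Background-subtract and reference-normalize a FRAP recovery.

    value(t) = (bleached(t) - background) / (reference(t) - background),
    rescaled so the pre-bleach mean equals 1.
    """
    b = np.asarray(bleached, dtype=float)
    r = np.asarray(reference, dtype=float)
    if b.shape != r.shape:
        raise ValueError("bleached and reference series differ in length")
    if pre_bleach_count < 1 or pre_bleach_count >= len(b):
        raise ValueError("pre_bleach_count must be >= 1 and < series length")
    ref_corr = r - background
    if np.any(ref_corr <= 0):
        raise ValueError("reference does not exceed background at every frame")
    vals = (b - background) / ref_corr
    pre = vals[:pre_bleach_count].mean()
    if pre <= 0:
        raise ValueError("pre-bleach corrected signal is not positive")
    vals = vals / pre
    if times is None:
        times = np.arange(len(b), dtype=float)
    return FrapCurve(
        times=np.asarray(times, dtype=float),
        raw_bleached=b,
        raw_reference=r,
        background=background,
        normalized=vals,
        bleach_frame=pre_bleach_count,
    )


def frap_halftime(curve: FrapCurve, min_post: int = 10) -> tuple[float, float]:
    """(recovery half-time s, mobile fraction) from a single-exponential fit.

    Fits f(t) = plateau - (plateau - f0) exp(-k t) to the post-bleach
    samples; the half-time is ln(2)/k and the mobile fraction
    (plateau - f0) / (1 - f0), where f0 is the fitted value at the bleach.
    A flat curve returns (nan, 0); a non-recovering (decreasing) curve
    raises :class:`FrapFitError`.
    """
    post = curve.normalized[curve.bleach_frame :]
    t = curve.times[curve.bleach_frame :]
    if len(post) < min_post:
        raise ValueError(f"need >= {min_post} post-bleach frames, got {len(post)}")
    t = t - t[0]
    f0_obs = post[0]
    if np.ptp(post) < 1e-6:
        return float("nan"), 0.0

    def model(tt, plateau, f0, k):
        return plateau - (plateau - f0) * np.exp(-k * tt)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model,
                t,
                post,
                p0=(post[-5:].mean(), f0_obs, np.log(2) / max(t[-1] / 4, 1e-6)),
                maxfev=10000,
            )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FrapFitError(f"recovery fit failed: {exc}") from exc
    plateau, f0, k = popt
    if k <= 0 or plateau < f0:
        raise FrapFitError("fitted curve does not recover (rate <= 0 or decreasing)")
    if f0 >= 1:
        raise FrapFitError("fitted bleach depth not below pre-bleach level")
    half_time = float(np.log(2) / k)
    mobile = float((plateau - f0) / (1 - f0))
    return half_time, mobile
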