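"""Synthetic calibrated movies with exact ground truth.

Every generator is a pure function of its parameters and a seed, and the
ground truth it returns is sufficient to score the downstream stage without
touching pixels. The generators emulate the imaging conditions of the
migrating-cell experiments the analysis was designed for: centriole pairs
imaged as diffraction-limited GFP puncta ~0.5-1 um apart that fracture at
rates of order um/min, linear front-back polarity gradients, FRAP series
with five 1-s pre-bleach frames, bulk-drifting collagen textures, and
vessel/cell proximity scenes at a 142.6-nm pixel size.

Conventions: positions are (x, y) in micrometers with x = column index *
pixel_size and y = row index * pixel_size; image arrays are indexed
[frame, row, col].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io import CalibratedMovie

__all__ = [
    "GroundTruth",
    "make_centriole_movie",
    "make_polarity_movie",
    "make_frap_series",
    "make_drift_sequence",
    "make_vessel_image",
    "polarity_bin_ratios",
]

#: imaging defaults shared by the generators
DEFAULT_PIXEL_SIZE = 0.1426  # um/px
DEFAULT_PSF_SIGMA = 0.2  # um, isotropic 2D Gaussian PSF
DEFAULT_FRAME_INTERVAL = 6.0  # s


@dataclass
class GroundTruth:
    """Oracle container: the scripted truth behind one synthetic dataset."""

    seed: Optional[int] = None
    # centriole movies
    positions_a: Optional[np.ndarray] = None  # (frames, 2) um
    positions_b: Optional[np.ndarray] = None
    distances: Optional[np.ndarray] = None  # (frames,) um
    fracture_onset: Optional[int] = None  # frame index
    separation_rate: Optional[float] = None  # um/min
    repair_frame: Optional[int] = None
    # drift sequences
    drift: Optional[np.ndarray] = None  # (frames-1, 2) px, (dx, dy)
    drift_um: Optional[np.ndarray] = None
    # polarity movies
    front_back_ratio: Optional[float] = None
    bin_ratios: Optional[np.ndarray] = None
    # FRAP
    mobile_fraction: Optional[float] = None
    half_time: Optional[float] = None
    background: Optional[float] = None
    bleach_frame: Optional[int] = None
    roi_bleach: Optional[tuple] = None  # (center_xy_um, radius_um)
    roi_reference: Optional[tuple] = None
    # vessels
    vessel_mask: Optional[np.ndarray] = None
    cell_positions: Optional[np.ndarray] = None  # (n, 2) um
    cell_distances: Optional[np.ndarray] = None  # (n,) um
    cell_inside: Optional[np.ndarray] = None  # (n,) bool

    def __post_init__(self) -> None:
        if self.distances is not None and np.any(np.asarray(self.distances) < 0):
            raise ValueError("ground-truth distances must be nonnegative")


def _render_spots(shape, centers_px, amplitude, sigma_px):
    """Noiseless image of Gaussian puncta at sub-pixel centers (col, row)."""
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    rad = int(np.ceil(6 * sigma_px))
    for cx, cy in centers_px:
        r0, r1 = int(np.floor(cy)) - rad, int(np.floor(cy)) + rad + 1
        c0, c1 = int(np.floor(cx)) - rad, int(np.floor(cx)) + rad + 1
        r0, r1 = max(r0, 0), min(r1, h)
        c0, c1 = max(c0, 0), min(c1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((cc - cx) ** 2 + (rr - cy) ** 2) / (2 * sigma_px**2)
        )
    return img


def _apply_noise(clean, snr, background, rng):
    """Poisson shot noise on (signal + background) plus Gaussian read noise.

    SNR is defined as peak signal amplitude over read-noise sigma.
    """
    if snr is None:
        return clean + background
    if snr <= 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    peak = clean.max() if clean.max() > 0 else 1.0
    read_sigma = peak / snr
    noisy = rng.poisson(clean + background).astype(float)
    noisy += rng.normal(0.0, read_sigma, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def make_centriole_movie(
    n_frames: int = 40,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    cohesive_distance: float = 0.8,
    fracture: Optional[tuple] = None,
    psf_sigma: float = DEFAULT_PSF_SIGMA,
    snr: Optional[float] = 10.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    amplitude: float = 200.0,
    background: float = 10.0,
    jitter_sd: float = 0.0,
    wander_sd: float = 0.0,
    orientation: Optional[float] = None,
) -> tuple[CalibratedMovie, GroundTruth]:
    """Two-punctum centriole movie with optionally scripted fracture.

    The inter-centriole distance is ``cohesive_distance`` before the fracture
    onset (cohesion at the observed 0.5-1 um scale), grows linearly at the
    scripted rate (um/min) after onset, and shrinks back at the same rate
    after the repair frame, if one is given. ``fracture`` is
    ``(onset_frame, rate_um_per_min, repair_frame_or_None)``.

    ``jitter_sd`` adds Gaussian jitter to the distance, ``wander_sd`` a
    random walk of the pair midpoint (both um per frame). Pass ``snr=None``
    for a noiseless movie.
    """
    if cohesive_distance < 0:
        raise ValueError("cohesive_distance must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    center = np.array([w / 2 * pixel_size, h / 2 * pixel_size])
    theta = rng.uniform(0, 2 * np.pi) if orientation is None else float(orientation)
    u = np.array([np.cos(theta), np.sin(theta)])

    onset = rate = repair = None
    if fracture is not None:
        onset, rate, repair = fracture
        if rate <= 0:
            raise ValueError("separation rate must be > 0")

    dt_min = frame_interval / 60.0
    dist = np.full(n_frames, float(cohesive_distance))
    if onset is not None:
        for t in range(n_frames):
            if t <= onset:
                continue
            if repair is not None and t > repair:
                peak = cohesive_distance + rate * (repair - onset) * dt_min
                d = peak - rate * (t - repair) * dt_min
            else:
                d = cohesive_distance + rate * (t - onset) * dt_min
            dist[t] = max(d, cohesive_distance)
    if jitter_sd > 0:
        dist = np.clip(dist + rng.normal(0, jitter_sd, n_frames), 0.0, None)

    mid = np.tile(center, (n_frames, 1))
    if wander_sd > 0:
        steps = rng.normal(0, wander_sd, (n_frames, 2))
        steps[0] = 0
        mid = mid + np.cumsum(steps, axis=0)

    pos_a = mid + 0.5 * dist[:, None] * u
    pos_b = mid - 0.5 * dist[:, None] * u
    lim = np.array([w * pixel_size, h * pixel_size])
    margin = 4 * psf_sigma
    for p in (pos_a, pos_b):
        if np.any(p < margin) or np.any(p > lim - margin):
            raise ValueError("puncta leave the field of view; enlarge shape")

    sigma_px = psf_sigma / pixel_size
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        centers_px = [tuple(pos_a[t] / pixel_size), tuple(pos_b[t] / pixel_size)]
        clean = _render_spots((h, w), centers_px, amplitude, sigma_px)
        frames[t] = _apply_noise(clean, snr, background, rng)

    movie = CalibratedMovie(
        channels={"centriole": frames},
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )
    truth = GroundTruth(
        seed=seed,
        positions_a=pos_a,
        positions_b=pos_b,
        distances=np.linalg.norm(pos_a - pos_b, axis=1),
        fracture_onset=onset,
        separation_rate=rate,
        repair_frame=repair,
    )
    return movie, truth


def polarity_bin_ratios(ratio: float, n_bins: int) -> np.ndarray:
    """Closed-form bin ratios of a linear front/back intensity ramp.

    For reporter I(s) = a + (b - a) s with b/a = ``ratio`` on s in [0, 1]
    (uniform pixel density, uniform reference), normalizing each channel by
    its whole-cell mean gives bin k of n the value
    ``(1 + (r - 1) (2k + 1) / (2n)) * 2 / (1 + r)``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    k = np.arange(n_bins)
    mid = (2 * k + 1) / (2 * n_bins)
    return (1 + (ratio - 1) * mid) * 2 / (1 + ratio)


def make_polarity_movie(
    n_frames: int = 8,
    gradient_ratio: float = 2.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = 300.0,
    shape: tuple[int, int] = (96, 64),
    cell_size_px: tuple[int, int] = (60, 36),
    step_px: float = 2.0,
    centriole_layout: Optional[Sequence[tuple[float, float]]] = (),
    noise_sd: float = 0.0,
    n_bins: int = 50,
    seed: int = 0,
) -> tuple[CalibratedMovie, GroundTruth, np.ndarray]:
    """Migrating rectangular cell with a linear polarity-reporter ramp.

    The cell (an axis-aligned ``cell_size_px`` rectangle, so the projection
    density along the migration axis is uniform and the bin ratios have an
    exact closed form) translates toward +y by ``step_px`` per frame. The
    polarity channel ramps linearly from back to front with the requested
    front/back intensity ratio; the reference channel is uniform inside the
    mask. ``centriole_layout`` gives per-cell centriole offsets (um) from the
    cell center, rendered as puncta in the reference channel.

    Returns (movie, truth, masks) where ``masks`` is the (frames, h, w)
    boolean cell mask stack and ``truth.bin_ratios`` the closed-form
    ``n_bins`` profile.
    """
    if gradient_ratio <= 0:
        raise ValueError("gradient_ratio must be > 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    ch, cw = cell_size_px
    if ch >= h - n_frames * step_px or cw >= w:
        raise ValueError("cell does not fit in the field over the trajectory")

    a = 100.0  # back intensity; front = a * ratio
    b = a * gradient_ratio
    ref_level = 120.0

    masks = np.zeros((n_frames, h, w), dtype=bool)
    reporter = np.zeros((n_frames, h, w))
    reference = np.zeros((n_frames, h, w))
    rows = np.arange(h)
    for t in range(n_frames):
        top = int(round(2 + t * step_px))
        bottom = top + ch
        if bottom >= h:
            raise ValueError("mask empty or out of field")
        c0 = (w - cw) // 2
        masks[t, top:bottom, c0 : c0 + cw] = True
        # migration toward +y: rear = smallest y (row top)
        s = (rows[top:bottom] - top) / (ch - 1)
        ramp = a + (b - a) * s
        reporter[t, top:bottom, c0 : c0 + cw] = ramp[:, None]
        reference[t, top:bottom, c0 : c0 + cw] = ref_level
        if centriole_layout:
            cx = (c0 + cw / 2) * pixel_size
            cy = (top + ch / 2) * pixel_size
            pts = [((cx + dx) / pixel_size, (cy + dy) / pixel_size)
                   for dx, dy in centriole_layout]
            reference[t] += _render_spots((h, w), pts, 4 * ref_level, 0.2 / pixel_size)
    if not masks.any():
        raise ValueError("mask empty")
    if noise_sd > 0:
        reporter = np.clip(reporter + rng.normal(0, noise_sd, reporter.shape), 0, None)
        reference = np.clip(reference + rng.normal(0, noise_sd, reference.shape), 0, None)

    movie = CalibratedMovie(
        channels={"polarity": reporter, "reference": reference},
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )
    truth = GroundTruth(
        seed=seed,
        front_back_ratio=gradient_ratio,
        bin_ratios=polarity_bin_ratios(gradient_ratio, n_bins),
    )
    return movie, truth, masks


def make_frap_series(
    pre_frames: int = 5,
    background: float = 10.0,
    reference_level: float = 110.0,
    bleach_depth: float = 0.0,
    mobile_fraction: float = 0.66,
    half_time: float = 20.0,
    n_post: int = 60,
    frame_interval: float = 1.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] = (48, 96),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CalibratedMovie, GroundTruth]:
    """FRAP movie: a bleached and a reference ROI on flat background.

    Five 1-s pre-bleach frames by default. After the bleach the
    background-corrected, reference-normalized ROI mean follows
    ``f0 + m (1 - f0) (1 - 2^(-t/t_half))`` with ``f0 = bleach_depth`` and
    ``m = mobile_fraction``; the reference ROI stays at ``reference_level``.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if not 0.0 <= bleach_depth < 1.0:
        raise ValueError("bleach_depth must be in [0, 1)")
    if pre_frames < 1 or half_time <= 0:
        raise ValueError("pre_frames >= 1 and half_time > 0 required")
    rng = np.random.default_rng(seed)
    h, w = shape
    n_frames = pre_frames + n_post
    t_post = np.arange(n_post) * frame_interval
    f0, m = bleach_depth, mobile_fraction
    recovery = f0 + m * (1 - f0) * (1 - 0.5 ** (t_post / half_time))
    norm = np.concatenate([np.ones(pre_frames), recovery])

    radius_px = max(4, h // 6)
    roi_bleach_px = (w // 4, h // 2)
    roi_ref_px = (3 * w // 4, h // 2)
    rr, cc = np.mgrid[0:h, 0:w]
    in_bleach = (cc - roi_bleach_px[0]) ** 2 + (rr - roi_bleach_px[1]) ** 2 <= radius_px**2
    in_ref = (cc - roi_ref_px[0]) ** 2 + (rr - roi_ref_px[1]) ** 2 <= radius_px**2

    frames = np.full((n_frames, h, w), background, dtype=float)
    signal = reference_level - background
    for t in range(n_frames):
        frames[t][in_ref] = reference_level
        frames[t][in_bleach] = background + signal * norm[t]
    if noise_sd > 0:
        frames = np.clip(frames + rng.normal(0, noise_sd, frames.shape), 0, None)

    movie = CalibratedMovie(
        channels={"frap": frames},
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )
    um = pixel_size
    truth = GroundTruth(
        seed=seed,
        mobile_fraction=mobile_fraction,
        half_time=half_time,
        background=background,
        bleach_frame=pre_frames,
        roi_bleach=((roi_bleach_px[0] * um, roi_bleach_px[1] * um), radius_px * um),
        roi_reference=((roi_ref_px[0] * um, roi_ref_px[1] * um), radius_px * um),
    )
    return movie, truth


def make_drift_sequence(
    n_frames: int = 10,
    shifts: Optional[np.ndarray] = None,
    texture_density: float = 0.01,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 1.0,
    frame_interval: float = 30.0,
    noise_sd: float = 0.0,
    search_radius: int = 25,
    seed: int = 0,
    source_axis: str = "+y",
) -> tuple[CalibratedMovie, GroundTruth]:
    """Drifting random-blob texture with exactly scripted displacement.

    ``shifts`` is an (n_frames - 1, 2) array of per-frame-pair (dx, dy) in
    pixels (subpixel allowed); frame t equals frame t-1 translated by
    ``shifts[t-1]``. Rendered by sampling a moving window of one large
    static texture, so integer shifts are exact crops.
    """
    rng = np.random.default_rng(seed)
    if shifts is None:
        shifts = np.zeros((n_frames - 1, 2))
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (n_frames - 1, 2):
        raise ValueError(f"shifts must have shape {(n_frames - 1, 2)}")
    if np.any(np.abs(shifts) > search_radius):
        raise ValueError("scripted shift exceeds the declared search radius")
    h, w = shape
    cum = np.vstack([np.zeros(2), np.cumsum(shifts, axis=0)])  # (n_frames, 2)
    span = int(np.ceil(np.abs(cum).max())) + 2
    bh, bw = h + 2 * span, w + 2 * span
    n_blobs = max(1, int(texture_density * bh * bw))
    base = np.zeros((bh, bw))
    ys = rng.uniform(0, bh, n_blobs)
    xs = rng.uniform(0, bw, n_blobs)
    amps = rng.uniform(50, 150, n_blobs)
    for y0, x0, a0 in zip(ys, xs, amps):
        base += a0 * np.exp(
            -((np.arange(bh)[:, None] - y0) ** 2 + (np.arange(bw)[None, :] - x0) ** 2)
            / (2 * 2.0**2)
        )

    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        # content translated by +cum[t] => sample base at (grid - cum[t])
        oy = span - cum[t, 1]
        ox = span - cum[t, 0]
        coords = np.meshgrid(rows + oy, cols + ox, indexing="ij")
        frames[t] = ndimage.map_coordinates(base, coords, order=1, mode="nearest")
    if noise_sd > 0:
        frames = np.clip(frames + rng.normal(0, noise_sd, frames.shape), 0, None)

    movie = CalibratedMovie(
        channels={"cells": frames},
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        source_axis=source_axis,
    )
    truth = GroundTruth(seed=seed, drift=shifts, drift_um=shifts * pixel_size)
    return movie, truth


def make_vessel_image(
    vessel_segments: Sequence[tuple] = (((20, 8), (20, 56), 3),),
    cell_positions_px: Optional[Sequence[tuple[float, float]]] = None,
    n_random_cells: int = 0,
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Binary vessel mask plus cell point set with brute-force distances.

    ``vessel_segments`` are ((row0, col0), (row1, col1), thickness_px)
    straight segments rasterized into the mask. Cell positions are (row,
    col) pixel coordinates; ``n_random_cells`` adds uniformly random ones.
    Ground-truth distances are exact nearest-vessel-pixel Euclidean
    distances in micrometers, computed by exhaustive search.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    for (r0, c0), (r1, c1), thick in vessel_segments:
        n = int(max(abs(r1 - r0), abs(c1 - c0))) * 4 + 2
        rr = np.linspace(r0, r1, n)
        cc = np.linspace(c0, c1, n)
        half = (thick - 1) / 2
        for r, c in zip(rr, cc):
            r_lo = max(int(np.floor(r - half)), 0)
            r_hi = min(int(np.ceil(r + half)) + 1, h)
            c_lo = max(int(np.floor(c - half)), 0)
            c_hi = min(int(np.ceil(c + half)) + 1, w)
            mask[r_lo:r_hi, c_lo:c_hi] = True
    if not mask.any():
        raise ValueError("no vessel pixels in mask")

    cells = list(cell_positions_px or [])
    if n_random_cells:
        cells += [
            (rng.uniform(0, h - 1), rng.uniform(0, w - 1)) for _ in range(n_random_cells)
        ]
    cells_px = np.asarray(cells, dtype=float).reshape(-1, 2)

    vr, vc = np.nonzero(mask)
    dists = np.empty(len(cells_px))
    inside = np.empty(len(cells_px), dtype=bool)
    for i, (r, c) in enumerate(cells_px):
        ri, ci = int(round(r)), int(round(c))
        inside[i] = mask[ri, ci]
        if inside[i]:
            dists[i] = 0.0
        else:
            dists[i] = np.sqrt(((vr - ri) ** 2 + (vc - ci) ** 2).min()) * pixel_size

    truth = GroundTruth(
        seed=seed,
        vessel_mask=mask,
        cell_positions=cells_px[:, ::-1] * pixel_size,  # -> (x, y) um
        cell_distances=dists,
        cell_inside=inside,
    )
    return mask, truth
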