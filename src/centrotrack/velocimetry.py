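"""Population-level migration velocimetry for dense collagen movies.

Re-implements the sequence-level tracking tool: the movie is background
corrected by subtracting the temporal mean, objects far from cell size can
be filtered out, the lateral displacement that optimizes each frame's
overlap with its predecessor is found by normalized cross-correlation over
integer shifts (optionally refined to sub-pixel by parabolic
interpolation), and the chemotactic velocity is the displacement component
toward the chemokine source over the frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "DriftSeries",
    "background_correct",
    "size_filter",
    "estimate_displacement",
    "chemotactic_velocity",
    "run_velocimetry",
]


@dataclass
class DriftSeries:
    """Per-frame-pair bulk displacement of a movie."""

    dx_px: np.ndarray  # (frames-1,)
    dy_px: np.ndarray
    score: np.ndarray  # correlation at the optimum
    pixel_size: float  # um/px
    frame_interval: float  # s
    source_axis: str = "+y"

    def __post_init__(self) -> None:
        if not (len(self.dx_px) == len(self.dy_px) == len(self.score)):
            raise ValueError("drift components differ in length")

    @property
    def dx_um(self) -> np.ndarray:
        return self.dx_px * self.pixel_size

    @property
    def dy_um(self) -> np.ndarray:
        return self.dy_px * self.pixel_size

    def to_table(self):
        import pandas as pd

        v, _ = chemotactic_velocity(self)
        return pd.DataFrame(
            {
                "pair": np.arange(len(self.dx_px)),
                "dx_px": self.dx_px,
                "dy_px": self.dy_px,
                "velocity_um_min": v,
                "score": self.score,
            }
        )


def background_correct(sequence: np.ndarray) -> np.ndarray:
    """Subtract the pixelwise temporal mean; negatives clipped to zero."""
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 3 or seq.shape[0] < 2:
        raise ValueError("need a (frames, h, w) sequence with >= 2 frames")
    return np.clip(seq - seq.mean(axis=0), 0.0, None)


def size_filter(
    binary: np.ndarray, min_area: float, max_area: float, pixel_size: float = 1.0
) -> np.ndarray:
    """Keep 8-connected components with area in [min_area, max_area] (um^2)."""
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    mask = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=float), labels, np.arange(1, n + 1))
    areas = areas * pixel_size**2
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = (areas >= min_area) & (areas <= max_area)
    return keep[labels]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -np.inf
    return float((a * b).sum() / denom)


def estimate_displacement(
    frame: np.ndarray,
    previous: np.ndarray,
    search_radius: int = 25,
    subpixel: bool = False,
) -> tuple[float, float, float]:
    """(dx, dy, score): the shift of ``frame`` relative to ``previous``.

    Maximizes the normalized cross-correlation of the overlapping region
    over integer shifts within ``search_radius``; exact ties go to the
    smaller |shift|. With ``subpixel=True`` the optimum is refined by a
    per-axis parabolic fit of the correlation surface.
    """
    f = np.asarray(frame, dtype=float)
    p = np.asarray(previous, dtype=float)
    if f.shape != p.shape:
        raise ValueError("frames differ in shape")
    if f.std() == 0 or p.std() == 0:
        raise ValueError("flat (zero-variance) frame; displacement undefined")
    h, w = f.shape
    if search_radius >= min(h, w) // 2:
        raise ValueError("search radius too large for frame size")

    shifts = [
        (dx, dy)
        for dy in range(-search_radius, search_radius + 1)
        for dx in range(-search_radius, search_radius + 1)
    ]
    # smaller shifts first so the first maximum wins exact ties
    shifts.sort(key=lambda s: (abs(s[0]) + abs(s[1]), abs(s[0]), abs(s[1]), s[0] >= 0, s[1] >= 0))

    scores = {}

    def score_at(dx: int, dy: int) -> float:
        if (dx, dy) in scores:
            return scores[(dx, dy)]
        # content moved by (dx, dy): frame[r, c] ~ previous[r - dy, c - dx]
        r0f, r1f = max(dy, 0), h + min(dy, 0)
        c0f, c1f = max(dx, 0), w + min(dx, 0)
        sub_f = f[r0f:r1f, c0f:c1f]
        sub_p = p[r0f - dy : r1f - dy, c0f - dx : c1f - dx]
        s = _pearson(sub_f, sub_p) if sub_f.size else -np.inf
        scores[(dx, dy)] = s
        return s

    best_s = -np.inf
    best = (0, 0)
    for dx, dy in shifts:
        s = score_at(dx, dy)
        if s > best_s:
            best_s = s
            best = (dx, dy)

    dx, dy = best
    if not subpixel:
        return float(dx), float(dy), best_s

    def parabolic(sm, s0, sp):
        denom = sm - 2 * s0 + sp
        if denom >= 0:  # not a local maximum
            return 0.0
        return float(np.clip(0.5 * (sm - sp) / denom, -0.5, 0.5))

    ddx = ddy = 0.0
    if abs(dx) < search_radius:
        ddx = parabolic(score_at(dx - 1, dy), best_s, score_at(dx + 1, dy))
    if abs(dy) < search_radius:
        ddy = parabolic(score_at(dx, dy - 1), best_s, score_at(dx, dy + 1))
    return dx + ddx, dy + ddy, best_s


def estimate_displacement_phase(
    frame: np.ndarray, previous: np.ndarray, upsample: int = 20
) -> tuple[float, float]:
    """Alternative registration path via phase correlation (sub-pixel)."""
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(
        np.asarray(previous, float), np.asarray(frame, float), upsample_factor=upsample
    )
    # skimage returns (row, col) of previous relative to frame
    return float(-shift[1]), float(-shift[0])


def run_velocimetry(
    sequence: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    source_axis: str = "+y",
    search_radius: int = 25,
    subpixel: bool = False,
    correct_background: bool = True,
    size_bounds: Optional[tuple[float, float]] = None,
) -> DriftSeries:
    """Full velocimetry pipeline on one (frames, h, w) sequence.

    Optional size filtering keeps only cell-sized connected components of
    the corrected sequence (Otsu-thresholded per frame) before
    registration.
    """
    seq = np.asarray(sequence, dtype=float)
    if correct_background:
        seq = background_correct(seq)
    if size_bounds is not None:
        from skimage.filters import threshold_otsu

        lo, hi = size_bounds
        out = np.zeros_like(seq)
        for t in range(seq.shape[0]):
            thr = threshold_otsu(seq[t]) if seq[t].std() > 0 else np.inf
            keep = size_filter(seq[t] > thr, lo, hi, pixel_size)
            out[t] = seq[t] * keep
        seq = out
    dxs, dys, scs = [], [], []
    for t in range(1, seq.shape[0]):
        dx, dy, s = estimate_displacement(seq[t], seq[t - 1], search_radius, subpixel)
        dxs.append(dx)
        dys.append(dy)
        scs.append(s)
    return DriftSeries(
        dx_px=np.asarray(dxs),
        dy_px=np.asarray(dys),
        score=np.asarray(scs),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        source_axis=source_axis,
    )


def chemotactic_velocity(drift: DriftSeries) -> tuple[np.ndarray, float]:
    """(per-pair, mean) migration velocity toward the source in um/min.

    The velocity uses the y-displacement toward the declared chemokine
    source over the time between consecutive frames; movement away from
    the source is negative.
    """
    if drift.pixel_size <= 0 or drift.frame_interval <= 0:
        raise ValueError("calibration must be positive")
    sign = 1.0 if drift.source_axis == "+y" else -1.0
    per_pair = sign * drift.dy_px * drift.pixel_size / (drift.frame_interval / 60.0)
    return per_pair, float(per_pair.mean()) if len(per_pair) else float("nan")
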