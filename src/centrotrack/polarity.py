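"""Back-to-front polarity gradient profiling of migrating cells.

Quantifies the ratio of a polarity reporter (e.g. the phosphoinositide
sensor PH-Akt) to a cytoplasmic reference (e.g. CETN2-GFP) along the
migration axis of one cell: pixels within an exclusion radius of any
centriole are dropped for the entire analysis, each channel is normalized
to that cell's all-time-point mean over the included pixels, positions are
projected onto the migration direction, rescaled to [0, 1] by the frame's
cell extent (rear = 0), grouped into equal-length segments (50 fine or 2
back/front), and the per-segment reporter/reference ratio is averaged
first within and then across time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fracture import cell_fractured

__all__ = [
    "PolarityProfile",
    "compute_polarity_profile",
    "estimate_migration_direction",
    "stratify_by_fracture",
    "otsu_cell_mask",
]


@dataclass
class PolarityProfile:
    """Binned back(0)-to-front(1) reporter/reference ratio of one cell."""

    n_bins: int
    bin_ratio: np.ndarray  # (n_bins,), NaN where a bin was empty in all frames
    per_frame: np.ndarray  # (n_frames, n_bins)
    bin_pixel_counts: np.ndarray  # (n_frames, n_bins)
    excluded_pixels: np.ndarray  # (n_frames,)
    cell_id: int = 0
    fractured: Optional[bool] = None

    def to_long(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "bin": np.arange(self.n_bins),
                "ratio": self.bin_ratio,
            }
        )


def estimate_migration_direction(
    masks: np.ndarray, smooth: int = 3
) -> np.ndarray:
    """Per-frame unit migration direction from cell-centroid displacement.

    Centroid steps are averaged over a ``smooth``-frame window; a frame
    with no net movement inherits the previous direction.
    """
    masks = np.asarray(masks, dtype=bool)
    cents = np.array(
        [np.flip(np.argwhere(m).mean(axis=0)) for m in masks]  # (x, y) px
    )
    steps = np.diff(cents, axis=0)
    dirs = np.zeros((len(masks), 2))
    prev = np.array([0.0, 1.0])
    for t in range(len(masks)):
        lo = max(t - smooth // 2 - 1, 0)
        hi = min(t + (smooth - 1) // 2, len(steps))
        v = steps[lo:hi].sum(axis=0) if hi > lo else np.zeros(2)
        n = np.linalg.norm(v)
        if n > 1e-9:
            prev = v / n
        dirs[t] = prev
    return dirs


def compute_polarity_profile(
    reporter: np.ndarray,
    reference: np.ndarray,
    masks: np.ndarray,
    centrioles: Sequence[Optional[np.ndarray]],
    directions: np.ndarray,
    pixel_size: float,
    n_bins: int = 50,
    exclusion_radius: float = 1.5,
    min_timepoints: int = 6,
    cell_id: int = 0,
) -> PolarityProfile:
    """Back-to-front binned reporter/reference profile of one cell.

    Parameters
    ----------
    reporter, reference
        (frames, h, w) channel stacks.
    masks
        (frames, h, w) boolean cell masks (one cell).
    centrioles
        Per frame: (k, 2) array of centriole (x, y) positions in um, or
        None/empty for no exclusion that frame.
    directions
        (frames, 2) migration direction vectors (x, y); need not be unit.
    exclusion_radius
        Radius (um) of the disk around each centriole dropped from the
        analysis (default 1.5 um).
    """
    reporter = np.asarray(reporter, dtype=float)
    reference = np.asarray(reference, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    n_frames = len(masks)
    if reporter.shape != reference.shape or reporter.shape != masks.shape:
        raise ValueError("reporter, reference and masks must share one shape")
    usable = [t for t in range(n_frames) if masks[t].any()]
    if len(usable) < min_timepoints:
        raise ValueError(
            f"cell observed in {len(usable)} frames; need >= {min_timepoints}"
        )

    h, w = masks.shape[1:]
    rr, cc = np.mgrid[0:h, 0:w]
    x_um = cc * pixel_size
    y_um = rr * pixel_size

    # centriole exclusion, applied for the entire analysis
    included = []
    excluded_counts = np.zeros(n_frames, dtype=int)
    for t in range(n_frames):
        inc = masks[t].copy()
        pts = centrioles[t] if centrioles is not None and centrioles[t] is not None else []
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        for cx, cy in pts:
            near = (x_um - cx) ** 2 + (y_um - cy) ** 2 <= exclusion_radius**2
            inc &= ~near
        excluded_counts[t] = int(masks[t].sum() - inc.sum())
        included.append(inc)

    # per-cell, all-time-point normalization over included pixels
    rep_all = np.concatenate([reporter[t][included[t]] for t in usable])
    ref_all = np.concatenate([reference[t][included[t]] for t in usable])
    if rep_all.size == 0:
        raise ValueError("exclusion removed every pixel of the cell")
    rep_norm_c = rep_all.mean()
    ref_norm_c = ref_all.mean()
    if rep_norm_c <= 0 or ref_norm_c <= 0:
        raise ValueError("channel mean over included pixels is not positive")

    per_frame = np.full((n_frames, n_bins), np.nan)
    counts = np.zeros((n_frames, n_bins), dtype=int)
    for t in usable:
        inc = included[t]
        if not inc.any():
            continue
        ux, uy = directions[t]
        nrm = np.hypot(ux, uy)
        if nrm <= 0:
            raise ValueError(f"zero migration direction at frame {t}")
        ux, uy = ux / nrm, uy / nrm
        # cell extent along the axis from the full mask (the cell length)
        s_mask = x_um[masks[t]] * ux + y_um[masks[t]] * uy
        s_min, s_max = s_mask.min(), s_mask.max()
        if s_max - s_min <= 0:
            raise ValueError(f"degenerate cell extent at frame {t}")
        s = (x_um[inc] * ux + y_um[inc] * uy - s_min) / (s_max - s_min)
        bins = np.clip((s * n_bins).astype(int), 0, n_bins - 1)
        rep_v = reporter[t][inc] / rep_norm_c
        ref_v = reference[t][inc] / ref_norm_c
        for k in range(n_bins):
            sel = bins == k
            counts[t, k] = int(sel.sum())
            if counts[t, k] == 0:
                continue  # empty bin stays missing, never imputed
            ref_mean = ref_v[sel].mean()
            if ref_mean > 0:
                per_frame[t, k] = rep_v[sel].mean() / ref_mean

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        bin_ratio = np.nanmean(per_frame[usable], axis=0)
    return PolarityProfile(
        n_bins=n_bins,
        bin_ratio=bin_ratio,
        per_frame=per_frame,
        bin_pixel_counts=counts,
        excluded_pixels=excluded_counts,
        cell_id=cell_id,
    )


def stratify_by_fracture(
    profiles: Sequence[PolarityProfile],
    distance_series: dict,
    threshold: float = 1.5,
    min_timepoints: int = 2,
) -> tuple[list, list]:
    """Partition cells into (intact, fractured) groups by their centriole
    distance series; group sizes sum to the input size."""
    ids = [p.cell_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell ids in profiles")
    missing = [i for i in ids if i not in distance_series]
    if missing:
        raise ValueError(f"no distance series for cells {missing}")
    intact, fractured = [], []
    for p in profiles:
        frac = cell_fractured(distance_series[p.cell_id], threshold, min_timepoints)
        p.fractured = frac
        (fractured if frac else intact).append(p)
    return intact, fractured


def otsu_cell_mask(image: np.ndarray) -> np.ndarray:
    """Basic Otsu-threshold mask helper (segmentation proper is upstream)."""
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    return img > threshold_otsu(img)
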