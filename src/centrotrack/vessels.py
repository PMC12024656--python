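"""Vessel-proximity analysis for tissue-sheet images.

Given a binary lymphatic-vessel mask and cell detections, computes the
Euclidean distance transform of the non-vessel region (in micrometers),
looks up each cell's nearest-vessel distance, and counts cells inside
versus outside the vessels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = ["VesselDistanceResult", "vessel_distance_map", "cell_vessel_stats"]


@dataclass
class VesselDistanceResult:
    """Per-cell nearest-vessel distances and inside/outside counts."""

    distance_map: np.ndarray  # (h, w) um; 0 exactly on vessel pixels
    cell_distances: np.ndarray  # (n,) um
    cell_inside: np.ndarray  # (n,) bool
    n_inside: int
    n_outside: int

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell": np.arange(len(self.cell_distances)),
                "distance_um": self.cell_distances,
                "inside": self.cell_inside,
            }
        )


def vessel_distance_map(vessel_mask: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Euclidean distance (um) from every pixel to the nearest vessel pixel."""
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask.any():
        raise ValueError("vessel mask is empty")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return ndimage.distance_transform_edt(~mask) * pixel_size


def cell_vessel_stats(
    cells: np.ndarray,
    vessel_mask: np.ndarray,
    pixel_size: float = 1.0,
    cell_pixels: bool = False,
) -> VesselDistanceResult:
    """Nearest-vessel distance and inside/outside label per cell.

    ``cells`` is an (n, 2) array of centroid (x, y) positions in um, or,
    with ``cell_pixels=True``, a boolean mask of supra-threshold cell
    pixels whose per-pixel distance distribution is reported instead (each
    pixel then counts as one observation, as when scoring every
    reporter-positive pixel).
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    dist_map = vessel_distance_map(mask, pixel_size)
    h, w = mask.shape
    if cell_pixels:
        cellmask = np.asarray(cells, dtype=bool)
        if cellmask.shape != mask.shape:
            raise ValueError("cell mask and vessel mask differ in shape")
        rr, cc = np.nonzero(cellmask)
        if len(rr) == 0:
            raise ValueError("no cell pixels")
        dists = dist_map[rr, cc]
        inside = mask[rr, cc]
    else:
        pts = np.asarray(cells, dtype=float).reshape(-1, 2)
        if len(pts) == 0:
            raise ValueError("no cell detections")
        cols = np.rint(pts[:, 0] / pixel_size).astype(int)
        rows = np.rint(pts[:, 1] / pixel_size).astype(int)
        if (
            rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w
        ):
            raise ValueError("cell detection outside image bounds")
        dists = dist_map[rows, cols]
        inside = mask[rows, cols]
    return VesselDistanceResult(
        distance_map=dist_map,
        cell_distances=np.asarray(dists, dtype=float),
        cell_inside=np.asarray(inside, dtype=bool),
        n_inside=int(inside.sum()),
        n_outside=int(len(inside) - inside.sum()),
    )
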