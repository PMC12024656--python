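"""Calibrated movie container, analysis configuration and table I/O.

All physical quantities carried by these types are in micrometers and
seconds. Pixel coordinates are 0-based array indices (row = y, col = x)
converted to micrometers through ``pixel_size``; intensities are arbitrary
nonnegative units and are never rescaled on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CalibratedMovie",
    "AnalysisConfig",
    "TRACK_TABLE_COLUMNS",
    "load_movie",
    "save_movie",
    "write_table",
    "read_table",
]

#: canonical column order of the track-table export surface
TRACK_TABLE_COLUMNS = ("track_id", "frame", "x_um", "y_um", "intensity", "channel")


@dataclass
class CalibratedMovie:
    """A multi-channel time-lapse with physical calibration.

    Parameters
    ----------
    channels
        Mapping of channel role label (e.g. ``"centriole"``, ``"nucleus"``,
        ``"polarity"``) to a ``(frames, height, width)`` intensity array.
        All channels must share one shape.
    pixel_size
        Micrometers per pixel, > 0.
    frame_interval
        Seconds between consecutive frames, > 0.
    source_axis
        Direction of the chemokine source, ``"+y"`` (increasing row index)
        or ``"-y"``. Used by the velocimetry stage.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size: float
    frame_interval: float
    source_axis: str = "+y"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("movie must have at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel arrays differ in shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValueError("channel arrays must be 3D (frames, height, width)")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if self.source_axis not in ("+y", "-y"):
            raise ValueError(f"source_axis must be '+y' or '-y', got {self.source_axis!r}")
        for role, arr in self.channels.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"channel {role!r} has negative intensities")

    @property
    def frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"movie has no channel with role {role!r}; "
                f"available: {sorted(self.channels)}"
            ) from None


@dataclass
class AnalysisConfig:
    """All numeric parameters of the analysis, with the published defaults.

    Distances and radii are micrometers; ``linker_gap_size``,
    ``min_fractured_timepoints``, ``rejoin_frames``, ``profile_norm_tail``
    and ``polarity_bins`` are frame/sample counts.
    """

    fracture_threshold: float = 1.5
    dc_category_bounds: tuple[float, ...] = (1.5, 3.5, 5.0)
    fibroblast_category_bounds: tuple[float, ...] = (1.5, 3.0)
    min_fractured_timepoints: int = 2
    roi_radius: float = 0.35
    profile_line_length: float = 5.0
    profile_norm_tail: int = 4
    polarity_bins: int = 50
    centriole_exclusion_radius: float = 1.5
    linker_max_distance: float = 25.0
    linker_gap_size: int = 3
    rejoin_frames: int = 3
    velocity_window: int = 3
    spot_diameter: float = 0.65
    search_radius_px: int = 25
    min_polarity_timepoints: int = 6

    def __post_init__(self) -> None:
        for name in (
            "fracture_threshold",
            "roi_radius",
            "profile_line_length",
            "centriole_exclusion_radius",
            "linker_max_distance",
            "spot_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("dc_category_bounds", "fibroblast_category_bounds"):
            bounds = tuple(getattr(self, name))
            if any(b <= 0 for b in bounds) or any(
                b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])
            ):
                raise ValueError(f"{name} must be strictly increasing positive, got {bounds}")
            object.__setattr__(self, name, bounds)
        if self.min_fractured_timepoints < 1:
            raise ValueError("min_fractured_timepoints must be >= 1")
        for name in ("profile_norm_tail", "polarity_bins", "linker_gap_size",
                     "rejoin_frames", "velocity_window", "search_radius_px",
                     "min_polarity_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dc_category_bounds", "fibroblast_category_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("dc_category_bounds", "fibroblast_category_bounds"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# movie I/O
# ---------------------------------------------------------------------------

def load_movie(
    path: str | Path,
    pixel_size: float,
    frame_interval: float,
    channel_roles: Sequence[str],
    source_axis: str = "+y",
) -> CalibratedMovie:
    """Read a multi-page TIFF with frame-interleaved channels.

    Pages are expected in the order frame0/ch0, frame0/ch1, ..., frame1/ch0,
    ... and are de-interleaved by the declared ``channel_roles`` order.
    Intensities are preserved bit-exact; calibration is attached as given.
    """
    if pixel_size <= 0 or frame_interval <= 0:
        raise ValueError("pixel_size and frame_interval must be positive")
    if not channel_roles:
        raise ValueError("channel_roles must be nonempty")
    pages = tifffile.imread(str(path))
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2D pages, got shape {pages.shape}")
    n_ch = len(channel_roles)
    if pages.shape[0] % n_ch != 0:
        raise ValueError(
            f"{pages.shape[0]} pages are not divisible by {n_ch} declared channels"
        )
    channels = {role: pages[i::n_ch] for i, role in enumerate(channel_roles)}
    return CalibratedMovie(
        channels=channels,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        source_axis=source_axis,
    )


def save_movie(movie: CalibratedMovie, path: str | Path) -> None:
    """Write a movie as a frame-interleaved multi-page TIFF (float32)."""
    roles = list(movie.channels)
    stacks = [np.asarray(movie.channels[r], dtype=np.float32) for r in roles]
    n_frames = stacks[0].shape[0]
    pages = np.empty((n_frames * len(roles),) + stacks[0].shape[1:], dtype=np.float32)
    for i, st in enumerate(stacks):
        pages[i :: len(roles)] = st
    tifffile.imwrite(str(path), pages)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path, float_precision=None) -> None:
    """Write a tabular result as CSV (header row, UTF-8).

    Coordinate-bearing tables are validated: non-finite coordinates are
    rejected and duplicate ``(track_id, frame)`` pairs raise. Round-trips
    losslessly through :func:`read_table`; pass ``float_precision`` (int)
    to round floats to that many significant digits instead.
    """
    df = pd.DataFrame(records)
    coord_cols = [c for c in df.columns if c in ("x_um", "y_um", "x", "y")]
    for col in coord_cols:
        vals = pd.to_numeric(df[col])
        if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
            raise ValueError(f"non-finite values in coordinate column {col!r}")
    if {"track_id", "frame"} <= set(df.columns) and len(df):
        if df.duplicated(subset=["track_id", "frame"]).any():
            raise ValueError("duplicate (track_id, frame) pairs")
    fmt = None if float_precision is None else f"%.{float_precision}g"
    df.to_csv(path, index=False, float_format=fmt, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
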