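"""Stage orchestration: chain the analysis stages over one movie and write
their tables under an output directory, with a deterministic run log."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import dataclasses
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import AnalysisConfig, CalibratedMovie, write_table
from .tracking import distance_series, track_centriole_pair
from .fracture import analyze_series
from .intensity import centrosome_intensity_ratio
from .polarity import compute_polarity_profile, estimate_migration_direction
from .velocimetry import run_velocimetry
from .vessels import cell_vessel_stats

__all__ = ["STAGES", "run_pipeline"]

STAGES = ("track", "fracture", "intensity", "polarity", "velocimetry", "vessels")


def _track_stage(movie, config, out):
    track = track_centriole_pair(movie, config)
    write_table(track.to_table(), out / "tracks.csv")
    series = distance_series(track)
    write_table(
        pd.DataFrame({"time_s": series[:, 0], "distance_um": series[:, 1]}),
        out / "distances.csv",
    )
    return track, series


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    stages: Sequence[str] = ("track", "fracture"),
    movie: Optional[CalibratedMovie] = None,
    masks: Optional[np.ndarray] = None,
    vessel_mask: Optional[np.ndarray] = None,
    cell_positions: Optional[np.ndarray] = None,
    seed: int = 0,
) -> dict:
    """Run the selected stages and write one table per stage.

    ``all`` expands to every stage whose inputs are present. Identical
    (inputs, config, seed) runs produce byte-identical outputs; the run log
    records config, seed and package version only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    if stages == ["all"]:
        stages = [s for s in STAGES if _stage_ready(s, movie, masks, vessel_mask, cell_positions)]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; known: {list(STAGES)}")

    results: dict = {}
    track = series = None
    for stage in stages:
        if stage in ("track", "fracture", "intensity") and movie is None:
            raise ValueError(f"stage {stage!r} requires a movie")
        if stage == "track":
            track, series = _track_stage(movie, config, out)
            results["track"] = track
        elif stage == "fracture":
            if track is None:
                track, series = _track_stage(movie, config, out)
                results["track"] = track
            report = analyze_series(
                series[:, 0],
                series[:, 1],
                cell_id=track.cell_id,
                threshold=config.fracture_threshold,
                min_timepoints=config.min_fractured_timepoints,
                velocity_window=config.velocity_window,
                rejoin_frames=config.rejoin_frames,
            )
            write_table(pd.DataFrame([report.to_row()]), out / "fracture_report.csv")
            write_table(
                pd.DataFrame(
                    {
                        "time_s": series[:, 0],
                        "distance_um": series[:, 1],
                        "category": report.frame_categories,
                    }
                ),
                out / "frame_categories.csv",
            )
            results["fracture"] = report
        elif stage == "intensity":
            if track is None:
                track, series = _track_stage(movie, config, out)
            stack = movie.channel("centriole")
            rows = []
            for i, f in enumerate(track.frames):
                a, b = track.pos_a[i], track.pos_b[i]
                if not (np.isfinite(a).all() and np.isfinite(b).all()):
                    continue
                try:
                    ratio = centrosome_intensity_ratio(
                        stack[f], a, b, movie.pixel_size, config.roi_radius
                    )
                except ValueError:
                    continue
                rows.append({"frame": int(f), "intensity_ratio": ratio})
            write_table(pd.DataFrame(rows), out / "intensity_ratio.csv")
            results["intensity"] = rows
        elif stage == "polarity":
            if movie is None:
                raise ValueError("stage 'polarity' requires a movie")
            reporter = movie.channel("polarity")
            reference = movie.channel("reference")
            if masks is None:
                raise ValueError("stage 'polarity' requires cell masks")
            if track is None and "centriole" in movie.channels:
                track, series = _track_stage(movie, config, out)
            cents = [None] * movie.frames
            if track is not None:
                cents = [None] * movie.frames
                for i, f in enumerate(track.frames):
                    pts = [p for p in (track.pos_a[i], track.pos_b[i]) if np.isfinite(p).all()]
                    cents[int(f)] = np.array(pts) if pts else None
            dirs = estimate_migration_direction(masks)
            profile = compute_polarity_profile(
                reporter,
                reference,
                masks,
                cents,
                dirs,
                movie.pixel_size,
                n_bins=config.polarity_bins,
                exclusion_radius=config.centriole_exclusion_radius,
                min_timepoints=config.min_polarity_timepoints,
            )
            write_table(profile.to_long(), out / "polarity_profile.csv")
            results["polarity"] = profile
        elif stage == "velocimetry":
            if movie is None:
                raise ValueError("stage 'velocimetry' requires a movie")
            role = "cells" if "cells" in movie.channels else next(iter(movie.channels))
            drift = run_velocimetry(
                movie.channel(role),
                movie.pixel_size,
                movie.frame_interval,
                source_axis=movie.source_axis,
                search_radius=config.search_radius_px,
            )
            write_table(drift.to_table(), out / "drift.csv")
            results["velocimetry"] = drift
        elif stage == "vessels":
            if vessel_mask is None or cell_positions is None:
                raise ValueError("stage 'vessels' requires vessel_mask and cell_positions")
            px = movie.pixel_size if movie is not None else 1.0
            res = cell_vessel_stats(cell_positions, vessel_mask, px)
            write_table(res.to_table(), out / "vessels.csv")
            results["vessels"] = res

    log = {
        "package": "centrotrack",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": dataclasses.asdict(config),
    }
    for key in ("dc_category_bounds", "fibroblast_category_bounds"):
        log["config"][key] = list(log["config"][key])
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return results


def _stage_ready(stage, movie, masks, vessel_mask, cell_positions) -> bool:
    if stage in ("track", "fracture", "intensity"):
        return movie is not None and "centriole" in movie.channels
    if stage == "polarity":
        return (
            movie is not None
            and {"polarity", "reference"} <= set(movie.channels)
            and masks is not None
        )
    if stage == "velocimetry":
        return movie is not None
    if stage == "vessels":
        return vessel_mask is not None and cell_positions is not None
    return False
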