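"""High-level study emulations built from the pipeline stages.

These wrap the low-level modules into the three benchmark experiments the
synthetic presets encode, so that the same entry points serve scripted
reproduction and tests:

* directed-transport speed measurement through the full
  movie → localize → link → run-detection chain;
* per-cell slow-fraction estimation from pooled displacements;
* two-channel colocalization recovery on rendered scenes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coloc import percent_colocalized
from .core import derive_seed
from .linking import DEFAULT_R_MAX_UM, link_tracks
from .localize import localize_movie
from .simulate import (
    PRESETS,
    make_geometry,
    make_two_channel_scene,
    render_movie,
    simulate_tracks,
)
from .smdm import DisplacementSample
from .transport import detect_runs_table, mean_transit_speed

__all__ = [
    "measure_directed_events",
    "simulate_cell_sample",
    "measure_coloc_scenes",
]

#: Localization error (μm) applied when emulating SMdM at the track level;
#: matches the ~0.15 px RMSE of the Gaussian spot fit at 130 nm/px.
TRACK_LEVEL_LOC_SD_UM = 0.02


def _default_geometry(imaging, seed: int):
    h, w = imaging.height_px, imaging.width_px
    return make_geometry(h, w, (0.45 * w, 0.45 * h), (0.12 * w, 0.12 * h), seed)


def measure_directed_events(
    preset_name: str, n_events: int, seed: int = 0, max_movies: int | None = None
) -> pd.DataFrame:
    """Measure ``n_events`` directed-movement events through the full chain.

    Simulates one directed particle per small movie under the given preset,
    renders it, localizes, links and detects runs, accumulating per-event
    speeds until ``n_events`` events have been measured (a simulated particle
    occasionally anchors or pauses before producing a detectable run, and a
    long pause can split one passage into two events). Returns the first
    ``n_events`` rows of the pooled run table.
    """
    preset = PRESETS[preset_name]
    imaging = preset.imaging
    if max_movies is None:
        max_movies = 4 * n_events
    all_runs: list[pd.DataFrame] = []
    total = 0
    for k in range(max_movies):
        movie_seed = derive_seed(seed, f"{preset_name}:event:{k}")
        geometry = _default_geometry(imaging, movie_seed)
        tracks = simulate_tracks(geometry, preset.kinetics, imaging, 1, movie_seed)
        movie = render_movie(tracks, imaging, seed=movie_seed + 1)
        locs = localize_movie(movie)
        linked = link_tracks(locs, DEFAULT_R_MAX_UM, pixel_size_nm=imaging.pixel_size_nm)
        linked.attrs["dt_s"] = imaging.frame_interval_s
        runs = detect_runs_table(linked, dt_s=imaging.frame_interval_s)
        if len(runs):
            runs = runs.assign(movie=k)
            all_runs.append(runs)
            total += len(runs)
        if total >= n_events:
            break
    if not all_runs:
        return pd.DataFrame()
    pooled = pd.concat(all_runs, ignore_index=True)
    return pooled.iloc[:n_events]


def simulate_cell_sample(
    preset_name: str,
    seed: int = 0,
    n_particles: int = 40,
    r_max_um: float = DEFAULT_R_MAX_UM,
) -> DisplacementSample:
    """Pooled single-frame displacements of one simulated cell.

    Emulates the SMdM acquisition at the track level: ground-truth tracks are
    simulated under the preset's kinetics, localization error of
    ``TRACK_LEVEL_LOC_SD_UM`` is added per coordinate, and consecutive-frame
    displacement magnitudes within ``r_max_um`` are pooled cell-wide.
    """
    preset = PRESETS[preset_name]
    imaging = preset.imaging
    geometry = _default_geometry(imaging, seed)
    tracks = simulate_tracks(geometry, preset.kinetics, imaging, n_particles, seed)
    rng = np.random.default_rng(derive_seed(seed, f"{preset_name}:locnoise"))
    pooled = []
    for tr in tracks:
        x = tr.x_um + rng.normal(0.0, TRACK_LEVEL_LOC_SD_UM, tr.n_frames)
        y = tr.y_um + rng.normal(0.0, TRACK_LEVEL_LOC_SD_UM, tr.n_frames)
        r = np.hypot(np.diff(x), np.diff(y))
        pooled.append(r[(r > 0) & (r <= r_max_um)])
    return DisplacementSample(
        np.concatenate(pooled), imaging.frame_interval_s, r_max_um
    )


def measure_coloc_scenes(
    n_scenes: int = 10,
    n_spots: int = 200,
    jitter_px: float = 1.0,
    radius_px: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection + matching colocalization recovery over synthetic scenes.

    Each scene is generated with the ``coloc_fixed`` preset geometry, both
    channels are localized, and the percentage of channel-A spots matched
    one-to-one within ``radius_px`` is recorded next to the scene's sampled
    ground truth. Returns one row per scene (columns: percent, truth_percent,
    n_a, n_b).
    """
    preset = PRESETS["coloc_fixed"]
    rows = []
    for k in range(n_scenes):
        scene_seed = derive_seed(seed, f"coloc:{k}")
        movie_a, movie_b, pairs = make_two_channel_scene(
            n_spots, preset.coloc_fraction, jitter_px, preset.imaging, scene_seed
        )
        locs_a = localize_movie(movie_a)
        locs_b = localize_movie(movie_b)
        rows.append((
            percent_colocalized(locs_a, locs_b, radius_px),
            100.0 * len(pairs) / n_spots,
            len(locs_a),
            len(locs_b),
        ))
    return pd.DataFrame(rows, columns=["percent", "truth_percent", "n_a", "n_b"])
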