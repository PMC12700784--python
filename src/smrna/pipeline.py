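"""Staged pipeline execution with a reproducible run manifest.

A run is described by a :class:`PipelineConfig` (defaults < config file <
CLI flags) and an ordered list of stage names. Each stage reads its
predecessor's files from the output directory and appends a manifest record
with its derived seed, parameters and input/output SHA-256 hashes, so any
stage can be re-run bit-identically (deterministic stages) or
distribution-identically (stochastic stages) from the manifest alone.

Per-stage seeds are derived from the global seed by stable hashing of the
stage name, so reordering stages never changes a stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .core import (
    InputError,
    Movie,
    derive_seed,
    read_movie,
    read_table,
    write_mask,
    write_movie,
    write_table,
)
from .simulate import (
    PRESETS,
    ImagingConfig,
    make_geometry,
    make_two_channel_scene,
    render_movie,
    simulate_tracks,
    tracks_to_table,
)

logger = logging.getLogger("smrna")

STAGE_ORDER = [
    "simulate", "localize", "link", "smdm", "runs", "kymo", "distances", "coloc",
]


@dataclass
class PipelineConfig:
    """Run configuration; every field has a default and is file/flag-overridable."""

    preset: str = "notch2_untreated"
    n_particles: int = 80
    pixel_size_nm: float = 130.0
    frame_interval_s: float = 0.1
    n_frames: int | None = None   # None: use the preset's imaging settings
    height_px: int | None = None
    width_px: int | None = None
    seed: int = 0
    out_dir: str = "smrna_run"
    params: dict = field(default_factory=dict)  # per-stage overrides

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages: list[str]) -> dict:
    """Execute the requested stages in order and write ``manifest.json``.

    Raises :class:`InputError` for an unknown stage name or when a stage's
    upstream artifact is missing.
    """
    for stage in stages:
        if stage not in STAGE_ORDER:
            raise InputError(f"unknown stage: {stage!r}")
    stages = sorted(stages, key=STAGE_ORDER.index)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "smrna",
        "version": __version__,
        "global_seed": config.seed,
        "config": asdict(config),
        "stages": [],
    }
    for stage in stages:
        seed = derive_seed(config.seed, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        record = {"name": stage, "seed": seed, "params": config.stage_params(stage)}
        outputs = _STAGES[stage](config, out, seed, record)
        record["outputs"] = {name: _sha256(out / name) for name in outputs}
        manifest["stages"].append(record)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _require(out: Path, name: str, stage: str) -> Path:
    path = out / name
    if not path.exists():
        raise InputError(f"stage {stage!r} needs missing upstream artifact {name!r}")
    return path


def _stage_simulate(config, out: Path, seed: int, record: dict) -> list[str]:
    preset = PRESETS[config.preset]
    imaging = ImagingConfig(
        pixel_size_nm=config.pixel_size_nm,
        frame_interval_s=config.frame_interval_s,
        n_frames=config.n_frames or preset.imaging.n_frames,
        height_px=config.height_px or preset.imaging.height_px,
        width_px=config.width_px or preset.imaging.width_px,
    )
    if preset.coloc_fraction is not None:
        params = config.stage_params("simulate")
        movie_a, movie_b, pairs = make_two_channel_scene(
            n_spots=params.get("n_spots", 200),
            coloc_fraction=preset.coloc_fraction,
            jitter_px=params.get("jitter_px", 1.0),
            imaging=imaging,
            seed=seed,
        )
        movie_a.meta["preset"] = movie_b.meta["preset"] = config.preset
        write_movie(out / "channel_a.tif", movie_a)
        write_movie(out / "channel_b.tif", movie_b)
        write_table(out / "true_pairs.csv", pairs)
        return ["channel_a.tif", "channel_b.tif", "true_pairs.csv"]
    h, w = imaging.height_px, imaging.width_px
    geometry = make_geometry(h, w, (0.42 * w, 0.42 * h), (0.15 * w, 0.15 * h), seed)
    tracks = simulate_tracks(geometry, preset.kinetics, imaging, config.n_particles, seed)
    movie = render_movie(tracks, imaging, seed=seed + 1)
    movie.meta.update({"preset": config.preset, "seed": seed})
    write_movie(out / "movie.tif", movie)
    write_mask(out / "cell_mask.tif", geometry.cell_mask)
    write_mask(out / "nucleus_mask.tif", geometry.nucleus_mask)
    write_table(out / "ground_truth.csv", tracks_to_table(tracks))
    return ["movie.tif", "cell_mask.tif", "nucleus_mask.tif", "ground_truth.csv"]


def _stage_localize(config, out: Path, seed: int, record: dict) -> list[str]:
    from .localize import LocalizeParams, localize_movie

    movie = read_movie(_require(out, "movie.tif", "localize"))
    table = localize_movie(movie, LocalizeParams(**config.stage_params("localize")))
    write_table(out / "locs.csv", table)
    return ["locs.csv"]


def _stage_link(config, out: Path, seed: int, record: dict) -> list[str]:
    from .linking import link_tracks, pair_displacements

    table = read_table(_require(out, "locs.csv", "link"))
    table.attrs["pixel_size_nm"] = config.pixel_size_nm
    table.attrs["frame_interval_s"] = config.frame_interval_s
    params = config.stage_params("link")
    disp = pair_displacements(table, **params)
    tracks = link_tracks(table, **params)
    write_table(out / "disps.csv", disp)
    write_table(out / "tracks.csv", tracks)
    return ["disps.csv", "tracks.csv"]


def _stage_smdm(config, out: Path, seed: int, record: dict) -> list[str]:
    from .linking import DEFAULT_R_MAX_UM
    from .smdm import DisplacementSample, fit_two, map_diffusivity

    disp = read_table(_require(out, "disps.csv", "smdm"))
    disp.attrs["dt_s"] = config.frame_interval_s
    disp.attrs["r_max_um"] = DEFAULT_R_MAX_UM
    params = config.stage_params("smdm")
    sample = DisplacementSample.from_displacements(disp)
    fit = fit_two(sample)
    (out / "smdm_fit.json").write_text(json.dumps({
        "F1": fit.F1, "D1_um2_s": fit.D1, "D2_um2_s": fit.D2, "b": fit.b,
        "logL": fit.logL, "n": fit.n, "degenerate": fit.degenerate,
    }, indent=2))
    dmap = map_diffusivity(
        disp, pixel_size_nm=config.pixel_size_nm,
        bin_size_px=params.get("bin_size_px", 2.5),
        n_min=params.get("n_min", 30),
    )
    tifffile.imwrite(out / "diffusivity_map.tif", dmap.D_um2_s.astype(np.float32))
    return ["smdm_fit.json", "diffusivity_map.tif"]


def _stage_runs(config, out: Path, seed: int, record: dict) -> list[str]:
    from .transport import detect_runs_table

    tracks = read_table(_require(out, "tracks.csv", "runs"))
    runs = detect_runs_table(
        tracks, dt_s=config.frame_interval_s, **config.stage_params("runs")
    )
    write_table(out / "runs.csv", runs)
    return ["runs.csv"]


def _stage_kymo(config, out: Path, seed: int, record: dict) -> list[str]:
    from .transport import extract_kymograph

    movie = read_movie(_require(out, "movie.tif", "kymo"))
    params = config.stage_params("kymo")
    path_file = out / "kymo_path.json"
    if path_file.exists():
        polyline = json.loads(path_file.read_text())["polyline_px"]
    else:  # default: horizontal midline
        _, h, w = movie.shape
        polyline = [[2.0, h / 2.0], [w - 2.0, h / 2.0]]
        path_file.write_text(json.dumps({"polyline_px": polyline}))
    kymo = extract_kymograph(movie, polyline, params.get("width_px", 5))
    tifffile.imwrite(out / "kymograph.tif", kymo.matrix.astype(np.float32))
    return ["kymograph.tif", "kymo_path.json"]


def _stage_distances(config, out: Path, seed: int, record: dict) -> list[str]:
    from .core import read_mask
    from .simulate import CellGeometry
    from .transport import distances

    locs = read_table(_require(out, "locs.csv", "distances"))
    geometry = CellGeometry(
        read_mask(_require(out, "cell_mask.tif", "distances")),
        read_mask(_require(out, "nucleus_mask.tif", "distances")),
    )
    stats = distances(locs, geometry, pixel_size_nm=config.pixel_size_nm)
    write_table(out / "distances.csv", stats)
    return ["distances.csv"]


def _stage_coloc(config, out: Path, seed: int, record: dict) -> list[str]:
    from .coloc import match_spots, percent_colocalized
    from .localize import localize_movie

    movie_a = read_movie(_require(out, "channel_a.tif", "coloc"))
    movie_b = read_movie(_require(out, "channel_b.tif", "coloc"))
    params = config.stage_params("coloc")
    radius = params.get("radius_px", 3.0)
    locs_a = localize_movie(movie_a)
    locs_b = localize_movie(movie_b)
    matches = match_spots(locs_a, locs_b, radius)
    write_table(out / "matches.csv", _matches_frame(matches))
    (out / "coloc_summary.json").write_text(json.dumps({
        "percent_colocalized": percent_colocalized(locs_a, locs_b, radius),
        "n_a": len(locs_a), "n_b": len(locs_b), "radius_px": radius,
    }, indent=2))
    return ["matches.csv", "coloc_summary.json"]


def _matches_frame(matches):
    import pandas as pd

    return pd.DataFrame(
        [(m.index_a, m.index_b, m.distance_px) for m in matches],
        columns=["index_a", "index_b", "distance_px"],
    )


_STAGES = {
    "simulate": _stage_simulate,
    "localize": _stage_localize,
    "link": _stage_link,
    "smdm": _stage_smdm,
    "runs": _stage_runs,
    "kymo": _stage_kymo,
    "distances": _stage_distances,
    "coloc": _stage_coloc,
}
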