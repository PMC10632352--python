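"""Readers and writers for the package's on-disk formats.

Movies are multi-page TIFF (one file per channel); tabular entities
(paths, spots, tracks, runs, events) are plain CSV; fit results are JSON;
configs round-trip through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .colocalization import ColocResult
from .kinetics import DwellEvent, SurvivalFit
from .localization import SpotDetection, Track
from .motility import MicrotubulePath, Run
from .simulate import MovieStack

__all__ = [
    "write_movie", "read_movie",
    "write_paths", "read_paths",
    "write_spots", "read_spots",
    "write_tracks", "read_tracks",
    "write_runs", "read_runs",
    "write_events", "read_events",
    "write_survival", "write_fit", "write_config",
]


def write_movie(path, movie: MovieStack) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32),
                     photometric="minisblack",
                     metadata={"pixel_size_nm": movie.pixel_size_nm,
                               "frame_interval_s": movie.frame_interval_s,
                               "channel": movie.channel})


def read_movie(path, pixel_size_nm: float | None = None,
               frame_interval_s: float | None = None,
               channel: str = "") -> MovieStack:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    return MovieStack(
        frames=frames,
        pixel_size_nm=pixel_size_nm or float(meta.get("pixel_size_nm", 160.0)),
        frame_interval_s=frame_interval_s or float(meta.get("frame_interval_s", 1.0)),
        channel=channel or str(meta.get("channel", "")))


def write_paths(path, paths: list[MicrotubulePath]) -> None:
    rows = [{"path_id": p.id, "vertex": i, "x_nm": v[0], "y_nm": v[1]}
            for p in paths for i, v in enumerate(p.vertices)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_paths(path) -> list[MicrotubulePath]:
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("path_id", sort=True):
        grp = grp.sort_values("vertex")
        out.append(MicrotubulePath(vertices=grp[["x_nm", "y_nm"]].to_numpy(),
                                   id=int(pid)))
    return out


_SPOT_COLS = ["frame", "x_nm", "y_nm", "amplitude", "offset", "sigma_nm",
              "residual", "channel"]


def write_spots(path, spots: list[SpotDetection]) -> None:
    pd.DataFrame([{k: getattr(s, k) for k in _SPOT_COLS} for s in spots]
                 ).to_csv(path, index=False)


def read_spots(path) -> list[SpotDetection]:
    df = pd.read_csv(path, keep_default_na=False)
    return [SpotDetection(frame=int(r.frame), x_nm=r.x_nm, y_nm=r.y_nm,
                          amplitude=r.amplitude, offset=r.offset,
                          sigma_nm=r.sigma_nm, residual=r.residual,
                          channel=str(r.channel)) for r in df.itertuples()]


def write_tracks(path, tracks: list[Track]) -> None:
    rows = []
    for tid, tr in enumerate(tracks):
        for s in tr.spots:
            row = {"track_id": tid, **{k: getattr(s, k) for k in _SPOT_COLS}}
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path, frame_interval_s: float | None = None) -> list[Track]:
    df = pd.read_csv(path, keep_default_na=False)
    tracks = []
    for _, grp in df.groupby("track_id", sort=True):
        spots = [SpotDetection(frame=int(r.frame), x_nm=r.x_nm, y_nm=r.y_nm,
                               amplitude=r.amplitude, offset=r.offset,
                               sigma_nm=r.sigma_nm, residual=r.residual,
                               channel=str(r.channel)) for r in grp.itertuples()]
        tracks.append(Track(spots=spots, channel=spots[0].channel,
                            frame_interval_s=frame_interval_s))
    return tracks


def write_runs(path, runs: list[Run]) -> None:
    pd.DataFrame([{"path_id": r.path_id, "t_start_s": r.t_start_s,
                   "t_end_s": r.t_end_s, "s_start_nm": r.s_start_nm,
                   "s_end_nm": r.s_end_nm, "velocity_nm_s": r.velocity_nm_s,
                   "direction": r.direction} for r in runs]).to_csv(path, index=False)


def read_runs(path) -> list[Run]:
    df = pd.read_csv(path)
    return [Run(path_id=int(r.path_id), t_start_s=r.t_start_s, t_end_s=r.t_end_s,
                s_start_nm=r.s_start_nm, s_end_nm=r.s_end_nm)
            for r in df.itertuples()]


def write_events(path, events: list[DwellEvent]) -> None:
    pd.DataFrame([{"start_s": e.start_s, "end_s": e.end_s,
                   "censored": int(e.censored)} for e in events]
                 ).to_csv(path, index=False)


def read_events(path) -> list[DwellEvent]:
    df = pd.read_csv(path)
    return [DwellEvent(start_s=r.start_s, end_s=r.end_s, censored=bool(r.censored))
            for r in df.itertuples()]


def write_survival(path, t: np.ndarray, s: np.ndarray) -> None:
    pd.DataFrame({"t_s": t, "survival": s}).to_csv(path, index=False)


def write_fit(path, fit: SurvivalFit) -> None:
    with open(path, "w") as fh:
        json.dump({"tau_s": fit.tau_s, "se_s": fit.se_s, "n_events": fit.n_events,
                   "n_censored": fit.n_censored, "method": fit.method}, fh, indent=2)
        fh.write("\n")


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_coloc(path, results: list[ColocResult]) -> None:
    pd.DataFrame([{"field": i, "fraction": r.fraction, "n_bait": r.n_bait,
                   "n_matched": r.n_matched, "r_max_nm": r.r_max_nm}
                  for i, r in enumerate(results)]).to_csv(path, index=False)
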