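"""Kymograph construction, processive-run detection and run-frequency statistics.

Runs are counted per microtubule: the number of processive excursions divided
by the filament length (µm) and the acquisition duration (s).  Summary
statistics are reported as mean ± sd across microtubules, never pooled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MicrotubulePath",
    "Kymograph",
    "Run",
    "FrequencyResult",
    "filter_microtubules",
    "build_kymograph",
    "detect_runs",
    "run_frequency",
    "normalize_frequency",
    "velocity",
]


@dataclass(frozen=True)
class MicrotubulePath:
    """Polyline geometry of one filament, vertices in nm."""

    vertices: np.ndarray  # (N, 2) array of (x, y) in nm
    id: int = 0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("polyline needs >= 2 vertices of shape (N, 2)")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive polyline vertices must be distinct")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "_seg_lengths", seg)
        object.__setattr__(self, "_cum", np.concatenate([[0.0], np.cumsum(seg)]))

    @property
    def length_nm(self) -> float:
        return float(self._cum[-1])

    @property
    def length_um(self) -> float:
        return self.length_nm / 1000.0

    def point_at(self, s) -> np.ndarray:
        """Interpolate position(s) at arc length ``s`` (nm) along the polyline."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length_nm)
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0,
                      len(self._seg_lengths) - 1)
        t = (s - self._cum[idx]) / self._seg_lengths[idx]
        p0 = self.vertices[idx]
        p1 = self.vertices[idx + 1]
        out = p0 + t[:, None] * (p1 - p0)
        return out if out.shape[0] > 1 else out[0]

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project xy points (nm) onto the polyline.

        Returns (arc_length_nm, perpendicular_distance_nm) per point.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        a = self.vertices[:-1]  # (S, 2)
        b = self.vertices[1:]
        ab = b - a
        denom = (ab ** 2).sum(axis=1)  # (S,)
        # (P, S) projection parameter of every point on every segment
        ap = pts[:, None, :] - a[None, :, :]
        t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
        proj = a[None, :, :] + t[..., None] * ab[None, :, :]
        d2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(pts))
        s = self._cum[best] + t[rows, best] * self._seg_lengths[best]
        return s, np.sqrt(d2[rows, best])


@dataclass
class Kymograph:
    """Space–time intensity map: rows = time (down), columns = arc length."""

    data: np.ndarray  # (n_frames, n_bins)
    bin_size_nm: float
    frame_interval_s: float
    path_id: int
    width_px: int


@dataclass(frozen=True)
class Run:
    """One processive excursion along a filament."""

    path_id: int
    t_start_s: float
    t_end_s: float
    s_start_nm: float
    s_end_nm: float

    def __post_init__(self):
        if self.t_end_s <= self.t_start_s:
            raise ValueError("run must have positive duration")

    @property
    def displacement_nm(self) -> float:
        return self.s_end_nm - self.s_start_nm

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    @property
    def direction(self) -> int:
        return 1 if self.displacement_nm >= 0 else -1

    @property
    def velocity_nm_s(self) -> float:
        return abs(self.displacement_nm) / self.duration_s


def velocity(run: Run) -> float:
    """Speed of a run in nm/s: |arc displacement| / elapsed time."""
    return run.velocity_nm_s


@dataclass
class FrequencyResult:
    """Per-microtubule run frequencies (runs µm⁻¹ s⁻¹) and their summary."""

    per_mt: np.ndarray
    mt_ids: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.per_mt = np.asarray(self.per_mt, dtype=float)
        self.mt_ids = np.asarray(self.mt_ids)
        if np.any(self.per_mt < 0):
            raise ValueError("frequencies must be >= 0")
        self.mean = float(self.per_mt.mean()) if self.per_mt.size else 0.0
        self.sd = float(self.per_mt.std(ddof=1)) if self.per_mt.size > 1 else 0.0

    @property
    def n(self) -> int:
        return int(self.per_mt.size)


def filter_microtubules(paths: Iterable[MicrotubulePath],
                        min_length_um: float = 10.0) -> list[MicrotubulePath]:
    """Keep filaments with arc length >= ``min_length_um`` (inclusive boundary)."""
    paths = list(paths)
    kept = [p for p in paths if p.length_um >= min_length_um]
    if paths and not kept:
        logger.warning("all %d microtubules shorter than %g um were excluded",
                       len(paths), min_length_um)
    return kept


def build_kymograph(movie, path: MicrotubulePath, width_px: int = 3) -> Kymograph:
    """Sample movie intensity along a filament path for every frame.

    The path is sampled at one bin per camera pixel by bilinear interpolation
    and averaged over ``width_px`` samples perpendicular to the local path
    direction.
    """
    px = movie.pixel_size_nm
    n_bins = int(math.ceil(path.length_nm / px))
    s_centers = (np.arange(n_bins) + 0.5) * px
    s_centers = np.minimum(s_centers, path.length_nm)
    centers = np.atleast_2d(path.point_at(s_centers))

    # local tangent via finite differences along arc length
    eps = min(px, path.length_nm / 4)
    ahead = np.atleast_2d(path.point_at(np.minimum(s_centers + eps, path.length_nm)))
    behind = np.atleast_2d(path.point_at(np.maximum(s_centers - eps, 0.0)))
    tang = ahead - behind
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    offsets = (np.arange(width_px) - (width_px - 1) / 2) * px
    # (n_bins, width, 2) sample coordinates in nm
    coords_nm = centers[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    ny, nx = movie.frames.shape[1:]
    col = coords_nm[..., 0] / px - 0.5  # pixel-center convention
    row = coords_nm[..., 1] / px - 0.5
    if (coords_nm[..., 0].min() < 0 or coords_nm[..., 1].min() < 0
            or col.max() > nx - 0.5 or row.max() > ny - 0.5):
        raise ValueError("path (including averaging width) exits the field of view")

    flat = np.stack([row.ravel(), col.ravel()])
    kymo = np.empty((movie.frames.shape[0], n_bins))
    for i, frame in enumerate(movie.frames):
        vals = ndimage.map_coordinates(frame, flat, order=1, mode="nearest")
        kymo[i] = vals.reshape(n_bins, width_px).mean(axis=1)
    return Kymograph(data=kymo, bin_size_nm=px,
                     frame_interval_s=movie.frame_interval_s,
                     path_id=path.id, width_px=width_px)


def _segment_series(t: np.ndarray, s: np.ndarray, min_run_length_nm: float,
                    min_duration_s: float, max_pause_s: float,
                    min_speed_nm_s: float, path_id: int) -> list[Run]:
    """State machine over an (time, arc-position) series.

    A run is a maximal stretch of steps in one direction; steps slower than
    ``min_speed_nm_s`` count as pauses, tolerated up to ``max_pause_s`` of
    accumulated pause time.  Accepted runs satisfy both the minimum length
    and the minimum duration.
    """
    runs: list[Run] = []
    n = len(t)
    if n < 2:
        return runs

    start = None      # index of segment start
    last_move = None  # index of last point reached by a moving step
    direction = 0
    pause = 0.0

    def flush():
        if start is None or last_move is None or last_move <= start:
            return
        disp = s[last_move] - s[start]
        dur = t[last_move] - t[start]
        if abs(disp) >= min_run_length_nm and dur >= min_duration_s:
            runs.append(Run(path_id=path_id, t_start_s=t[start], t_end_s=t[last_move],
                            s_start_nm=s[start], s_end_nm=s[last_move]))

    for i in range(n - 1):
        ds = s[i + 1] - s[i]
        dt = t[i + 1] - t[i]
        step_dir = 0 if abs(ds) / dt < min_speed_nm_s else (1 if ds > 0 else -1)
        if step_dir == 0:
            pause += dt
            if start is not None and pause > max_pause_s:
                flush()
                start, last_move, direction, pause = None, None, 0, 0.0
            continue
        pause = 0.0
        if start is None:
            start, direction, last_move = i, step_dir, i + 1
        elif step_dir == direction:
            last_move = i + 1
        else:  # reversal: close current segment, begin a new one
            flush()
            start, direction, last_move = i, step_dir, i + 1
    flush()
    return runs


def detect_runs(tracks: Sequence, path: MicrotubulePath,
                min_run_length_nm: float = 500.0,
                min_duration_s: float = 2.0,
                max_pause_s: float = 3.0,
                association_radius_nm: float = 320.0,
                min_speed_nm_s: float = 100.0) -> list[Run]:
    """Detect processive runs of tracked particles along one filament.

    Tracks are projected onto the path; samples farther than
    ``association_radius_nm`` from the filament are dropped.  Diffusive and
    static segments are excluded by the per-step speed threshold.
    """
    runs: list[Run] = []
    for tr in tracks:
        t = np.asarray([sp.frame for sp in tr.spots], dtype=float)
        if hasattr(tr, "frame_interval_s") and tr.frame_interval_s is not None:
            t = t * tr.frame_interval_s
        xy = np.array([[sp.x_nm, sp.y_nm] for sp in tr.spots])
        if len(xy) < 2:
            continue
        s, perp = path.project(xy)
        keep = perp <= association_radius_nm
        if keep.sum() < 2:
            continue
        runs.extend(_segment_series(t[keep], s[keep], min_run_length_nm,
                                    min_duration_s, max_pause_s,
                                    min_speed_nm_s, path.id))
    return runs


def run_frequency(runs: Sequence[Run], paths: Sequence[MicrotubulePath],
                  duration_s: float) -> FrequencyResult:
    """Per-microtubule run frequency: n_runs / (L_um * duration).

    Microtubules without any run contribute a frequency of zero.  The
    summary is the mean ± sd of the per-microtubule values.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    by_id = {p.id: p for p in paths}
    if len(by_id) != len(paths):
        raise ValueError("duplicate path ids")
    counts = {pid: 0 for pid in by_id}
    for r in runs:
        if r.path_id not in by_id:
            raise ValueError(f"run references unknown path id {r.path_id}")
        counts[r.path_id] += 1
    ids = sorted(by_id)
    values = [counts[i] / (by_id[i].length_um * duration_s) for i in ids]
    return FrequencyResult(per_mt=np.array(values), mt_ids=np.array(ids))


def normalize_frequency(result: FrequencyResult,
                        reference: FrequencyResult) -> np.ndarray:
    """Fold-change of per-MT frequencies relative to the reference mean."""
    if reference.mean <= 0:
        raise ValueError("reference mean frequency must be > 0")
    return result.per_mt / reference.mean
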