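"""Bait–prey colocalization, comigration and release-latency analysis.

Colocalization is scored per imaging field by one-to-one nearest-pair
matching with a fixed distance cutoff (300 nm by default); the fraction is
matched baits over total baits.  Comigration asks whether a second-channel
track accompanies a processive run for most of its lifetime.  Release
latency measures the delay between prey-signal disappearance and the onset
of motility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ColocResult",
    "ReleaseEvent",
    "match_spots",
    "chance_colocalization",
    "comigration_fraction",
    "release_latency",
    "presence_from_intensity",
    "brute_force_matches",
]


@dataclass(frozen=True)
class ColocResult:
    """Colocalized fraction of bait spots in one field."""

    fraction: float
    n_bait: int
    n_matched: int
    r_max_nm: float
    field_area_um2: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class ReleaseEvent:
    """Outcome of one complex in a real-time release experiment."""

    complex_id: int
    t_disappear_s: float | None
    t_onset_s: float | None
    latency_s: float | None
    outcome: str  # "released" | "comigrated"

    def __post_init__(self):
        if self.outcome not in ("released", "comigrated"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "released" and self.latency_s is not None \
                and self.latency_s < 0:
            raise ValueError("released latency must be >= 0")


def _as_xy(points) -> np.ndarray:
    a = np.asarray(points, dtype=float)
    if a.size == 0:
        return a.reshape(0, 2)
    return np.atleast_2d(a)


def match_spots(bait_spots, prey_spots, r_max_nm: float = 300.0,
                field_area_um2: float | None = None
                ) -> tuple[list[tuple[int, int, float]], ColocResult]:
    """One-to-one greedy matching of bait to prey spots, closest pairs first.

    Parameters
    ----------
    bait_spots, prey_spots : (n, 2) arrays of xy positions in nm.
    r_max_nm : float
        Maximum peak-to-peak distance that counts as colocalized.

    Returns
    -------
    matches : list of (bait_index, prey_index, distance_nm)
    result : ColocResult with fraction = matched bait / total bait.
    """
    bait = _as_xy(bait_spots)
    prey = _as_xy(prey_spots)
    if len(bait) == 0:
        raise ValueError("empty bait set: colocalized fraction undefined")
    matches: list[tuple[int, int, float]] = []
    if len(prey) > 0:
        d = cdist(bait, prey)
        bi, pi = np.nonzero(d <= r_max_nm)
        order = np.argsort(d[bi, pi], kind="stable")
        used_b, used_p = set(), set()
        for k in order:
            b, p = int(bi[k]), int(pi[k])
            if b in used_b or p in used_p:
                continue
            used_b.add(b)
            used_p.add(p)
            matches.append((b, p, float(d[b, p])))
    result = ColocResult(fraction=len(matches) / len(bait), n_bait=len(bait),
                         n_matched=len(matches), r_max_nm=r_max_nm,
                         field_area_um2=field_area_um2)
    return matches, result


def brute_force_matches(bait_spots, prey_spots, r_max_nm: float = 300.0
                        ) -> list[tuple[int, int, float]]:
    """Exhaustive optimal matching oracle for small instances.

    Maximizes the number of matched pairs with distance <= r_max, breaking
    ties by minimal total distance.  Exponential-time; intended for
    verifying the greedy matcher on instances with at most ~8 spots.
    """
    bait = _as_xy(bait_spots)
    prey = _as_xy(prey_spots)
    d = cdist(bait, prey) if len(bait) and len(prey) else np.empty((len(bait), 0))
    feasible = [[p for p in range(d.shape[1]) if d[b, p] <= r_max_nm]
                for b in range(d.shape[0])]

    best: dict = {"count": -1, "dist": math.inf, "pairs": []}

    def recurse(b: int, used: set, pairs: list, total: float):
        if b == len(feasible):
            count = len(pairs)
            if count > best["count"] or (count == best["count"]
                                         and total < best["dist"]):
                best.update(count=count, dist=total, pairs=list(pairs))
            return
        recurse(b + 1, used, pairs, total)  # leave bait b unmatched
        for p in feasible[b]:
            if p in used:
                continue
            used.add(p)
            pairs.append((b, p, float(d[b, p])))
            recurse(b + 1, used, pairs, total + d[b, p])
            pairs.pop()
            used.remove(p)

    recurse(0, set(), [], 0.0)
    return best["pairs"]


def chance_colocalization(prey_density_per_um2: float,
                          r_max_nm: float = 300.0) -> float:
    """Expected random colocalized fraction: 1 - exp(-rho * pi * r^2).

    The probability that a uniformly random prey field of density ``rho``
    (per µm²) places at least one molecule within ``r_max`` of a bait.
    """
    if prey_density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    r_um = r_max_nm / 1000.0
    return 1.0 - math.exp(-prey_density_per_um2 * math.pi * r_um ** 2)


def _trajectory(obj) -> tuple[np.ndarray, np.ndarray]:
    """Extract (times, xy) from a Track or a (times, xy) tuple."""
    if hasattr(obj, "xy_nm") and callable(getattr(obj, "times", None)):
        return np.asarray(obj.times(), dtype=float), np.asarray(obj.xy_nm, dtype=float)
    t, xy = obj
    return np.asarray(t, dtype=float), np.atleast_2d(np.asarray(xy, dtype=float))


def comigration_fraction(runs_a, tracks_b, r_max_nm: float = 300.0,
                         min_overlap_fraction: float = 0.8) -> float:
    """Fraction of channel-A runs that comigrate with a channel-B track.

    A run comigrates when some single B track stays within ``r_max_nm`` of
    the run's moving position for at least ``min_overlap_fraction`` of the
    run's sampled lifetime.  Runs are given as trajectories: Track objects
    or (times, xy) tuples with positions in nm.
    """
    if not runs_a:
        raise ValueError("no runs to score")
    trajs_b = [_trajectory(tb) for tb in tracks_b]
    n_comig = 0
    for ra in runs_a:
        ta, xya = _trajectory(ra)
        comig = False
        for tb, xyb in trajs_b:
            # B positions interpolated at A's sample times, only within B's span
            inside = (ta >= tb[0]) & (ta <= tb[-1])
            if inside.sum() == 0:
                continue
            bx = np.interp(ta, tb, xyb[:, 0])
            by = np.interp(ta, tb, xyb[:, 1])
            near = np.hypot(bx - xya[:, 0], by - xya[:, 1]) <= r_max_nm
            if (near & inside).sum() / len(ta) >= min_overlap_fraction:
                comig = True
                break
        n_comig += comig
    return n_comig / len(runs_a)


def presence_from_intensity(intensity, background: float, noise_sd: float,
                            k: float = 3.0, min_frames: int = 2) -> np.ndarray:
    """Boolean presence series: intensity above background + k*noise for at
    least ``min_frames`` consecutive frames (hysteresis against blinking)."""
    above = np.asarray(intensity, dtype=float) > background + k * noise_sd
    out = np.zeros_like(above)
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_frames:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def release_latency(complex_id: int, prey_presence, frame_interval_s: float,
                    t_onset_s: float | None) -> ReleaseEvent | None:
    """Classify one complex as released or comigrated around motility onset.

    Parameters
    ----------
    prey_presence : bool array
        Per-frame presence of the prey signal at the complex position
        (see :func:`presence_from_intensity`).
    t_onset_s : float or None
        Time of sustained motility onset; None if the complex never moves,
        in which case no event is produced (censored, reported separately).

    Returns
    -------
    ReleaseEvent or None.  Released events carry
    ``latency = onset - disappearance``; comigrated events (prey persists
    through onset) have undefined latency.
    """
    if t_onset_s is None:
        return None
    presence = np.asarray(prey_presence, dtype=bool)
    present_frames = np.nonzero(presence)[0]
    if len(present_frames) == 0:
        return None  # prey never detected; cannot time the release
    # disappearance = end of the last presence frame before/at onset
    t_disappear = (present_frames[-1] + 1) * frame_interval_s
    if t_disappear >= t_onset_s:
        return ReleaseEvent(complex_id=complex_id, t_disappear_s=None,
                            t_onset_s=t_onset_s, latency_s=None,
                            outcome="comigrated")
    return ReleaseEvent(complex_id=complex_id, t_disappear_s=t_disappear,
                        t_onset_s=t_onset_s, latency_s=t_onset_s - t_disappear,
                        outcome="released")
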