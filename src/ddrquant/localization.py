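"""Diffraction-limited spot detection, sub-pixel Gaussian fitting and linking.

Detection runs a difference-of-Gaussians filter and keeps local maxima above
a robust noise threshold; candidates are refined by nonlinear least-squares
fitting of a symmetric 2D Gaussian plus offset; detections are linked into
tracks by greedy nearest-neighbor assignment with gap closing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from skimage.feature import peak_local_max
from skimage.filters import gaussian as gaussian_filter

__all__ = [
    "SpotDetection",
    "Track",
    "SpotFitError",
    "detect_spots",
    "fit_spot",
    "link_tracks",
    "robust_noise_sd",
]


class SpotFitError(RuntimeError):
    """Raised when a candidate cannot be fit to a credible Gaussian spot."""


@dataclass
class SpotDetection:
    """One sub-pixel localization."""

    frame: int
    x_nm: float
    y_nm: float
    amplitude: float
    offset: float
    sigma_nm: float
    residual: float
    channel: str = ""

    @property
    def xy_nm(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm])


@dataclass
class Track:
    """Frame-ordered chain of detections from one channel."""

    spots: list[SpotDetection]
    channel: str = ""
    n_gaps: int = 0
    frame_interval_s: float | None = None
    truth_mt_id: int | None = None

    def __post_init__(self):
        frames = [sp.frame for sp in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([sp.frame for sp in self.spots])

    @property
    def xy_nm(self) -> np.ndarray:
        return np.array([[sp.x_nm, sp.y_nm] for sp in self.spots])

    def times(self) -> np.ndarray:
        dt = self.frame_interval_s if self.frame_interval_s is not None else 1.0
        return self.frames * dt


def robust_noise_sd(image: np.ndarray) -> float:
    """1.4826 * median absolute deviation, a Gaussian-consistent sd estimate."""
    med = np.median(image)
    return float(1.4826 * np.median(np.abs(image - med)))


def detect_spots(image: np.ndarray, threshold_k: float = 5.0,
                 min_separation_px: int = 3,
                 psf_sigma_px: float = 1.1) -> np.ndarray:
    """Find candidate spot pixels as thresholded DoG local maxima.

    Returns an (n, 2) array of (row, col) candidate pixels.  The response
    threshold is ``threshold_k`` times the robust noise sd (1.4826 * MAD) of
    the filtered image.  Candidates closer than ``min_separation_px`` keep
    only the brighter.  A constant image yields an empty list.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be > 0")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    dog = (gaussian_filter(img, psf_sigma_px, preserve_range=True)
           - gaussian_filter(img, 1.6 * psf_sigma_px, preserve_range=True))
    noise = robust_noise_sd(dog)
    if noise == 0.0:
        # noiseless image: any distinctly positive response is a candidate
        if dog.max() <= 0.0:
            return np.empty((0, 2), dtype=int)
        threshold = 1e-6 * dog.max()
    else:
        threshold = threshold_k * noise
    return peak_local_max(dog, min_distance=min_separation_px,
                          threshold_abs=threshold, exclude_border=False)


def _gauss2d_model(params, yy, xx):
    amp, x0, y0, sigma, off = params
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma ** 2)) + off


def fit_spot(image: np.ndarray, candidate, window_px: int = 5,
             pixel_size_nm: float = 160.0,
             sigma_bounds_px: tuple[float, float] = (0.5, 4.0),
             frame: int = 0, channel: str = "") -> SpotDetection:
    """Least-squares fit of amplitude * Gaussian(x0, y0, sigma) + offset.

    ``candidate`` is the (row, col) seed pixel and ``window_px`` the
    half-width of the square fitting window.  Raises :class:`SpotFitError`
    when the window is clipped by the image edge, the optimizer fails, the
    fitted sigma leaves its bounds, or the amplitude is not credibly above
    the fit residual (flat background).
    """
    img = np.asarray(image, dtype=float)
    r, c = int(candidate[0]), int(candidate[1])
    w = int(window_px)
    if r - w < 0 or c - w < 0 or r + w >= img.shape[0] or c + w >= img.shape[1]:
        raise SpotFitError("fitting window clipped by image edge")
    patch = img[r - w:r + w + 1, c - w:c + w + 1]
    if np.ptp(patch) == 0:
        raise SpotFitError("flat window: no spot to fit")
    yy, xx = np.mgrid[r - w:r + w + 1, c - w:c + w + 1].astype(float)

    off0 = float(patch.min())
    amp0 = float(patch[w, w] - off0)
    p0 = [max(amp0, 1e-3), float(c), float(r), 1.2, off0]
    lo = [0.0, c - w, r - w, sigma_bounds_px[0], -np.inf]
    hi = [np.inf, c + w, r + w, sigma_bounds_px[1], np.inf]

    def resid(p):
        return (_gauss2d_model(p, yy, xx) - patch).ravel()

    try:
        res = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf")
    except ValueError as exc:
        raise SpotFitError(f"optimizer failure: {exc}") from exc
    if not res.success:
        raise SpotFitError("fit did not converge")
    amp, x0, y0, sigma, off = res.x
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    if sigma <= sigma_bounds_px[0] * 1.001 or sigma >= sigma_bounds_px[1] * 0.999:
        raise SpotFitError(f"fitted sigma {sigma:.2f} px outside bounds")
    if amp <= max(3.0 * rms, 1e-12):
        raise SpotFitError("amplitude not above residual noise (no spot)")
    # pixel-center convention: center of pixel (r, c) sits at ((c+0.5)px, (r+0.5)px)
    return SpotDetection(frame=frame, x_nm=(x0 + 0.5) * pixel_size_nm,
                         y_nm=(y0 + 0.5) * pixel_size_nm, amplitude=float(amp),
                         offset=float(off), sigma_nm=float(sigma) * pixel_size_nm,
                         residual=rms, channel=channel)


def detect_and_fit(image: np.ndarray, frame: int = 0, threshold_k: float = 5.0,
                   min_separation_px: int = 3, window_px: int = 5,
                   pixel_size_nm: float = 160.0, channel: str = "") -> list[SpotDetection]:
    """Convenience: detect candidates then fit each, dropping failures."""
    spots = []
    for rc in detect_spots(image, threshold_k, min_separation_px):
        try:
            spots.append(fit_spot(image, rc, window_px, pixel_size_nm,
                                  frame=frame, channel=channel))
        except SpotFitError:
            continue
    return spots


def link_tracks(detections: list[SpotDetection], max_disp_nm: float = 640.0,
                max_gap_frames: int = 2,
                frame_interval_s: float | None = None) -> list[Track]:
    """Link detections into tracks by greedy closest-pair-first assignment.

    Per frame, every (active track, new detection) pair within
    ``max_disp_nm`` is considered, closest pairs first, one-to-one; a track
    stays active for up to ``max_gap_frames`` missed frames (gap closing).
    Unassigned detections start new tracks, so the result partitions the
    input.
    """
    by_frame: dict[int, list[SpotDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)

    active: list[dict] = []   # {"spots": [...], "gaps": int}
    done: list[dict] = []
    for f in sorted(by_frame):
        dets = by_frame[f]
        pairs = []
        for ti, tr in enumerate(active):
            gap = f - tr["spots"][-1].frame - 1
            if gap > max_gap_frames:
                continue
            last = tr["spots"][-1].xy_nm
            for di, d in enumerate(dets):
                dist = float(np.hypot(*(d.xy_nm - last)))
                if dist <= max_disp_nm:
                    pairs.append((dist, ti, di))
        pairs.sort(key=lambda p: p[0])
        used_t, used_d = set(), set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = active[ti]
            tr["gaps"] += f - tr["spots"][-1].frame - 1
            tr["spots"].append(dets[di])
        for di, d in enumerate(dets):
            if di not in used_d:
                active.append({"spots": [d], "gaps": 0})
        still = []
        for tr in active:
            if f - tr["spots"][-1].frame > max_gap_frames:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)
    channel = detections[0].channel if detections else ""
    tracks = [Track(spots=tr["spots"], channel=channel, n_gaps=tr["gaps"],
                    frame_interval_s=frame_interval_s) for tr in done]
    tracks.sort(key=lambda t: (t.spots[0].frame, t.spots[0].x_nm, t.spots[0].y_nm))
    return tracks
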