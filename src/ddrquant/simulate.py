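"""Synthetic TIRF experiments with complete ground truth.

Emulates the imaging geometry of an EMCCD-based single-molecule motility /
colocalization assay: 160-nm pixels, 40x40 µm fields, 5-minute movies,
integrated-Gaussian PSF rendering, Poisson shot noise with optional EM
excess noise, and Gaussian read noise.  Every simulator returns both the
rendered data and a truth table so downstream estimators can be validated
by parameter recovery.

Conventions
-----------
Positions are continuous (x, y) in nm.  Pixel (0, 0) is the image origin
with its center at (pixel/2, pixel/2) nm — i.e. pixel ``i`` covers
``[i*px, (i+1)*px)`` nm.  All randomness flows from a single
``numpy.random.Generator``; a fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import erf

from .massphot import MixtureModel
from .motility import MicrotubulePath

__all__ = [
    "SimulationConfig",
    "MovieStack",
    "LabelingModel",
    "MotilityParams",
    "RunRecord",
    "MotilityTruth",
    "BindingParams",
    "BindingEvent",
    "BindingTruth",
    "draw_dye_count",
    "render_frame",
    "simulate_motility_truth",
    "simulate_motility_movie",
    "simulate_binding_truth",
    "simulate_binding_movie",
    "truth_to_tracks",
    "random_microtubule_paths",
    "sample_masses",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and camera parameters of a simulated acquisition.

    Defaults follow the target assay: 40x40 µm field, 160-nm pixels and a
    5-minute movie.  ``photon_rate_per_dye`` is photons emitted per dye per
    second; ``background_photons`` is per pixel per frame.
    """

    field_size_um: tuple[float, float] = (40.0, 40.0)
    pixel_size_nm: float = 160.0
    frame_interval_s: float = 0.5
    n_frames: int = 600
    psf_sigma_nm: float = 170.0
    photon_rate_per_dye: float = 2000.0
    background_photons: float = 10.0
    read_noise_sd: float = 2.0
    em_gain: float = 1.0
    bleach_tau_s: float | None = None
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("pixel_size_nm", "frame_interval_s", "psf_sigma_nm",
                     "photon_rate_per_dye", "em_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.background_photons < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.bleach_tau_s is not None and self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be > 0")
        for dim in self.field_size_um:
            n_px = dim * 1000.0 / self.pixel_size_nm
            if abs(n_px - round(n_px)) > 1e-9:
                raise ValueError("field size must divide into whole pixels")

    @property
    def shape_px(self) -> tuple[int, int]:
        """(rows, cols) = (y, x) image shape."""
        w, h = self.field_size_um
        return (int(round(h * 1000 / self.pixel_size_nm)),
                int(round(w * 1000 / self.pixel_size_nm)))

    @property
    def field_size_nm(self) -> tuple[float, float]:
        return (self.field_size_um[0] * 1000.0, self.field_size_um[1] * 1000.0)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def photons_per_dye_per_frame(self) -> float:
        return self.photon_rate_per_dye * self.frame_interval_s


@dataclass
class MovieStack:
    """A time-ordered image series for one channel, with calibration."""

    frames: np.ndarray  # (n_frames, ny, nx) float
    pixel_size_nm: float
    frame_interval_s: float
    channel: str = ""

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class LabelingModel:
    """Per-monomer labeling probability p for an n-subunit complex."""

    p: float
    n: int = 2

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def prob_at_least_one_dye(self) -> float:
        return 1.0 - (1.0 - self.p) ** self.n


def draw_dye_count(label: LabelingModel, rng: np.random.Generator,
                   size=None) -> np.ndarray | int:
    """Binomial(n, p) dye count per complex."""
    return rng.binomial(label.n, label.p, size=size)


def _integrated_gaussian_1d(edges_lo: np.ndarray, center: float,
                            sigma: float) -> np.ndarray:
    """Integral of a unit 1D Gaussian over [edge, edge + px) per pixel."""
    s = sigma * math.sqrt(2.0)
    hi = np.empty_like(edges_lo)
    hi[:-1] = edges_lo[1:]
    hi[-1] = edges_lo[-1] + (edges_lo[1] - edges_lo[0])
    return 0.5 * (erf((hi - center) / s) - erf((edges_lo - center) / s))


def render_frame(emitters, cfg: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 noise: bool = True) -> np.ndarray:
    """Render one camera frame from a list of point emitters.

    Each emitter contributes an integrated symmetric 2D Gaussian
    (erf-difference per pixel, sigma = ``cfg.psf_sigma_nm``).  With
    ``noise=True`` the photon image is passed through Poisson shot noise,
    EM gain (gamma-distributed excess noise when ``em_gain > 1``) and
    additive Gaussian read noise; the result is clipped at zero.

    Parameters
    ----------
    emitters : sequence of (x_nm, y_nm, photons)
        Emitters outside the field contribute their in-field tail.
    """
    ny, nx = cfg.shape_px
    px = cfg.pixel_size_nm
    img = np.full((ny, nx), float(cfg.background_photons))
    x_edges = np.arange(nx) * px
    y_edges = np.arange(ny) * px
    for x, y, photons in emitters:
        if photons <= 0:
            continue
        gx = _integrated_gaussian_1d(x_edges, float(x), cfg.psf_sigma_nm)
        gy = _integrated_gaussian_1d(y_edges, float(y), cfg.psf_sigma_nm)
        img += float(photons) * np.outer(gy, gx)
    if not noise:
        return img * cfg.em_gain
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    counts = rng.poisson(img).astype(float)
    if cfg.em_gain > 1.0:
        # EM register: gamma(shape=n, scale=gain) has mean g*n, var g^2*n
        # (excess-noise factor 2 relative to scaled shot noise)
        out = np.zeros_like(counts)
        mask = counts > 0
        out[mask] = rng.gamma(counts[mask], cfg.em_gain)
        counts = out
    else:
        counts *= cfg.em_gain
    if cfg.read_noise_sd > 0:
        counts += rng.normal(0.0, cfg.read_noise_sd, counts.shape)
    return np.maximum(counts, 0.0)


# ---------------------------------------------------------------------------
# motility simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotilityParams:
    """Kinetic truth parameters for a motility simulation.

    ``landing_rate_per_um_s`` is the expected number of processive runs per
    µm of filament per second.  Run lengths are ``run_length_min_nm`` plus
    an exponential with mean ``run_length_mean_nm - run_length_min_nm``.
    """

    landing_rate_per_um_s: float
    velocity_mean_nm_s: float = 500.0
    velocity_sd_nm_s: float = 50.0
    run_length_mean_nm: float = 3000.0
    run_length_min_nm: float = 1500.0
    labeling: LabelingModel = field(default_factory=lambda: LabelingModel(p=1.0, n=1))

    def __post_init__(self):
        if self.landing_rate_per_um_s < 0:
            raise ValueError("landing rate must be >= 0")
        if self.velocity_mean_nm_s <= 0 or self.velocity_sd_nm_s < 0:
            raise ValueError("velocity mean must be > 0 and sd >= 0")
        if not 0 <= self.run_length_min_nm <= self.run_length_mean_nm:
            raise ValueError("need 0 <= run_length_min <= run_length_mean")


@dataclass(frozen=True)
class RunRecord:
    """Ground truth for one processive run."""

    mt_id: int
    t_on_s: float
    t_off_s: float
    s_on_nm: float
    s_off_nm: float
    velocity_nm_s: float
    direction: int
    dye_count: int

    @property
    def length_nm(self) -> float:
        return abs(self.s_off_nm - self.s_on_nm)

    def arc_position_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.s_on_nm + self.direction * self.velocity_nm_s * (t - self.t_on_s)


@dataclass
class MotilityTruth:
    """Complete truth tables of a motility simulation."""

    paths: list[MicrotubulePath]
    runs: list[RunRecord]
    landing_rate_per_um_s: float
    duration_s: float

    def runs_on(self, mt_id: int) -> list[RunRecord]:
        return [r for r in self.runs if r.mt_id == mt_id]


def _check_paths_in_field(paths, cfg: SimulationConfig):
    w_nm, h_nm = cfg.field_size_nm
    for p in paths:
        v = p.vertices
        if (v[:, 0].min() < 0 or v[:, 1].min() < 0
                or v[:, 0].max() > w_nm or v[:, 1].max() > h_nm):
            raise ValueError(f"microtubule {p.id} extends outside the field")


def simulate_motility_truth(cfg: SimulationConfig, params: MotilityParams,
                            paths: Sequence[MicrotubulePath],
                            rng: np.random.Generator | None = None) -> MotilityTruth:
    """Draw ground-truth processive runs without rendering a movie.

    Per filament the run count is Poisson with mean ``rate * L_um * T``.
    Landing arc positions and times are placed so each run completes inside
    the filament and the acquisition window, keeping the expected count
    exact (runs longer than the filament or movie are truncated).
    """
    if not paths:
        raise ValueError("need at least one microtubule path")
    _check_paths_in_field(paths, cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    T = cfg.duration_s
    runs: list[RunRecord] = []
    for path in paths:
        n = rng.poisson(params.landing_rate_per_um_s * path.length_um * T)
        for _ in range(n):
            extra = params.run_length_mean_nm - params.run_length_min_nm
            length = params.run_length_min_nm + (rng.exponential(extra) if extra > 0 else 0.0)
            length = min(length, path.length_nm)
            if params.velocity_sd_nm_s > 0:
                v = max(rng.normal(params.velocity_mean_nm_s, params.velocity_sd_nm_s),
                        0.05 * params.velocity_mean_nm_s)
            else:
                v = params.velocity_mean_nm_s
            direction = 1 if rng.random() < 0.5 else -1
            if direction > 0:
                s_on = rng.uniform(0.0, path.length_nm - length)
            else:
                s_on = rng.uniform(length, path.length_nm)
            duration = length / v
            if duration >= T:
                t_on, duration = 0.0, T
                length = v * T
            else:
                t_on = rng.uniform(0.0, T - duration)
            dyes = int(draw_dye_count(params.labeling, rng))
            runs.append(RunRecord(mt_id=path.id, t_on_s=t_on, t_off_s=t_on + duration,
                                  s_on_nm=s_on, s_off_nm=s_on + direction * length,
                                  velocity_nm_s=v, direction=direction,
                                  dye_count=dyes))
    runs.sort(key=lambda r: (r.mt_id, r.t_on_s))
    return MotilityTruth(paths=list(paths), runs=runs,
                         landing_rate_per_um_s=params.landing_rate_per_um_s,
                         duration_s=T)


def simulate_motility_movie(cfg: SimulationConfig, params: MotilityParams,
                            paths: Sequence[MicrotubulePath],
                            rng: np.random.Generator | None = None,
                            noise: bool = True) -> tuple[MovieStack, MotilityTruth]:
    """Render a motility movie plus its complete truth tables."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    truth = simulate_motility_truth(cfg, params, paths, rng)
    path_by_id = {p.id: p for p in truth.paths}
    bleach = {}
    if cfg.bleach_tau_s is not None:
        for i, r in enumerate(truth.runs):
            bleach[i] = np.sort(rng.exponential(cfg.bleach_tau_s, r.dye_count))
    frames = np.empty((cfg.n_frames, *cfg.shape_px))
    for f in range(cfg.n_frames):
        t = f * cfg.frame_interval_s
        emitters = []
        for i, r in enumerate(truth.runs):
            if not (r.t_on_s <= t <= r.t_off_s) or r.dye_count == 0:
                continue
            n_dyes = r.dye_count
            if cfg.bleach_tau_s is not None:
                n_dyes = int(np.sum(bleach[i] > (t - r.t_on_s)))
                if n_dyes == 0:
                    continue
            s = float(r.arc_position_at(t))
            xy = path_by_id[r.mt_id].point_at(s)
            emitters.append((xy[0], xy[1], n_dyes * cfg.photons_per_dye_per_frame))
        frames[f] = render_frame(emitters, cfg, rng=rng, noise=noise)
    movie = MovieStack(frames=frames, pixel_size_nm=cfg.pixel_size_nm,
                       frame_interval_s=cfg.frame_interval_s, channel="motility")
    return movie, truth


def truth_to_tracks(truth: MotilityTruth, cfg: SimulationConfig,
                    localization_noise_nm: float = 20.0,
                    rng: np.random.Generator | None = None) -> list:
    """Convert truth runs to per-run localization tracks (movie-free path).

    Emulates the output of the detection + linking stage: one track per
    labeled run, sampled at the frame interval with isotropic Gaussian
    localization error.  Used for fast large-scale recovery studies where
    rendering full movies would be wasteful.
    """
    from .localization import SpotDetection, Track

    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    path_by_id = {p.id: p for p in truth.paths}
    tracks = []
    for r in truth.runs:
        if r.dye_count == 0:
            continue
        f0 = int(math.ceil(r.t_on_s / cfg.frame_interval_s))
        f1 = int(math.floor(r.t_off_s / cfg.frame_interval_s))
        f1 = min(f1, cfg.n_frames - 1)
        if f1 < f0:
            continue
        frames = np.arange(f0, f1 + 1)
        s = r.arc_position_at(frames * cfg.frame_interval_s)
        xy = np.atleast_2d(path_by_id[r.mt_id].point_at(s))
        if localization_noise_nm > 0:
            xy = xy + rng.normal(0.0, localization_noise_nm, xy.shape)
        spots = [SpotDetection(frame=int(f), x_nm=float(x), y_nm=float(y),
                               amplitude=1.0, offset=0.0,
                               sigma_nm=cfg.psf_sigma_nm, residual=0.0)
                 for f, (x, y) in zip(frames, xy)]
        tracks.append(Track(spots=spots, channel="motility",
                            frame_interval_s=cfg.frame_interval_s,
                            truth_mt_id=r.mt_id))
    return tracks


# ---------------------------------------------------------------------------
# binding simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingParams:
    """Kinetics of prey molecules binding surface-immobilized baits."""

    n_baits: int
    dwell_mean_s: float
    arrival_rate_per_s: float = 0.02
    prey_channel: str = "prey"
    labeling: LabelingModel = field(default_factory=lambda: LabelingModel(p=1.0, n=1))

    def __post_init__(self):
        if self.n_baits < 0:
            raise ValueError("n_baits must be >= 0")
        if self.dwell_mean_s <= 0:
            raise ValueError("dwell mean must be > 0")
        if self.arrival_rate_per_s < 0:
            raise ValueError("arrival rate must be >= 0")


@dataclass(frozen=True)
class BindingEvent:
    bait_id: int
    t_on_s: float
    t_off_s: float
    censored: bool

    @property
    def duration_s(self) -> float:
        return self.t_off_s - self.t_on_s


@dataclass
class BindingTruth:
    """Bait positions and the binding episodes on each bait."""

    bait_xy_nm: np.ndarray  # (n_baits, 2)
    events: list[BindingEvent]
    dwell_mean_s: float
    prey_channel: str = "prey"

    def events_on(self, bait_id: int) -> list[BindingEvent]:
        return [e for e in self.events if e.bait_id == bait_id]


def simulate_binding_truth(cfg: SimulationConfig, params: BindingParams,
                           rng: np.random.Generator | None = None,
                           bait_xy_nm: np.ndarray | None = None) -> BindingTruth:
    """Draw bait positions and exponential binding episodes.

    Episodes on one bait are sequential (non-overlapping); an episode still
    in progress at the end of the movie is truncated there and flagged
    censored.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    w_nm, h_nm = cfg.field_size_nm
    if bait_xy_nm is None:
        bait_xy_nm = np.column_stack([rng.uniform(0, w_nm, params.n_baits),
                                      rng.uniform(0, h_nm, params.n_baits)])
    bait_xy_nm = np.asarray(bait_xy_nm, dtype=float).reshape(-1, 2)
    n = len(bait_xy_nm)
    if n > 1:
        # nearest-neighbor spacing estimate for a Poisson spatial process
        density = n / (w_nm * h_nm)
        mean_nn = 0.5 / math.sqrt(density)
        if mean_nn <= 4 * cfg.psf_sigma_nm:
            warnings.warn("bait density too high: mean nearest-neighbor spacing "
                          f"{mean_nn:.0f} nm <= 4 sigma", stacklevel=2)
    T = cfg.duration_s
    events: list[BindingEvent] = []
    for b in range(n):
        t = 0.0
        while True:
            if params.arrival_rate_per_s == 0:
                break
            t += rng.exponential(1.0 / params.arrival_rate_per_s)
            if t >= T:
                break
            dwell = rng.exponential(params.dwell_mean_s)
            t_off = t + dwell
            censored = t_off > T
            events.append(BindingEvent(bait_id=b, t_on_s=t,
                                       t_off_s=min(t_off, T), censored=censored))
            if censored:
                break
            t = t_off
    return BindingTruth(bait_xy_nm=bait_xy_nm, events=events,
                        dwell_mean_s=params.dwell_mean_s,
                        prey_channel=params.prey_channel)


def simulate_binding_movie(cfg: SimulationConfig, params: BindingParams,
                           rng: np.random.Generator | None = None,
                           noise: bool = True
                           ) -> tuple[dict[str, MovieStack], BindingTruth]:
    """Render a two-channel binding movie: static baits plus dynamic prey."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    truth = simulate_binding_truth(cfg, params, rng)
    n_frames = cfg.n_frames
    ph = cfg.photons_per_dye_per_frame

    bait_emitters = [(x, y, ph) for x, y in truth.bait_xy_nm]
    bait_frames = np.empty((n_frames, *cfg.shape_px))
    prey_frames = np.empty_like(bait_frames)
    dyes = {i: int(draw_dye_count(params.labeling, rng))
            for i in range(len(truth.events))}
    for f in range(n_frames):
        t = f * cfg.frame_interval_s
        bait_frames[f] = render_frame(bait_emitters, cfg, rng=rng, noise=noise)
        emitters = []
        for i, e in enumerate(truth.events):
            if e.t_on_s <= t <= e.t_off_s and dyes[i] > 0:
                x, y = truth.bait_xy_nm[e.bait_id]
                emitters.append((x, y, dyes[i] * ph))
        prey_frames[f] = render_frame(emitters, cfg, rng=rng, noise=noise)
    movies = {
        "bait": MovieStack(bait_frames, cfg.pixel_size_nm, cfg.frame_interval_s, "bait"),
        params.prey_channel: MovieStack(prey_frames, cfg.pixel_size_nm,
                                        cfg.frame_interval_s, params.prey_channel),
    }
    return movies, truth


def random_microtubule_paths(cfg: SimulationConfig, n: int,
                             min_length_um: float = 12.0,
                             max_length_um: float = 25.0,
                             rng: np.random.Generator | None = None,
                             margin_nm: float = 1000.0) -> list[MicrotubulePath]:
    """Straight filaments at random positions/orientations, fully in-field."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    w_nm, h_nm = cfg.field_size_nm
    paths = []
    for i in range(n):
        for _ in range(1000):
            length = rng.uniform(min_length_um, max_length_um) * 1000.0
            theta = rng.uniform(0, math.pi)
            dx, dy = length * math.cos(theta), length * math.sin(theta)
            x0 = rng.uniform(margin_nm, w_nm - margin_nm)
            y0 = rng.uniform(margin_nm, h_nm - margin_nm)
            x1, y1 = x0 + dx, y0 + dy
            if (margin_nm <= x1 <= w_nm - margin_nm
                    and margin_nm <= y1 <= h_nm - margin_nm):
                paths.append(MicrotubulePath(
                    vertices=np.array([[x0, y0], [x1, y1]]), id=i))
                break
        else:
            raise RuntimeError("could not place a filament inside the field")
    return paths


def sample_masses(mixture: MixtureModel, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw mass samples from a skew-normal mixture (multinomial by weight)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    weights = mixture.weights
    counts = rng.multinomial(n, weights / weights.sum())
    parts = [comp.rvs(int(c), rng) for comp, c in zip(mixture.components, counts)
             if c > 0]
    out = np.concatenate(parts) if parts else np.empty(0)
    rng.shuffle(out)
    return out
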