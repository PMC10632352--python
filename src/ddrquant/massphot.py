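"""Mass-photometry calibration and skew-Gaussian mixture deconvolution.

The mass histogram of a landing assay is decomposed into Azzalini
skew-normal components by expectation-maximization; each component is
reported with its distribution mean, spread, shape and population
percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr

__all__ = [
    "SkewComponent",
    "MixtureModel",
    "Calibration",
    "calibrate",
    "fit_mixture",
    "population_percentages",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class SkewComponent:
    """One skew-normal population: location/scale in kDa, Azzalini shape."""

    loc: float
    scale: float
    shape: float
    weight: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def mean(self) -> float:
        """Distribution mean: loc + scale * delta * sqrt(2/pi)."""
        delta = self.shape / math.sqrt(1.0 + self.shape ** 2)
        return self.loc + self.scale * delta * _SQRT_2_OVER_PI

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.loc) / self.scale
        return (math.log(2.0) - math.log(self.scale)
                + stats.norm._logpdf(z) + log_ndtr(self.shape * z))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return stats.skewnorm.rvs(self.shape, loc=self.loc, scale=self.scale,
                                  size=n, random_state=rng)


@dataclass
class MixtureModel:
    """K skew-normal components sorted by location, with fit diagnostics."""

    components: list[SkewComponent]
    log_likelihood: float = float("nan")
    n_samples: int = 0
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.components) < 1:
            raise ValueError("mixture needs at least one component")
        w = sum(c.weight for c in self.components)
        if not math.isclose(w, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError("weights must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        comp = np.stack([(math.log(c.weight) if c.weight > 0 else -np.inf)
                         + c.logpdf(x) for c in self.components])
        return _logsumexp0(comp)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))


def _logsumexp0(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m).sum(axis=0))


@dataclass(frozen=True)
class Calibration:
    """Linear map from ratiometric contrast to molecular mass (kDa)."""

    slope: float
    intercept: float
    residual: float
    standards: tuple

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")

    def contrast_to_mass(self, contrast) -> np.ndarray:
        return self.slope * np.asarray(contrast, dtype=float) + self.intercept


def calibrate(contrast_means, known_masses) -> Calibration:
    """Ordinary least-squares line mapping measured contrast to known mass."""
    c = np.asarray(contrast_means, dtype=float)
    m = np.asarray(known_masses, dtype=float)
    if c.size != m.size or c.size < 2:
        raise ValueError("need >= 2 (contrast, mass) calibration pairs")
    if np.ptp(c) == 0:
        raise ValueError("degenerate calibration: identical contrast values")
    slope, intercept = np.polyfit(c, m, 1)
    resid = float(np.sqrt(np.mean((slope * c + intercept - m) ** 2)))
    return Calibration(slope=float(slope), intercept=float(intercept),
                       residual=resid, standards=tuple(zip(c.tolist(), m.tolist())))


def _weighted_normal_mle(x, r):
    w = r.sum()
    mu = float((r * x).sum() / w)
    sd = float(np.sqrt((r * (x - mu) ** 2).sum() / w))
    return mu, max(sd, 1e-9)


def _comp_nll(params, x, r, fix_shape):
    loc, log_scale = params[0], params[1]
    shape = 0.0 if fix_shape else params[2]
    scale = math.exp(log_scale)
    z = (x - loc) / scale
    ll = -log_scale + stats.norm._logpdf(z) + log_ndtr(shape * z)
    return -(r * ll).sum()


def _m_step_component(x, r, comp: SkewComponent, fix_shape: bool) -> SkewComponent:
    """Maximize the responsibility-weighted log-likelihood of one component."""
    if fix_shape and comp.shape == 0.0:
        mu, sd = _weighted_normal_mle(x, r)
        return SkewComponent(mu, sd, 0.0, comp.weight)
    p0 = [comp.loc, math.log(comp.scale)] + ([] if fix_shape else [comp.shape])
    res = optimize.minimize(_comp_nll, p0, args=(x, r, fix_shape),
                            method="Nelder-Mead",
                            options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-6})
    # keep the better of (old params, optimized params): guarantees EM monotonicity
    if res.fun <= _comp_nll(p0, x, r, fix_shape):
        loc, log_scale = res.x[0], res.x[1]
        shape = 0.0 if fix_shape else float(res.x[2])
        return SkewComponent(float(loc), math.exp(float(log_scale)), shape, comp.weight)
    return comp


def _kmeanspp_locations(x, k, rng):
    locs = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min([(x - l) ** 2 for l in locs], axis=0)
        p = d2 / d2.sum() if d2.sum() > 0 else None
        locs.append(rng.choice(x, p=p))
    return np.sort(np.asarray(locs, dtype=float))


def _em_once(x, k, rng, fix_shape, max_iter, tol):
    locs = _kmeanspp_locations(x, k, rng)
    scale0 = max(float(np.std(x)) / max(k, 1), 1e-6)
    comps = [SkewComponent(float(l), scale0, 0.0, 1.0 / k) for l in locs]
    history = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        log_r = np.stack([np.log(c.weight) + c.logpdf(x) for c in comps])
        log_norm = _logsumexp0(log_r)
        ll = float(log_norm.sum())
        history.append(ll)
        r = np.exp(log_r - log_norm)
        weights = r.mean(axis=1)
        weights = np.maximum(weights, 1e-10)
        weights /= weights.sum()
        comps = [_m_step_component(x, r[j], SkewComponent(c.loc, c.scale, c.shape,
                                                          float(weights[j])),
                                   fix_shape)
                 for j, c in enumerate(comps)]
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
    comps = sorted(comps, key=lambda c: c.loc)
    return MixtureModel(components=comps, log_likelihood=history[-1],
                        n_samples=len(x), ll_history=history)


def fit_mixture(masses, k: int, init_strategy: str = "kmeans++",
                n_restarts: int = 5, seed: int = 0, fix_shape: bool = False,
                max_iter: int = 150, tol: float = 1e-6) -> MixtureModel:
    """Fit a k-component skew-normal mixture by EM with restarts.

    Deterministic given ``seed``.  Components are returned sorted by
    location so that output order is stable under label switching.  The
    log-likelihood history is stored on the model and is nondecreasing.

    Parameters
    ----------
    masses : array-like
        Mass (or calibrated contrast) samples, one per landing event.
    k : int
        Number of populations.
    fix_shape : bool
        Fit symmetric Gaussians (shape pinned to 0).
    """
    x = np.asarray(masses, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if init_strategy != "kmeans++":
        raise ValueError(f"unknown init strategy {init_strategy!r}")
    rng = np.random.default_rng(seed)
    best = None
    errors = []
    for _ in range(n_restarts):
        try:
            model = _em_once(x, k, rng, fix_shape, max_iter, tol)
        except (ValueError, FloatingPointError) as exc:  # degenerate restart
            errors.append(exc)
            continue
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise RuntimeError(f"EM failed to converge in {n_restarts} restarts: {errors}")
    return best


def population_percentages(model: MixtureModel) -> list[int]:
    """Component weights as integer percentages summing exactly to 100.

    Rounding is reconciled by the largest-remainder rule; remainder ties go
    to later components (higher location).
    """
    raw = model.weights * 100.0
    floors = np.floor(raw).astype(int)
    shortfall = 100 - int(floors.sum())
    remainders = raw - floors
    # ties broken toward later components: sort by (remainder, index) descending
    order = sorted(range(len(raw)), key=lambda i: (remainders[i], i), reverse=True)
    out = floors.copy()
    for i in order[:shortfall]:
        out[i] += 1
    return out.tolist()
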