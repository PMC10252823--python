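"""Dietary-niche hypervolumes and Sorensen overlap.

A community's dietary niche is represented as a point cloud in K dimensions
(one per retained basal source): each point is the vector of posterior
median diet proportions of one consumer group in one season.  After pooled
z-standardization the niche region is estimated by a Gaussian product-kernel
density with per-dimension Silverman bandwidths, thresholded to enclose a
target probability mass (default 95%); its volume is computed by importance
sampling and the region is represented by a uniform random point cloud.

Overlap between two regions is the Sorensen index 2 V(intersection) /
(V1 + V2), with the intersection volume estimated by cross-membership of
the two uniform clouds, and a bootstrap confidence interval obtained by
resampling the underlying niche points and rebuilding both hypervolumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "NichePointSet", "OverlapResult", "GaussianHypervolume",
    "assemble_niche_points", "z_transform", "build_hypervolume",
    "sorensen_overlap",
]

log = logging.getLogger(__name__)


@dataclass
class NichePointSet:
    """Dietary-niche points of one area (rows = group x season)."""

    area: str
    points: np.ndarray            # (m, K)
    dimensions: list              # source names
    labels: list | None = None    # (season, taxon_group) per row
    z_params: dict | None = None  # dimension -> (mean, sd) after z-transform


@dataclass
class OverlapResult:
    """Sorensen overlap of two hypervolumes with a bootstrap CI."""

    sorensen: float
    v1: float
    v2: float
    v_intersection: float
    ci95: tuple
    bootstrap_reps: int


def assemble_niche_points(results, area: str = "") -> NichePointSet:
    """One niche point per mixing result: its posterior median diet vector.

    ``results`` are :class:`~isoweb.mixing.MixingResult` objects for one
    area (typically one per taxon group x season); all must share the same
    ordered source list.
    """
    results = list(results)
    if len(results) < 2:
        raise InputError("assemble_niche_points: need >= 2 mixing results")
    dims = list(results[0].sources)
    pts, labels = [], []
    for r in results:
        if list(r.sources) != dims:
            raise InputError(
                f"assemble_niche_points: source sets differ "
                f"({list(r.sources)} vs {dims})")
        pts.append(np.asarray(r.medians, dtype=float))
        labels.append(r.group)
    pts = np.vstack(pts)
    if np.allclose(pts, pts[0]):
        warnings.warn("assemble_niche_points: all medians identical; "
                      "degenerate cloud", stacklevel=2)
    return NichePointSet(area=area, points=pts, dimensions=dims,
                         labels=labels)


def z_transform(point_sets: dict):
    """Standardize all areas' niche points with pooled per-dimension stats.

    The pooled mean and sample SD (n-1) across every area's points define
    one shared transform, so volumes stay comparable between areas.
    Zero-variance dimensions are dropped with a warning.  Returns
    ``(standardized point_sets, z_params)`` where ``z_params`` maps
    dimension name -> (mean, sd).
    """
    areas = list(point_sets)
    dims = point_sets[areas[0]].dimensions
    pooled = np.vstack([point_sets[a].points for a in areas])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [d for d, k in zip(dims, keep) if not k]
        warnings.warn(f"z_transform: zero-variance dimensions dropped: "
                      f"{dropped}", stacklevel=2)
    kept_dims = [d for d, k in zip(dims, keep) if k]
    z_params = {d: (float(m), float(s))
                for d, m, s, k in zip(dims, mean, sd, keep) if k}
    out = {}
    for a in areas:
        ps = point_sets[a]
        pts = (ps.points[:, keep] - mean[keep]) / sd[keep]
        out[a] = NichePointSet(area=ps.area, points=pts,
                               dimensions=kept_dims, labels=ps.labels,
                               z_params=z_params)
    return out, z_params


class GaussianHypervolume:
    """Kernel-density hypervolume estimator.

    Parameters
    ----------
    mass_quantile : float
        Fraction of the kernel-density probability mass the region encloses
        (default 0.95).
    n_samples : int
        Monte-Carlo samples drawn from the KDE mixture for thresholding and
        the importance-sampling volume estimate.
    point_density : float
        Requested uniform cloud points per unit volume (z-units^-d); the
        cloud size is clipped to [200, 20000].
    seed : int or None

    After :meth:`fit`: ``volume_`` (z-units^d), ``cloud_`` (uniform points
    inside the region), ``bandwidth_`` (per-dimension kernel SD),
    ``density_threshold_`` and ``points_`` (the training points).
    """

    def __init__(self, mass_quantile: float = 0.95, n_samples: int = 10_000,
                 point_density: float = 100.0, seed: int | None = None):
        self.mass_quantile = mass_quantile
        self.n_samples = n_samples
        self.point_density = point_density
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"mass_quantile": self.mass_quantile,
                "n_samples": self.n_samples,
                "point_density": self.point_density, "seed": self.seed}

    def set_params(self, **params) -> "GaussianHypervolume":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- kernel density -----------------------------------------------------

    def _density(self, x: np.ndarray) -> np.ndarray:
        """KDE mixture density at points ``x`` (m, d)."""
        data = self.points_
        h = self.bandwidth_
        z = (x[:, None, :] - data[None, :, :]) / h     # (m, n, d)
        logk = -0.5 * (z * z).sum(axis=2)
        norm = (np.sqrt(2.0 * np.pi) ** len(h)) * np.prod(h)
        return np.exp(logk).sum(axis=1) / (len(data) * norm)

    def fit(self, X, y=None) -> "GaussianHypervolume":
        if not (0.0 < self.mass_quantile < 1.0):
            raise InputError("mass_quantile must lie in (0, 1)")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, d = X.shape
        if n < 2 or np.allclose(X, X[0]):
            raise InputError("GaussianHypervolume: need >= 2 distinct "
                             "points")
        if d > 6:
            raise InputError("GaussianHypervolume: at most 6 dimensions")
        sigma = X.std(axis=0, ddof=1)
        if np.any(sigma == 0):
            # degenerate axis: fall back to the pooled spread so the kernel
            # still has full support
            sigma = np.where(sigma == 0, sigma[sigma > 0].mean(), sigma)
        self.points_ = X
        # per-dimension Silverman bandwidth for a Gaussian product kernel
        factor = (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))
        self.bandwidth_ = sigma * factor
        rng = np.random.default_rng(self.seed)
        comp = rng.integers(0, n, size=self.n_samples)
        samples = X[comp] + self.bandwidth_ * rng.standard_normal(
            (self.n_samples, d))
        f = self._density(samples)
        # density threshold enclosing mass_quantile of the KDE mass
        self.density_threshold_ = float(
            np.quantile(f, 1.0 - self.mass_quantile))
        inside = f >= self.density_threshold_
        # importance-sampling volume of {f >= c}: E_f[ 1{f>=c} / f ]
        self.volume_ = float(np.mean(inside / f))
        # uniform cloud inside the region: importance-resample with 1/f
        weights = np.where(inside, 1.0 / f, 0.0)
        weights /= weights.sum()
        n_cloud = int(np.clip(self.point_density * self.volume_, 200,
                              20_000))
        idx = rng.choice(self.n_samples, size=n_cloud, p=weights)
        self.cloud_ = samples[idx]
        return self

    def contains(self, X) -> np.ndarray:
        """Membership of points in the fitted region (f >= threshold)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._density(X) >= self.density_threshold_


def build_hypervolume(points, mass_quantile: float = 0.95,
                      point_density: float = 100.0,
                      seed: int | None = None,
                      n_samples: int = 10_000) -> GaussianHypervolume:
    """Functional wrapper: fit a :class:`GaussianHypervolume` on points."""
    hv = GaussianHypervolume(mass_quantile=mass_quantile,
                             n_samples=n_samples,
                             point_density=point_density, seed=seed)
    return hv.fit(points)


def _intersection_volume(h1: GaussianHypervolume,
                         h2: GaussianHypervolume) -> float:
    frac1 = float(h2.contains(h1.cloud_).mean())
    frac2 = float(h1.contains(h2.cloud_).mean())
    v_int = 0.5 * (frac1 * h1.volume_ + frac2 * h2.volume_)
    return min(v_int, h1.volume_, h2.volume_)


def sorensen_overlap(h1: GaussianHypervolume, h2: GaussianHypervolume,
                     bootstrap_reps: int = 100,
                     seed: int | None = None) -> OverlapResult:
    """Sorensen overlap 2 V(int) / (V1 + V2) of two fitted hypervolumes.

    The intersection volume comes from cross-membership of the two uniform
    clouds.  The 95% CI resamples each hypervolume's niche points with
    replacement, rebuilds both regions and recomputes the index
    (percentile interval over ``bootstrap_reps`` replicates; set to 0 to
    skip).
    """
    if h1.points_.shape[1] != h2.points_.shape[1]:
        raise InputError("sorensen_overlap: dimension mismatch")
    v_int = _intersection_volume(h1, h2)
    sor = 2.0 * v_int / (h1.volume_ + h2.volume_)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(bootstrap_reps):
        try:
            b1 = _refit(h1, rng)
            b2 = _refit(h2, rng)
        except InputError:
            continue   # degenerate resample (all identical points)
        vi = _intersection_volume(b1, b2)
        reps.append(2.0 * vi / (b1.volume_ + b2.volume_))
    if reps:
        lo, hi = np.percentile(reps, [2.5, 97.5])
        ci = (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))
    else:
        ci = (float("nan"), float("nan"))
    return OverlapResult(sorensen=float(sor), v1=h1.volume_, v2=h2.volume_,
                         v_intersection=float(v_int), ci95=ci,
                         bootstrap_reps=len(reps))


def _refit(h: GaussianHypervolume, rng) -> GaussianHypervolume:
    pts = h.points_
    idx = rng.integers(0, len(pts), size=len(pts))
    return GaussianHypervolume(
        mass_quantile=h.mass_quantile, n_samples=h.n_samples,
        point_density=h.point_density,
        seed=int(rng.integers(0, 2 ** 31))).fit(pts[idx])
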