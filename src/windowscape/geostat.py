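"""Empirical semivariogram and exponential model fit.

The semivariance of a bin is half the mean squared difference of the variable
between all point pairs whose great-circle separation falls in the bin.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import least_squares

from ._util import pairwise_haversine_km, validate_coords


@dataclasses.dataclass
class Variogram:
    bin_centers_km: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    lag_width_km: float
    max_dist_km: float

    def __post_init__(self):
        if np.any(self.pair_counts < 0):
            raise ValueError("negative pair count")
        if np.any(self.semivariance[self.pair_counts > 0] < 0):
            raise ValueError("negative semivariance")


def empirical_variogram(values, lons, lats, lag_width_km: float = 50.0,
                        max_dist_km: float | None = None) -> Variogram:
    """Bin pair distances into half-open intervals [k*w, (k+1)*w) and compute
    the semivariance per bin; empty bins get N = 0 and NaN."""
    values = np.asarray(values, dtype=float)
    lons, lats = validate_coords(lons, lats)
    if values.size < 2:
        raise ValueError("need >= 2 locations")
    if lag_width_km <= 0:
        raise ValueError("lag_width_km must be > 0")
    dist = pairwise_haversine_km(lons, lats)
    iu = np.triu_indices(values.size, k=1)
    d = dist[iu]
    sq = (values[iu[0]] - values[iu[1]]) ** 2
    if max_dist_km is None:
        max_dist_km = float(d.max()) + 1e-9
    n_bins = int(np.ceil(max_dist_km / lag_width_km))
    if n_bins < 1:
        n_bins = 1
    keep = d < n_bins * lag_width_km
    if not keep.any():
        warnings.warn("all pairs beyond max_dist_km; variogram is empty")
    idx = np.floor(d[keep] / lag_width_km).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sq[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    gamma[counts == 0] = np.nan
    centers = (np.arange(n_bins) + 0.5) * lag_width_km
    return Variogram(centers, gamma, counts, lag_width_km, n_bins * lag_width_km)


def fit_exponential(vgm: Variogram) -> tuple[float, float, float]:
    """Weighted least-squares fit of gamma(h) = nugget + sill*(1 - exp(-h/range)).

    Weights are the bin pair counts. Returns (nugget, sill, range_km), all
    non-negative.
    """
    ok = (vgm.pair_counts > 0) & np.isfinite(vgm.semivariance)
    if ok.sum() < 4:
        raise ValueError("need >= 4 non-empty bins to fit")
    h = vgm.bin_centers_km[ok]
    g = vgm.semivariance[ok]
    w = np.sqrt(vgm.pair_counts[ok].astype(float))

    def resid(theta):
        nugget, sill, rng = theta
        return w * (nugget + sill * (1.0 - np.exp(-h / rng)) - g)

    level = max(float(np.nanmax(g)), 1e-12)
    x0 = np.array([max(g[0], 1e-9 * level), max(level - g[0], 1e-9 * level),
                   max(h.mean() / 3.0, 1e-6)])
    sol = least_squares(resid, x0, bounds=([0.0, 0.0, 1e-9], np.inf),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"exponential variogram fit failed: {sol.message}")
    nugget, sill, rng = sol.x
    return float(nugget), float(sill), float(rng)
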