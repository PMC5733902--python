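"""Inverse-distance-weighted interpolation of point values onto a raster grid."""
from __future__ import annotations

import dataclasses

import numpy as np

from ._util import haversine_km, validate_coords
from .io_formats import Raster


@dataclasses.dataclass
class IDWConfig:
    power: float = 2.0
    k_nearest: int = 12
    radius_km: float | None = None

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be > 0")
        if self.k_nearest < 1:
            raise ValueError("k_nearest must be >= 1")


def idw_interpolate(lons, lats, values, template: Raster,
                    config: IDWConfig | None = None) -> Raster:
    """IDW onto the template grid: cell value = sum(w_i v_i) / sum(w_i) with
    w_i = d_i^(-p) over the k nearest points (within the search radius when
    one is set). A cell whose center coincides with a data point gets that
    point's value exactly; cells with no usable point become NoData.
    """
    if config is None:
        config = IDWConfig()
    lons, lats = validate_coords(lons, lats)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    lons, lats, values = lons[ok], lats[ok], values[ok]
    shape = template.data.shape
    out = np.full(shape, np.nan)
    if values.size == 0:
        return Raster(out, template.xllcorner, template.yllcorner,
                      template.cellsize, nodata=template.nodata)
    glon, glat = template.cell_centers()
    flat_lon = glon.reshape(-1)
    flat_lat = glat.reshape(-1)
    # (cells, points) distance matrix; grids here are modest
    d = haversine_km(flat_lon[:, None], flat_lat[:, None],
                     lons[None, :], lats[None, :])
    k = min(config.k_nearest, values.size)
    part = np.argpartition(d, k - 1, axis=1)[:, :k]
    rows = np.arange(d.shape[0])[:, None]
    dk = d[rows, part]
    vk = values[part]
    if config.radius_km is not None:
        mask = dk > config.radius_km
        dk = np.where(mask, np.nan, dk)
    exact = dk <= 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        w = dk ** (-config.power)
    w[~np.isfinite(w)] = 0.0
    flat = np.full(d.shape[0], np.nan)
    has_exact = exact.any(axis=1)
    if has_exact.any():
        first = np.argmax(exact, axis=1)
        flat[has_exact] = vk[has_exact, first[has_exact]]
    wsum = w.sum(axis=1)
    usable = ~has_exact & (wsum > 0)
    flat[usable] = (w * vk).sum(axis=1)[usable] / wsum[usable]
    out = flat.reshape(shape)
    return Raster(out, template.xllcorner, template.yllcorner,
                  template.cellsize, nodata=template.nodata)
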