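"""Synthetic landscapes and microsatellite genotypes with known ground truth.

Landscapes are smooth random fields (optionally with a low-conductance
barrier strip); genotypes come from a forward-in-time Wright-Fisher
island/stepping-stone model whose pairwise migration decays exponentially
with the commute distance over a chosen conductance surface, with stepwise
(+/-1 repeat) microsatellite mutation.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import GenotypeTable, Raster
from .resistance import (SCENARIOS, build_graph, commute_distance,
                         normalize_matrix, scenario_conductance, snap_to_node)

RASTER_ROLES = ("temperature", "elevation", "pine_density")


@dataclasses.dataclass
class SimConfig:
    """Configuration of one synthetic dataset."""

    n_rows: int = 24
    n_cols: int = 36
    cellsize_deg: float = 0.25
    xllcorner: float = -9.5
    yllcorner: float = 36.0
    gradients: dict = dataclasses.field(default_factory=lambda: {
        "temperature": "linear-x", "elevation": "linear-y", "pine_density": "linear-y"})
    driver: str | None = "T"          # scenario whose conductance drives migration
    barrier: bool = True              # carve a resistant strip into the driver raster
    barrier_frac: tuple[float, float] = (0.48, 0.52)
    n_demes: int = 24
    deme_size: int = 80               # diploid individuals per WF deme
    sample_per_deme: int = 6
    n_loci: int = 20
    mutation_rate: float = 0.005      # stepwise, per gene copy per generation
    migration_rate: float = 0.05      # total emigration probability per copy
    commute_theta: float = 0.15       # decay scale of migration vs normalized commute
    n_generations: int = 400
    founder_allele: int = 100
    min_deme_separation_cells: float = 2.0
    coord_jitter: float = 0.4         # uniform jitter within the deme cell,
    seed: int = 0                     # as a fraction of cellsize (< 0.5)

    def __post_init__(self):
        for name, v in (("n_rows", self.n_rows), ("n_cols", self.n_cols),
                        ("n_demes", self.n_demes), ("deme_size", self.deme_size),
                        ("sample_per_deme", self.sample_per_deme),
                        ("n_loci", self.n_loci),
                        ("n_generations", self.n_generations)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.mutation_rate <= 0.01:
            raise ValueError("mutation_rate must be in (0, 0.01]")
        if not 0.0 <= self.migration_rate < 1.0:
            raise ValueError("migration_rate must be in [0, 1)")
        if self.driver is not None and self.driver not in SCENARIOS:
            raise ValueError(f"unknown driver scenario {self.driver!r}")


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    sigma = max(min(shape) / 5.0, 1.0)
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _gradient_field(shape: tuple[int, int], spec: str,
                    rng: np.random.Generator) -> np.ndarray:
    rows, cols = shape
    if spec == "random":
        return _smooth_field(shape, rng)
    if spec == "linear-x":
        base = np.tile(np.linspace(-1.0, 1.0, cols), (rows, 1))
    elif spec == "linear-y":
        base = np.tile(np.linspace(-1.0, 1.0, rows)[:, None], (1, cols))
    elif spec == "radial":
        r = np.hypot(*np.meshgrid(np.linspace(-1, 1, cols), np.linspace(-1, 1, rows)))
        base = 1.0 - r
    else:
        raise ValueError(f"unknown gradient spec {spec!r}")
    base = (base - base.mean()) / base.std()
    return base + 0.3 * _smooth_field(shape, rng)


def correlated_field(base: np.ndarray, rho: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth field with target correlation `rho` to `base`."""
    indep = _smooth_field(base.shape, rng)
    b = (base - base.mean()) / base.std()
    i = (indep - indep.mean()) / indep.std()
    # orthogonalize the independent part so the mixing is exact in-sample
    i = i - (i.reshape(-1) @ b.reshape(-1)) / (b.reshape(-1) @ b.reshape(-1)) * b
    i = i / i.std()
    return rho * b + np.sqrt(max(0.0, 1.0 - rho ** 2)) * i


def simulate_landscape(cfg: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> dict[str, Raster]:
    """Temperature, elevation and pine-density rasters.

    When `cfg.barrier` is set and a driver scenario is chosen, a vertical
    strip of the driver's raster is pushed to its resistant extreme so that
    the strip's conductance sits at the rescaling floor.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    fields = {role: _gradient_field(shape, cfg.gradients.get(role, "random"), rng)
              for role in RASTER_ROLES}
    if cfg.barrier and cfg.driver is not None:
        scenario = SCENARIOS[cfg.driver]
        field = fields[scenario.raster_role]
        lo = int(cfg.barrier_frac[0] * cfg.n_cols)
        hi = max(lo + 1, int(cfg.barrier_frac[1] * cfg.n_cols))
        span = field.max() - field.min()
        extreme = (field.min() - 0.5 * span if scenario.high_is_conductive
                   else field.max() + 0.5 * span)
        field[:, lo:hi] = extreme
    return {role: Raster(fields[role], cfg.xllcorner, cfg.yllcorner,
                         cfg.cellsize_deg, units=role)
            for role in RASTER_ROLES}


def driver_conductance(cfg: SimConfig, rasters: dict[str, Raster]) -> Raster:
    """Conductance surface used for migration: the driver scenario's surface,
    or a uniform surface when there is no driver (null model)."""
    if cfg.driver is None:
        flat = np.ones((cfg.n_rows, cfg.n_cols))
        return Raster(flat, cfg.xllcorner, cfg.yllcorner, cfg.cellsize_deg,
                      units="conductance")
    scenario = SCENARIOS[cfg.driver]
    return scenario_conductance(rasters[scenario.raster_role], scenario)


def place_demes(cfg: SimConfig, conductance: Raster,
                rng: np.random.Generator) -> np.ndarray:
    """(n_demes, 2) row/col of deme cells.

    Demes sit on an evenly spaced (lightly jittered) grid, balanced across
    the two sides of the barrier strip when one is present, so that every
    replicate carries cross-barrier signal and no spurious directional
    clustering. Cells at the conductance floor (the barrier) are avoided.
    """
    valid = np.isfinite(conductance.data)
    floor = np.nanmin(conductance.data)
    habitable = valid & (conductance.data > floor + 1e-12)
    if habitable.sum() < cfg.n_demes:
        habitable = valid
    if cfg.barrier and cfg.driver is not None:
        mid = int(0.5 * (cfg.barrier_frac[0] + cfg.barrier_frac[1]) * cfg.n_cols)
        west = habitable.copy()
        west[:, mid:] = False
        east = habitable.copy()
        east[:, :mid] = False
        half = cfg.n_demes // 2
        return np.vstack([
            _grid_cells(west, half, rng),
            _grid_cells(east, cfg.n_demes - half, rng),
        ])
    return _grid_cells(habitable, cfg.n_demes, rng)


def _grid_cells(mask: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k cells on a regular grid over the mask's bounding box (jitter of up to
    one cell), snapped to the nearest habitable cell."""
    cells = np.argwhere(mask)
    if cells.shape[0] < k:
        raise ValueError("not enough habitable cells for the requested demes")
    r0, c0 = cells.min(axis=0)
    r1, c1 = cells.max(axis=0)
    # grid layout close to the box aspect ratio
    n_rows = max(1, int(round(np.sqrt(k * (r1 - r0 + 1) / (c1 - c0 + 1)))))
    n_cols = int(np.ceil(k / n_rows))
    rr = np.linspace(r0 + 0.5, r1 - 0.5, n_rows) if n_rows > 1 else [(r0 + r1) / 2]
    cc = np.linspace(c0 + 0.5, c1 - 0.5, n_cols) if n_cols > 1 else [(c0 + c1) / 2]
    targets = [(r, c) for r in rr for c in cc][:k]
    chosen: list[tuple[int, int]] = []
    taken = set()
    for r, c in targets:
        jr = r + rng.uniform(-1.0, 1.0)
        jc = c + rng.uniform(-1.0, 1.0)
        d2 = (cells[:, 0] - jr) ** 2 + (cells[:, 1] - jc) ** 2
        for idx in np.argsort(d2):
            cand = (int(cells[idx, 0]), int(cells[idx, 1]))
            if cand not in taken:
                taken.add(cand)
                chosen.append(cand)
                break
    return np.array(chosen)



def _cell_lonlat(raster: Raster, row: int, col: int) -> tuple[float, float]:
    lon = raster.xllcorner + (col + 0.5) * raster.cellsize
    lat = raster.yllcorner + (raster.n_rows - 1 - row + 0.5) * raster.cellsize
    return lon, lat


def migration_matrix(cfg: SimConfig, commute: np.ndarray) -> np.ndarray:
    """Row-stochastic migration matrix: off-diagonal proportional to
    exp(-normalized commute / theta), total emigration = migration_rate."""
    d = cfg.n_demes
    if not np.all(np.isfinite(commute)):
        raise ValueError("demes are disconnected on the conductance surface")
    if d == 1:
        return np.ones((1, 1))
    cnorm = normalize_matrix(commute) if commute.max() > commute.min() else \
        np.zeros_like(commute)
    w = np.exp(-cnorm / cfg.commute_theta)
    np.fill_diagonal(w, 0.0)
    m = np.zeros((d, d))
    for i in range(d):
        total = w[i].sum()
        if total > 0:
            m[i] = cfg.migration_rate * w[i] / total
        m[i, i] = 1.0 - m[i].sum()
    return m


def _wright_fisher(cfg: SimConfig, mig: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Forward WF with stepwise mutation; returns final allele pools of shape
    (n_demes, n_loci, 2 * deme_size)."""
    d, loci, copies = cfg.n_demes, cfg.n_loci, 2 * cfg.deme_size
    # shared ancestral pool with standing diversity (+/- 10 repeats around the
    # founder allele); drift then differentiates demes much faster than the
    # slow stepwise mutational input alone would
    ancestral = rng.integers(cfg.founder_allele - 10, cfg.founder_allele + 11,
                             size=(loci, copies)).astype(np.int32)
    pool = np.broadcast_to(ancestral, (d, loci, copies)).copy()
    cum = np.cumsum(mig, axis=1)
    for _ in range(cfg.n_generations):
        u = rng.random((d, loci, copies))
        src = np.empty((d, loci, copies), dtype=np.int64)
        for i in range(d):
            src[i] = np.searchsorted(cum[i], u[i])
        pick = rng.integers(0, copies, size=(d, loci, copies))
        locus_idx = np.broadcast_to(np.arange(loci)[None, :, None], src.shape)
        pool = pool[src, locus_idx, pick]
        mut = rng.random(pool.shape) < cfg.mutation_rate
        if mut.any():
            steps = rng.choice((-1, 1), size=int(mut.sum()))
            pool = pool.copy()
            pool[mut] += steps.astype(np.int32)
    return pool


def simulate_genotypes(cfg: SimConfig, conductance: Raster,
                       rng: np.random.Generator | None = None
                       ) -> GenotypeTable:
    """Simulate a genotype table on the given conductance surface.

    Demes are placed on valid cells; migration between demes is proportional
    to exp(-commute distance / theta); after `n_generations` of WF evolution
    `sample_per_deme` diploid individuals are drawn per deme.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    deme_cells = place_demes(cfg, conductance, rng)
    graph = build_graph(conductance, 8)
    nodes = [snap_to_node(graph, *_cell_lonlat(conductance, r, c))
             for r, c in deme_cells]
    commute = commute_distance(graph, nodes=nodes)
    mig = migration_matrix(cfg, commute)
    pool = _wright_fisher(cfg, mig, rng)
    ids, demes, lons, lats = [], [], [], []
    calls = np.zeros((cfg.n_demes * cfg.sample_per_deme, cfg.n_loci, 2),
                     dtype=np.int64)
    k = 0
    jit = cfg.coord_jitter * conductance.cellsize
    for i, (r, c) in enumerate(deme_cells):
        lon, lat = _cell_lonlat(conductance, int(r), int(c))
        picks = rng.choice(2 * cfg.deme_size,
                           size=2 * cfg.sample_per_deme, replace=False)
        for s in range(cfg.sample_per_deme):
            ids.append(f"sim{i:02d}_{s:02d}")
            demes.append(f"deme{i:02d}")
            # jitter stays inside the deme cell, so resistance distances
            # (cell-level) are unaffected while geographic distances vary
            lons.append(lon + jit * (2.0 * rng.random() - 1.0))
            lats.append(lat + jit * (2.0 * rng.random() - 1.0))
            calls[k, :, 0] = pool[i, :, picks[2 * s]]
            calls[k, :, 1] = pool[i, :, picks[2 * s + 1]]
            k += 1
    return GenotypeTable(ids, demes, np.array(lons), np.array(lats),
                         [f"L{j:02d}" for j in range(cfg.n_loci)], calls)


def simulate_dataset(cfg: SimConfig) -> tuple[dict[str, Raster], GenotypeTable]:
    """Landscape rasters plus a genotype table driven by the configured
    scenario (or uniform migration when driver is None). Deterministic for a
    given config/seed."""
    rng = np.random.default_rng(cfg.seed)
    rasters = simulate_landscape(cfg, rng)
    conductance = driver_conductance(cfg, rasters)
    table = simulate_genotypes(cfg, conductance, rng)
    return rasters, table
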