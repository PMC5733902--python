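"""Multi-scale, multi-site sliding-window resampling: window generation, the
per-window partial-Mantel/support analysis, per-scale aggregation, the
per-individual support surface, and environmental-heterogeneity comparisons.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import haversine_km
from .io_formats import Raster, RunConfig
from .matrix_stats import (CommonalityResult, MantelResult, SupportDecision,
                           commonality, mantel, partial_mantel,
                           support_criterion)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class Window:
    """A circular study area centered on a sampling location."""

    window_id: str
    center_id: str
    center_lon: float
    center_lat: float
    diameter_km: float
    member_ids: list[str]
    n_demes: int

    @property
    def radius_km(self) -> float:
        return self.diameter_km / 2.0

    @property
    def n_individuals(self) -> int:
        return len(self.member_ids)


@dataclasses.dataclass
class WindowResult:
    window: Window
    ibd: MantelResult | None
    per_hypothesis: dict[str, tuple[MantelResult, MantelResult, SupportDecision]]
    commonality: CommonalityResult | None
    testable: bool
    reason: str = ""


@dataclasses.dataclass
class ScaleSummary:
    diameter_km: float
    n_windows: int
    support_pct: dict[str, float]
    mean_r_supported: dict[str, float]
    n_supported: dict[str, int]
    ibd_significant_pct: float


def generate_windows(locations: pd.DataFrame, diameters_km: Sequence[float],
                     individuals: pd.DataFrame, min_demes: int = 3
                     ) -> tuple[list[Window], list[Window]]:
    """One candidate window per (location, diameter); windows gathering fewer
    than `min_demes` demes are dropped.

    `locations` needs columns location_id, lon, lat; `individuals` needs
    individual_id, deme_id, lon, lat. Membership is great-circle distance
    from the center <= diameter / 2. Returns (kept, dropped).
    """
    for col in ("location_id", "lon", "lat"):
        if col not in locations.columns:
            raise ValueError(f"locations missing column {col!r}")
    for col in ("individual_id", "deme_id", "lon", "lat"):
        if col not in individuals.columns:
            raise ValueError(f"individuals missing column {col!r}")
    ind_lon = individuals["lon"].to_numpy(dtype=float)
    ind_lat = individuals["lat"].to_numpy(dtype=float)
    ind_ids = individuals["individual_id"].tolist()
    ind_demes = individuals["deme_id"].tolist()
    kept: list[Window] = []
    dropped: list[Window] = []
    for _, loc in locations.iterrows():
        dist = haversine_km(loc["lon"], loc["lat"], ind_lon, ind_lat)
        for d in diameters_km:
            inside = dist <= d / 2.0
            members = [i for i, ok in zip(ind_ids, inside) if ok]
            demes = {dm for dm, ok in zip(ind_demes, inside) if ok}
            w = Window(f"{loc['location_id']}_d{int(round(d))}",
                       str(loc["location_id"]), float(loc["lon"]),
                       float(loc["lat"]), float(d), members, len(demes))
            if len(demes) >= min_demes:
                kept.append(w)
            else:
                log.debug("window %s dropped: %d demes < %d", w.window_id,
                          len(demes), min_demes)
                dropped.append(w)
    if not kept:
        warnings.warn("no windows satisfy the min_demes filter")
    return kept, dropped


def window_seed(global_seed: int, window_id: str) -> int:
    """Deterministic per-window seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(window_id.encode())) % (2 ** 32)


def _subset(matrix: np.ndarray, labels: Sequence[str],
            wanted: Sequence[str]) -> np.ndarray:
    pos = {lab: k for k, lab in enumerate(labels)}
    idx = np.array([pos[w] for w in wanted], dtype=int)
    return np.asarray(matrix, dtype=float)[np.ix_(idx, idx)]


def run_window(window: Window, g: np.ndarray, ibd: np.ndarray,
               ibr: Mapping[str, np.ndarray], labels: Sequence[str],
               config: RunConfig, with_commonality: bool | None = None
               ) -> WindowResult:
    """Partial Mantel IBR|IBD and IBD|IBR per scenario on the member-subset
    matrices, plus a simple Mantel for IBD; matrices are label-subsets of the
    global matrices, never recomputed."""
    if with_commonality is None:
        with_commonality = config.commonality
    members = window.member_ids
    if len(members) < 4:
        return WindowResult(window, None, {}, None, False, "fewer than 4 members")
    gs = _subset(g, labels, members)
    ds = _subset(ibd, labels, members)
    seed = window_seed(config.seed, window.window_id)
    try:
        ibd_res = mantel(gs, ds, config.n_permutations, seed=seed)
    except ValueError as exc:
        return WindowResult(window, None, {}, None, False, f"untestable: {exc}")
    per_hyp = {}
    for name in config.scenarios:
        xs = _subset(ibr[name], labels, members)
        if not np.all(np.isfinite(xs)):
            return WindowResult(window, None, {}, None, False,
                                f"untestable: non-finite {name} distances")
        try:
            ibr_given_ibd = partial_mantel(gs, xs, ds, config.n_permutations,
                                           seed=seed, label="IBD")
            ibd_given_ibr = partial_mantel(gs, ds, xs, config.n_permutations,
                                           seed=seed, label=name)
        except ValueError as exc:
            return WindowResult(window, None, {}, None, False, f"untestable: {exc}")
        decision = support_criterion(ibr_given_ibd.p, ibd_given_ibr.p,
                                     config.alpha, hypothesis=name)
        per_hyp[name] = (ibr_given_ibd, ibd_given_ibr, decision)
    comm = None
    if with_commonality:
        comm = commonality(gs, [_subset(ibr[n], labels, members)
                                for n in config.scenarios],
                           labels=list(config.scenarios))
    return WindowResult(window, ibd_res, per_hyp, comm, True)


def run_all_windows(windows: Sequence[Window], g, ibd, ibr, labels,
                    config: RunConfig) -> list[WindowResult]:
    return [run_window(w, g, ibd, ibr, labels, config) for w in windows]


def summarize_by_scale(results: Sequence[WindowResult],
                       scenarios: Sequence[str],
                       alpha: float = 0.05) -> list[ScaleSummary]:
    """Per diameter: percent of testable windows supporting each hypothesis,
    mean partial-Mantel r among supported windows, and IBD significance."""
    by_scale: dict[float, list[WindowResult]] = {}
    for res in results:
        by_scale.setdefault(res.window.diameter_km, []).append(res)
    out = []
    for d in sorted(by_scale):
        testable = [r for r in by_scale[d] if r.testable]
        n = len(testable)
        support_pct: dict[str, float] = {}
        mean_r: dict[str, float] = {}
        n_supported: dict[str, int] = {}
        for s in scenarios:
            if n == 0:
                support_pct[s] = float("nan")
                mean_r[s] = float("nan")
                n_supported[s] = 0
                continue
            supported = [r for r in testable if r.per_hypothesis[s][2].supported]
            n_supported[s] = len(supported)
            support_pct[s] = 100.0 * len(supported) / n
            mean_r[s] = (float(np.mean([r.per_hypothesis[s][0].r for r in supported]))
                         if supported else float("nan"))
        ibd_pct = (100.0 * sum(r.ibd.p < alpha for r in testable) / n
                   if n else float("nan"))
        out.append(ScaleSummary(d, n, support_pct, mean_r, n_supported, ibd_pct))
    return out


def scale_summary_frame(summaries: Sequence[ScaleSummary],
                        scenarios: Sequence[str]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"diameter_km": s.diameter_km, "n_windows": s.n_windows,
               "ibd_significant_pct": s.ibd_significant_pct}
        for name in scenarios:
            row[f"support_pct_{name}"] = s.support_pct[name]
            row[f"mean_r_{name}"] = s.mean_r_supported[name]
            row[f"n_supported_{name}"] = s.n_supported[name]
        rows.append(row)
    return pd.DataFrame(rows)


def support_surface(results: Sequence[WindowResult],
                    individual_ids: Sequence[str],
                    scenarios: Sequence[str],
                    scale_band_km: tuple[float, float] = (220.0, 600.0)
                    ) -> pd.DataFrame:
    """Per individual and hypothesis: supported windows containing the
    individual / testable windows containing it, over the scale band.
    Individuals in no testable window get NaN."""
    lo, hi = scale_band_km
    in_band = [r for r in results
               if r.testable and lo <= r.window.diameter_km <= hi]
    pos = {iid: k for k, iid in enumerate(individual_ids)}
    n = len(individual_ids)
    testable_count = np.zeros(n)
    supported_count = {s: np.zeros(n) for s in scenarios}
    for r in in_band:
        idx = [pos[i] for i in r.window.member_ids if i in pos]
        testable_count[idx] += 1
        for s in scenarios:
            if r.per_hypothesis[s][2].supported:
                supported_count[s][idx] += 1
    out = pd.DataFrame({"individual_id": list(individual_ids)})
    with np.errstate(invalid="ignore", divide="ignore"):
        for s in scenarios:
            vals = supported_count[s] / testable_count
            vals[testable_count == 0] = np.nan
            out[s] = vals
    return out


def env_heterogeneity(results: Sequence[WindowResult], conductance: Raster,
                      scenario: str) -> pd.DataFrame:
    """Per scale, mean SD (population) of raster values over the cells whose
    centers fall inside the circle, split by supported vs non-supported."""
    lon, lat = conductance.cell_centers()
    vals = conductance.data
    valid = np.isfinite(vals)
    per_window = []
    for r in results:
        if not r.testable:
            continue
        dist = haversine_km(r.window.center_lon, r.window.center_lat, lon, lat)
        inside = (dist <= r.window.radius_km) & valid
        sd = float(np.std(vals[inside])) if inside.any() else float("nan")
        per_window.append((r.window.diameter_km,
                           r.per_hypothesis[scenario][2].supported, sd))
    df = pd.DataFrame(per_window, columns=["diameter_km", "supported", "sd"])
    rows = []
    for d, grp in df.groupby("diameter_km"):
        rows.append({
            "diameter_km": d,
            "mean_sd_supported": grp.loc[grp.supported, "sd"].mean(),
            "mean_sd_unsupported": grp.loc[~grp.supported, "sd"].mean(),
            "n_supported": int(grp.supported.sum()),
            "n_unsupported": int((~grp.supported).sum()),
        })
    return pd.DataFrame(rows)


def window_sd(window: Window, raster: Raster) -> float:
    """Population SD of valid raster cells inside one window (NaN if none)."""
    lon, lat = raster.cell_centers()
    dist = haversine_km(window.center_lon, window.center_lat, lon, lat)
    inside = (dist <= window.radius_km) & np.isfinite(raster.data)
    if not inside.any():
        return float("nan")
    return float(np.std(raster.data[inside]))
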