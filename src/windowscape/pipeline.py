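"""End-to-end convenience: genotype table + rasters -> distance matrices ->
windows -> per-scale summaries. Thin glue over the other modules, used by the
CLI and by the end-to-end tests."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genetics import bray_curtis, encode_alleles
from .io_formats import GenotypeTable, Raster, RunConfig
from .resampling import (ScaleSummary, Window, WindowResult, generate_windows,
                         run_all_windows, summarize_by_scale)
from .resistance import (SCENARIOS, build_graph, commute_distance,
                         geographic_distance, normalize_matrix,
                         scenario_conductance)


@dataclasses.dataclass
class AnalysisMatrices:
    labels: list[str]
    genetic: np.ndarray
    ibd: np.ndarray
    ibr: dict[str, np.ndarray]


def build_matrices(table: GenotypeTable, rasters: dict[str, Raster],
                   config: RunConfig) -> AnalysisMatrices:
    """Genetic (Bray-Curtis), geographic (normalized great-circle) and
    per-scenario resistance (normalized commute) matrices for all
    individuals, computed once on the full extent."""
    am = encode_alleles(table)
    g = bray_curtis(am)
    ibd = normalize_matrix(geographic_distance(table.lon, table.lat))
    lonlats = list(zip(table.lon, table.lat))
    ibr = {}
    for name in config.scenarios:
        scenario = SCENARIOS[name]
        cond = scenario_conductance(rasters[scenario.raster_role], scenario)
        graph = build_graph(cond, config.connectivity)
        commute = commute_distance(graph, lonlats=lonlats)
        ibr[name] = normalize_matrix(commute)
    return AnalysisMatrices(list(table.individual_id), g, ibd, ibr)


def locations_frame(table: GenotypeTable) -> pd.DataFrame:
    """One row per distinct sampling location (deme)."""
    df = pd.DataFrame({"location_id": table.deme_id, "lon": table.lon,
                       "lat": table.lat})
    return df.groupby("location_id", as_index=False).first()


def individuals_frame(table: GenotypeTable) -> pd.DataFrame:
    return pd.DataFrame({"individual_id": table.individual_id,
                         "deme_id": table.deme_id,
                         "lon": table.lon, "lat": table.lat})


def run_pipeline(table: GenotypeTable, rasters: dict[str, Raster],
                 config: RunConfig
                 ) -> tuple[list[Window], list[WindowResult], list[ScaleSummary]]:
    matrices = build_matrices(table, rasters, config)
    windows, _ = generate_windows(locations_frame(table), config.diameters_km,
                                  individuals_frame(table), config.min_demes)
    results = run_all_windows(windows, matrices.genetic, matrices.ibd,
                              matrices.ibr, matrices.labels, config)
    summaries = summarize_by_scale(results, config.scenarios, config.alpha)
    return windows, results, summaries
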