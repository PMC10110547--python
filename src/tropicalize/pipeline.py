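"""End-to-end orchestration of the tropicalisation analysis.

``run_pipeline`` wires the stages together — simulate (or accept) tables,
zone the sites, identify functional groups, compute footprints and leading
edges, kernel niche metrics, and driver tests — and returns every
intermediate artifact in one bundle.  The numbered scripts under
``analysis/``, the test suite and the acceptance script all go through
this module so the computation has a single home.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from .config import ScenarioConfig, default_scenario
from .synthetic import generate_metacommunity, GroundTruth
from .zoning import zone_survey
from .grouping import gower_distance, cluster_species, FunctionalGrouping
from .niche import pcoa_cailliez, site_group_niche_metrics, TraitSpace
from .footprint import footprints, zone_estimates, leading_edge
from .drivers import (build_driver_table, leading_edge_driver_tests,
                      footprint_niche_correlations)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    survey: pd.DataFrame
    traits: pd.DataFrame
    truth: GroundTruth | None
    zones: dict
    grouping: FunctionalGrouping
    space: TraitSpace
    footprint_table: pd.DataFrame
    zone_estimates: pd.DataFrame
    edges: pd.DataFrame
    niche_metrics: pd.DataFrame
    correlations: pd.DataFrame
    driver_table: pd.DataFrame
    driver_tests: pd.DataFrame
    timings: dict = field(default_factory=dict)


def run_pipeline(
    cfg: ScenarioConfig | None = None,
    survey: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    *,
    k: int | None = None,
    n_zones: int | None = None,
    grid_cells: int = 150,
    min_points: int = 3,
    compute_niche: bool = True,
    compute_drivers: bool = True,
) -> PipelineResult:
    """Run the full analysis on a scenario or on supplied tables.

    With a ``cfg`` the synthetic generator supplies the tables (and ground
    truth); otherwise validated ``survey`` and ``traits`` tables must be
    given.  ``k`` defaults to the scenario's group count (callers without a
    scenario must pass it, or run the bootstrap profile separately and pick
    from it).  ``grid_cells`` scales the kernel-UD grid.
    """
    timings: dict = {}
    t0 = time.perf_counter()
    truth = None
    if cfg is not None:
        survey, traits, truth = generate_metacommunity(cfg)
        if k is None:
            k = len(cfg.groups)
        if n_zones is None:
            n_zones = cfg.n_zones
    if survey is None or traits is None:
        raise ValueError("either cfg or both survey and traits are required")
    if k is None or n_zones is None:
        raise ValueError("k and n_zones are required when running from tables")
    timings["simulate"] = time.perf_counter() - t0

    t = time.perf_counter()
    zones = zone_survey(survey, n_zones)
    timings["zoning"] = time.perf_counter() - t

    t = time.perf_counter()
    dist = gower_distance(traits)
    grouping = cluster_species(dist, k)
    timings["grouping"] = time.perf_counter() - t

    t = time.perf_counter()
    space = pcoa_cailliez(dist, m=4)
    fp = footprints(survey, zones, grouping, traits)
    est = zone_estimates(fp, zones)
    edges = leading_edge(est, zones)
    timings["footprints"] = time.perf_counter() - t

    metrics = pd.DataFrame()
    correlations = pd.DataFrame()
    driver_table = pd.DataFrame()
    driver_tests = pd.DataFrame()
    if compute_niche:
        t = time.perf_counter()
        metrics = site_group_niche_metrics(survey, zones, grouping, traits, space,
                                           grid_cells=grid_cells, min_points=min_points)
        correlations = footprint_niche_correlations(fp, metrics)
        timings["niche"] = time.perf_counter() - t
        if compute_drivers:
            t = time.perf_counter()
            driver_table = build_driver_table(survey, zones, grouping, traits, edges,
                                              metrics)
            driver_tests = leading_edge_driver_tests(driver_table)
            timings["drivers"] = time.perf_counter() - t

    for stage, sec in timings.items():
        log.info("stage %-10s %.2fs", stage, sec)
    return PipelineResult(
        survey=survey, traits=traits, truth=truth, zones=zones, grouping=grouping,
        space=space, footprint_table=fp, zone_estimates=est, edges=edges,
        niche_metrics=metrics, correlations=correlations,
        driver_table=driver_table, driver_tests=driver_tests, timings=timings,
    )


def overlap_power_scenario(seed: int = 0, n_sites: int = 12,
                           scale: float = 0.5) -> ScenarioConfig:
    """Reduced default scenario used by the seeded recovery/power loops."""
    cfg = default_scenario(seed=seed, n_sites=n_sites, scale=scale)
    return cfg
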