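"""Functional-niche areas and overlaps in PCoA trait space.

Species are embedded by Principal Coordinates Analysis of the Gower trait
distance matrix with the Cailliez correction (the smallest constant added
to off-diagonal dissimilarities that makes the configuration Euclidean).
The first four axes form six two-dimensional functional spaces (all axis
pairs); niche metrics are computed in each and averaged with weights
proportional to the variance explained by each pair of axes.

Within a functional space, the niche of a set of species is the 99%
utilisation distribution (UD) of a Gaussian kernel density over the
species' points: the smallest set of highest-density grid cells holding
99% of the probability mass.  Tropical-temperate niche overlap at a site
is the fraction of the tropical UD area covered by the temperate UD; if
any of the six spaces shows exactly zero overlap, the site's averaged
overlap is forced to zero (a site where guilds are fully segregated in
some trait plane is not considered to share niche space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import DistanceMatrix

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# PCoA with Cailliez correction

def _double_centre(sq: np.ndarray) -> np.ndarray:
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ sq @ J


def cailliez_constant(d: np.ndarray, tol: float = 1e-9) -> float:
    """Smallest c such that d_ij + c (i != j) has a Euclidean embedding.

    Computed as the largest real eigenvalue of the 2n x 2n companion
    matrix built from the centred distance and squared-distance matrices;
    returns 0 when the configuration is already Euclidean.
    """
    n = d.shape[0]
    b = _double_centre(d ** 2)
    eig = np.linalg.eigvalsh(b)
    if eig.min() >= -tol * max(1.0, eig.max()):
        return 0.0
    delta1 = _double_centre(d ** 2)
    delta2 = _double_centre(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    ev = np.linalg.eigvals(np.vstack([upper, lower]))
    c = float(np.max(ev.real))
    return max(c, 0.0)


@dataclass
class TraitSpace:
    """Species coordinates on the retained PCoA axes, plus axis-pair weights."""

    coordinates: pd.DataFrame  # index: species, columns: A1..Am
    variance_fractions: np.ndarray  # per retained axis, of total positive mass
    cailliez_c: float
    axis_pairs: list[tuple[int, int]]
    pair_weights: np.ndarray  # normalised over pairs, sum 1

    @property
    def m(self) -> int:
        return self.coordinates.shape[1]

    def pair_coordinates(self, pair: tuple[int, int]) -> pd.DataFrame:
        i, j = pair
        return self.coordinates.iloc[:, [i, j]]


def pcoa_cailliez(dist: DistanceMatrix, m: int = 4) -> TraitSpace:
    """Embed a dissimilarity matrix; retain the first ``m`` axes.

    If the double-centred matrix is positive semi-definite the classical
    solution is returned with c = 0; otherwise the Cailliez constant is
    added to all off-diagonal dissimilarities first, making the corrected
    configuration exactly Euclidean.  Variance fractions are eigenvalues
    relative to the total positive eigenvalue mass after correction; pair
    weights are the normalised sums of each pair's two fractions.
    """
    if m < 2:
        raise ValueError("need at least two retained axes")
    d = dist.values.copy()
    c = cailliez_constant(d)
    if c > 0:
        d = d + c
        np.fill_diagonal(d, 0.0)
    b = _double_centre(d ** 2)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-9 * max(1.0, abs(eigval[0]))
    n_pos = int(pos.sum())
    if m > n_pos:
        raise ValueError(f"only {n_pos} positive axes available, requested {m}")
    lam = eigval[:m]
    coords = eigvec[:, :m] * np.sqrt(lam)
    frac = lam / eigval[pos].sum()
    pairs = list(combinations(range(m), 2))
    w = np.array([frac[i] + frac[j] for i, j in pairs])
    return TraitSpace(
        coordinates=pd.DataFrame(coords, index=dist.labels,
                                 columns=[f"A{i + 1}" for i in range(m)]),
        variance_fractions=frac,
        cailliez_c=c,
        axis_pairs=pairs,
        pair_weights=w / w.sum(),
    )


# ----------------------------------------------------------------------
# kernel utilisation distributions

@dataclass
class KernelUD:
    """A 99% (or other isopleth) utilisation-distribution mask on a grid."""

    defined: bool
    area: float  # trait-space units²; 0.0 for an empty species set
    mask: np.ndarray | None  # boolean (nx, ny)
    x_edges: np.ndarray | None
    y_edges: np.ndarray | None
    reason: str = ""

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0]))


def reference_bandwidth(points: np.ndarray, multiplier: float = 1.0) -> np.ndarray:
    """Bivariate-normal reference bandwidth per axis, h = sigma * n^(-1/6).

    Degenerate axes (zero spread) fall back to a small fraction of the
    larger axis spread so the kernel stays proper.
    """
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1)
    scale = max(sd.max(), np.abs(points).max(), 1e-6)
    sd = np.where(sd > 0, sd, 0.05 * scale)
    return multiplier * sd * n ** (-1.0 / 6.0)


def _grid_edges(lo, hi, n_cells):
    return np.linspace(lo, hi, n_cells + 1)


def kernel_ud(
    points: np.ndarray,
    iso: float = 0.99,
    grid_cells: int = 150,
    min_points: int = 3,
    bandwidth_multiplier: float = 1.0,
    extent: tuple[float, float, float, float] | None = None,
) -> KernelUD:
    """Kernel utilisation distribution of 2-D points.

    A product-Gaussian kernel density is evaluated on a regular grid
    covering the point extent padded by one bandwidth (or a caller-supplied
    ``extent``, so two guilds can share one grid and their masks intersect
    cell-exactly).  The UD mask is the smallest set of highest-density
    cells whose summed probability reaches ``iso``; its area is the cell
    count times the cell area.  Fewer than ``min_points`` distinct points
    yields an undefined (flagged) niche, never a zero one.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    distinct = np.unique(pts, axis=0)
    if len(distinct) < min_points:
        return KernelUD(False, np.nan, None, None, None,
                        reason=f"{len(distinct)} distinct point(s) < min_points={min_points}")
    h = reference_bandwidth(pts, bandwidth_multiplier)
    if extent is None:
        pad = 3.0 * h
        extent = (pts[:, 0].min() - pad[0], pts[:, 0].max() + pad[0],
                  pts[:, 1].min() - pad[1], pts[:, 1].max() + pad[1])
    x_edges = _grid_edges(extent[0], extent[1], grid_cells)
    y_edges = _grid_edges(extent[2], extent[3], grid_cells)
    xc = (x_edges[:-1] + x_edges[1:]) / 2.0
    yc = (y_edges[:-1] + y_edges[1:]) / 2.0
    # separable evaluation: density = (Kx @ Ky.T) / n
    kx = np.exp(-0.5 * ((xc[:, None] - pts[None, :, 0]) / h[0]) ** 2) / h[0]
    ky = np.exp(-0.5 * ((yc[:, None] - pts[None, :, 1]) / h[1]) ** 2) / h[1]
    dens = kx @ ky.T / (2.0 * np.pi * len(pts))
    cell_area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    prob = dens.ravel() * cell_area
    total = prob.sum()
    if total <= 0:
        return KernelUD(False, np.nan, None, None, None, reason="degenerate density")
    prob = prob / total
    order = np.argsort(prob)[::-1]
    cum = np.cumsum(prob[order])
    n_in = int(np.searchsorted(cum, iso) + 1)
    mask = np.zeros(prob.shape, dtype=bool)
    mask[order[:n_in]] = True
    mask = mask.reshape(dens.shape)
    return KernelUD(True, float(n_in * cell_area), mask, x_edges, y_edges)


def overlap_proportion(tropical: KernelUD, temperate: KernelUD) -> float:
    """Fraction of the tropical UD area covered by the temperate UD.

    Both masks must live on a common grid.  Undefined (NaN) when either
    niche is undefined or the tropical mask is empty.
    """
    if not (tropical.defined and temperate.defined):
        return np.nan
    if tropical.mask.shape != temperate.mask.shape or not (
        np.allclose(tropical.x_edges, temperate.x_edges)
        and np.allclose(tropical.y_edges, temperate.y_edges)
    ):
        raise ValueError("overlap requires both masks on one common grid")
    denom = tropical.mask.sum()
    if denom == 0:
        return np.nan
    return float((tropical.mask & temperate.mask).sum() / denom)


# ----------------------------------------------------------------------
# site x group niche metrics

def combine_pair_overlaps(overlaps, weights) -> tuple[float, bool]:
    """Variance-weighted mean overlap across axis-pair spaces, with the
    zero-forcing rule: any exactly-zero pair overlap forces the combined
    overlap to zero.  Returns (overlap, zero_forced); NaN if any pair is
    undefined."""
    overlaps = np.asarray(overlaps, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.isnan(overlaps).any():
        return float("nan"), False
    if (overlaps == 0).any():
        return 0.0, True
    return float((weights * overlaps).sum()), False


def site_species_pools(survey: pd.DataFrame) -> pd.DataFrame:
    """Species with positive summed biomass per (region, site)."""
    tot = survey.groupby(["region", "site", "species"])["biomass"].sum().reset_index()
    return tot[tot["biomass"] > 0]


def _guild_points(space: TraitSpace, pair, species) -> np.ndarray:
    coords = space.pair_coordinates(pair)
    present = [s for s in species if s in coords.index]
    return coords.loc[present].to_numpy()


def _pair_metrics(space, pair, trop_pts, temp_pts, grid_cells, min_points, bw_mult,
                  reference_area: float | None):
    """Area, overlap and area proportion of one axis-pair functional space."""
    n_trop_distinct = len(np.unique(trop_pts, axis=0)) if len(trop_pts) else 0
    if len(trop_pts) == 0:
        return 0.0, np.nan, 0.0 if reference_area else np.nan
    if n_trop_distinct < min_points:
        return np.nan, np.nan, np.nan
    both = np.vstack([trop_pts, temp_pts]) if len(temp_pts) else trop_pts
    h = reference_bandwidth(both, bw_mult)
    extent = (both[:, 0].min() - 3 * h[0], both[:, 0].max() + 3 * h[0],
              both[:, 1].min() - 3 * h[1], both[:, 1].max() + 3 * h[1])
    trop_ud = kernel_ud(trop_pts, grid_cells=grid_cells, min_points=min_points,
                        bandwidth_multiplier=bw_mult, extent=extent)
    area = trop_ud.area
    if len(temp_pts) and len(np.unique(temp_pts, axis=0)) >= min_points:
        temp_ud = kernel_ud(temp_pts, grid_cells=grid_cells, min_points=min_points,
                            bandwidth_multiplier=bw_mult, extent=extent)
        ov = overlap_proportion(trop_ud, temp_ud)
    else:
        ov = np.nan
    prop = area / reference_area if reference_area else np.nan
    return area, ov, prop


def reference_tropical_areas(
    survey, zones, grouping, traits, space,
    grid_cells: int = 150, min_points: int = 3, bandwidth_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Per (region, group, axis pair): tropical kernel area over the pooled
    reference-zone sites (the denominator of the area proportion)."""
    guild = traits.set_index("species")["thermal_guild"]
    pools = site_species_pools(survey)
    rows = []
    for region, part in zones.items():
        ref_sites = part.site_zone.index[part.site_zone == part.reference_zone]
        pool = pools[(pools["region"] == region) & (pools["site"].isin(ref_sites))]
        sp = set(pool["species"])
        for g in grouping.major_groups:
            members = set(grouping.species_group.index[grouping.species_group == g])
            trop = sorted(sp & members & set(guild.index[guild == "tropical"]))
            for p_i, pair in enumerate(space.axis_pairs):
                pts = _guild_points(space, pair, trop)
                ud = kernel_ud(pts, grid_cells=grid_cells, min_points=min_points,
                               bandwidth_multiplier=bandwidth_multiplier) \
                    if len(pts) >= min_points else KernelUD(False, np.nan, None, None, None)
                rows.append(dict(region=region, group=g, pair=p_i,
                                 reference_area=ud.area if ud.defined else np.nan))
    return pd.DataFrame(rows)


def site_group_niche_metrics(
    survey: pd.DataFrame,
    zones: dict,
    grouping,
    traits: pd.DataFrame,
    space: TraitSpace,
    grid_cells: int = 150,
    min_points: int = 3,
    bandwidth_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Kernel niche metrics per (region, site, major functional group).

    For each site and group the species present (positive summed biomass)
    are split by thermal guild; in each of the six axis-pair spaces the two
    guilds share one grid and contribute a tropical UD area, a tropical-
    temperate overlap, and an area proportion relative to the group's
    pooled reference-zone tropical area.  Pair values are averaged with the
    trait-space pair weights; a single zero pair overlap forces the site's
    averaged overlap to zero (logged).  Sites where the group's tropical
    guild is absent score zero area; sites with too few distinct points
    for a kernel are flagged undefined, never zero.
    """
    guild = traits.set_index("species")["thermal_guild"]
    pools = site_species_pools(survey)
    ref = reference_tropical_areas(survey, zones, grouping, traits, space,
                                   grid_cells, min_points, bandwidth_multiplier)
    ref_lookup = ref.set_index(["region", "group", "pair"])["reference_area"]
    w = space.pair_weights
    rows = []
    for region, part in zones.items():
        reg_pool = pools[pools["region"] == region]
        for site in part.site_zone.index:
            sp = set(reg_pool.loc[reg_pool["site"] == site, "species"])
            for g in grouping.major_groups:
                members = set(grouping.species_group.index[grouping.species_group == g])
                trop = sorted(sp & members & set(guild.index[guild == "tropical"]))
                temp = sorted(sp & members & set(guild.index[guild == "temperate"]))
                areas, overlaps, props = [], [], []
                for p_i, pair in enumerate(space.axis_pairs):
                    ra = ref_lookup.get((region, g, p_i), np.nan)
                    a, ov, pr = _pair_metrics(
                        space, pair,
                        _guild_points(space, pair, trop),
                        _guild_points(space, pair, temp),
                        grid_cells, min_points, bandwidth_multiplier,
                        None if np.isnan(ra) else float(ra),
                    )
                    areas.append(a)
                    overlaps.append(ov)
                    props.append(pr)
                areas, overlaps, props = map(np.asarray, (areas, overlaps, props))

                def wmean(v):
                    return float((w * v).sum()) if not np.isnan(v).any() else np.nan

                mean_ov, zero_forced = combine_pair_overlaps(overlaps, w)
                if zero_forced:
                    log.info("zero-forcing overlap at %s/%s group %s", region, site, g)
                row = dict(
                    region=region, site=site, group=g,
                    zone=int(part.site_zone[site]),
                    latitude=float(part.site_latitude[site]),
                    n_tropical=len(trop), n_temperate=len(temp),
                    tropical_area=wmean(areas),
                    tropical_area_proportion=wmean(props),
                    overlap_proportion=mean_ov,
                    overlap_zero_forced=bool(zero_forced),
                    undefined=bool(np.isnan(areas).any()),
                )
                for p_i in range(len(space.axis_pairs)):
                    row[f"area_p{p_i}"] = areas[p_i]
                    row[f"overlap_p{p_i}"] = overlaps[p_i]
                rows.append(row)
    return pd.DataFrame(rows)


def environmental_filtering_signal(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-site proportional tropical niche-area change vs the reference zone.

    Simply extracts (region, site, group, latitude, proportion) rows where
    the proportion is defined; groups whose reference area was undefined are
    dropped with a warning.  Proportion 1 means parity with the reference
    zone, < 1 indicates environmental filtering.
    """
    out = metrics[["region", "site", "group", "zone", "latitude",
                   "tropical_area_proportion"]].copy()
    dropped = out.loc[out["tropical_area_proportion"].isna(), "group"].unique()
    if len(dropped):
        log.warning("filtering signal undefined for groups: %s", sorted(map(str, dropped)))
    return out.dropna(subset=["tropical_area_proportion"]).reset_index(drop=True)
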