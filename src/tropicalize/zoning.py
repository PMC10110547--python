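"""Latitudinal community zonation.

Sites are grouped into transition zones by average-linkage (UPGMA)
hierarchical clustering of Bray-Curtis dissimilarities between
log(1+x)-transformed site-by-species biomass profiles, one clustering per
region.  Zones are ordered by mean absolute site latitude; the lowest-
latitude zone is the reference ("Tropical Coral Reef") zone against which
tropicalisation footprints are normalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .io import DistanceMatrix


@dataclass
class ZonePartition:
    """Site -> zone assignment for one region, ordered equatorward first."""

    region: str
    site_zone: pd.Series  # index: site, value: zone index 0..n_zones-1
    zone_latitude: pd.Series  # representative |latitude| per zone index
    site_latitude: pd.Series  # signed latitude per site

    @property
    def n_zones(self) -> int:
        return int(self.site_zone.max()) + 1

    @property
    def reference_zone(self) -> int:
        return 0

    def zones(self) -> list[int]:
        return list(range(self.n_zones))

    @classmethod
    def from_assignments(cls, region: str, site_zone: pd.Series,
                         site_latitude: pd.Series) -> "ZonePartition":
        """Rebuild a partition from a saved site->zone table."""
        lat = site_latitude.reindex(site_zone.index)
        zl = (pd.DataFrame({"zone": site_zone, "lat": lat.abs()})
              .groupby("zone")["lat"].mean().rename("zone_latitude"))
        return cls(region=region, site_zone=site_zone, zone_latitude=zl,
                   site_latitude=lat)

    def summary(self) -> pd.DataFrame:
        lat = self.site_latitude.abs()
        df = pd.DataFrame({"zone": self.site_zone, "abs_latitude": lat})
        out = df.groupby("zone")["abs_latitude"].agg(["count", "mean", "min", "max"])
        out.columns = ["n_sites", "mean_latitude", "min_latitude", "max_latitude"]
        return out.reset_index()


def site_species_matrix(survey: pd.DataFrame, region: str | None = None) -> pd.DataFrame:
    """Site-by-species matrix of log(1 + mean transect biomass).

    The mean is over the site's transects with species absent from a
    transect counted as zero, so the matrix is invariant to the order in
    which transects are listed and species never surveyed at a site get 0.
    """
    df = survey if region is None else survey[survey["region"] == region]
    if df.empty:
        raise ValueError("empty survey (or no rows for the requested region)")
    per_transect = df.pivot_table(
        index=["site", "transect", "year"], columns="species", values="biomass",
        aggfunc="sum", fill_value=0.0,
    )
    site_mean = per_transect.groupby(level="site").mean()
    return np.log1p(site_mean)


def bray_curtis(matrix: pd.DataFrame, zero_pair_sentinel: float = 0.0) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, d = Σ|x-y| / Σ(x+y), between matrix rows.

    A pair of all-zero rows has an undefined dissimilarity; it is set to
    ``zero_pair_sentinel`` with a warning rather than propagating NaN.
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    undefined = den == 0
    np.fill_diagonal(undefined, False)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum()) // 2} all-zero row pair(s); "
            f"distance set to sentinel {zero_pair_sentinel}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), zero_pair_sentinel)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(matrix.index), d)


def upgma_tree(dist: DistanceMatrix) -> np.ndarray:
    """Average-linkage merge tree (scipy linkage format)."""
    return linkage(dist.condensed(), method="average")


def cluster_zones(dist: DistanceMatrix, n_zones: int,
                  site_latitude: pd.Series, region: str = "") -> ZonePartition:
    """Cut the UPGMA tree of site dissimilarities into latitude-ordered zones.

    Zone indices are relabelled by increasing mean absolute member latitude,
    so zone 0 is always the reference (lowest-latitude) zone regardless of
    input site order.  ``zone_latitude`` is the mean absolute latitude of
    member sites.
    """
    if not 2 <= n_zones <= dist.n:
        raise ValueError(f"n_zones must be in [2, {dist.n}], got {n_zones}")
    tree = upgma_tree(dist)
    raw = fcluster(tree, t=n_zones, criterion="maxclust")
    lat = site_latitude.reindex(dist.labels).abs()
    means = pd.Series(lat.values, index=raw).groupby(level=0).mean().sort_values()
    relabel = {old: new for new, old in enumerate(means.index)}
    zone = pd.Series([relabel[r] for r in raw], index=dist.labels,
                     name="zone").rename_axis("site")
    zone_lat = (
        pd.DataFrame({"zone": zone.values, "lat": lat.values})
        .groupby("zone")["lat"].mean().rename("zone_latitude")
    )
    return ZonePartition(
        region=region,
        site_zone=zone,
        zone_latitude=zone_lat,
        site_latitude=site_latitude.reindex(dist.labels),
    )


def zone_survey(survey: pd.DataFrame, n_zones: int) -> dict[str, ZonePartition]:
    """Run the full zonation per region on a survey table."""
    out = {}
    for region, df in survey.groupby("region"):
        mat = site_species_matrix(df)
        site_lat = df.groupby("site")["latitude"].first()
        out[region] = cluster_zones(bray_curtis(mat), n_zones, site_lat, region=region)
    return out


def silhouette_by_k(dist: DistanceMatrix, k_range=range(2, 11)) -> pd.DataFrame:
    """Mean silhouette width of the UPGMA cut at each k (zoning diagnostics)."""
    from sklearn.metrics import silhouette_score

    tree = upgma_tree(dist)
    rows = []
    for k in k_range:
        if not 2 <= k <= dist.n - 1:
            continue
        labels = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        rows.append(dict(k=k, silhouette=silhouette_score(dist.values, labels,
                                                          metric="precomputed")))
    return pd.DataFrame(rows)
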