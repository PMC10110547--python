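"""Functional-group identification from mixed-type traits.

Species are clustered into functional groups by average-linkage (UPGMA)
hierarchical clustering of Gower distances over five traits: diet and
habitat association (nominal), body size and depth range (continuous,
log-transformed), and aggregation (ordinal).  Missing trait values are
never imputed: each species pair is compared over its shared non-missing
traits with the Gower average renormalised accordingly.

The number of groups is validated with a bootstrap of cluster stability:
on each iteration 5% of the species are omitted, distances recomputed
(range-scaled against the *full* data so distances stay comparable), the
tree rebuilt, and — for each candidate k — the mean silhouette width of
the bootstrap partition, the clusterwise Jaccard similarity against the
original partition, and the Rand matching index are recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster, cophenet, to_tree
from sklearn.metrics import silhouette_score, rand_score, adjusted_rand_score

from .io import DistanceMatrix

NOMINAL_TRAITS = ("diet", "habitat_association")
LOG_TRAITS = ("body_size", "depth_range")
ORDINAL_TRAITS = ("aggregation",)
ALL_TRAITS = NOMINAL_TRAITS + LOG_TRAITS + ORDINAL_TRAITS


# ----------------------------------------------------------------------
# Gower distances

def trait_ranges(traits: pd.DataFrame) -> dict[str, float]:
    """Full-data scaling ranges for the quantitative traits (log scale for
    body size and depth range, rank scale for aggregation)."""
    r = {}
    for col in LOG_TRAITS:
        v = np.log(pd.to_numeric(traits[col], errors="coerce").astype(float))
        r[col] = float(np.nanmax(v) - np.nanmin(v)) if v.notna().any() else 0.0
    for col in ORDINAL_TRAITS:
        v = pd.to_numeric(traits[col], errors="coerce").astype(float)
        r[col] = float(np.nanmax(v) - np.nanmin(v)) if v.notna().any() else 0.0
    return r


def gower_distance(traits: pd.DataFrame, ranges: dict[str, float] | None = None) -> DistanceMatrix:
    """Gower dissimilarity between species over the five functional traits.

    Per pair: nominal traits contribute 0/1 mismatch; body size and depth
    range contribute |Δ log| / range; aggregation contributes |Δ| / range
    of the ordinal levels.  Traits missing in either member of a pair are
    excluded and the average renormalised over the comparable traits.
    ``ranges`` overrides the scaling ranges (used by the bootstrap so
    subsample distances stay on the full-data scale).
    """
    if len(traits) < 2:
        raise ValueError("Gower distance needs at least two species")
    species = list(traits["species"])
    n = len(species)
    if ranges is None:
        ranges = trait_ranges(traits)

    total = np.zeros((n, n))
    count = np.zeros((n, n))

    def add(contrib: np.ndarray, comparable: np.ndarray) -> None:
        total[comparable] += contrib[comparable]
        count[comparable] += 1

    for col in NOMINAL_TRAITS:
        v = traits[col].to_numpy(dtype=object)
        ok = pd.notna(v)
        comparable = ok[:, None] & ok[None, :]
        mismatch = (v[:, None] != v[None, :]).astype(float)
        add(mismatch, comparable)
    for col in LOG_TRAITS + ORDINAL_TRAITS:
        raw = pd.to_numeric(traits[col], errors="coerce").to_numpy(dtype=float)
        v = np.log(raw) if col in LOG_TRAITS else raw
        ok = np.isfinite(v)
        comparable = ok[:, None] & ok[None, :]
        rng = ranges.get(col, 0.0)
        if rng > 0:
            diff = np.abs(np.subtract.outer(v, v)) / rng
        else:  # all comparable values identical -> zero contribution
            diff = np.zeros((n, n))
        diff = np.nan_to_num(diff)
        add(diff, comparable)

    if (count == 0).any():
        i, j = np.argwhere(count == 0)[0]
        raise ValueError(
            f"species pair ({species[i]}, {species[j]}) shares no comparable trait"
        )
    d = total / count
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(species, np.clip(d, 0.0, 1.0))


# ----------------------------------------------------------------------
# clustering

@dataclass
class FunctionalGrouping:
    """Species -> functional-group assignment at a chosen k."""

    species_group: pd.Series  # index: species, value: group label "FG1".. by size
    k: int
    major_threshold: float = 0.02  # fraction of species for a "major" group

    @property
    def sizes(self) -> pd.Series:
        return self.species_group.value_counts()

    @property
    def major_groups(self) -> list[str]:
        s = self.sizes
        return list(s.index[s >= self.major_threshold * s.sum()])

    def guild_counts(self, traits: pd.DataFrame) -> pd.DataFrame:
        guild = traits.set_index("species")["thermal_guild"]
        df = pd.DataFrame({"group": self.species_group,
                           "guild": guild.reindex(self.species_group.index)})
        return df.groupby(["group", "guild"]).size().unstack(fill_value=0)


def species_tree(dist: DistanceMatrix) -> np.ndarray:
    """UPGMA merge tree over species (scipy linkage format)."""
    return linkage(dist.condensed(), method="average")


def _relabel_by_size(labels: np.ndarray, species: list) -> pd.Series:
    """Stable group labels: FG1 = largest group, ties by first species index."""
    s = pd.Series(labels, index=species)
    order = sorted(
        s.unique(), key=lambda g: (-(s == g).sum(), int(np.argmax(s.values == g)))
    )
    mapping = {g: f"FG{i + 1}" for i, g in enumerate(order)}
    return s.map(mapping).rename("group").rename_axis("species")


def cluster_species(dist: DistanceMatrix, k: int,
                    major_threshold: float = 0.02) -> FunctionalGrouping:
    """Cut the species UPGMA tree at k functional groups."""
    if not 2 <= k <= dist.n:
        raise ValueError(f"k must be in [2, {dist.n}], got {k}")
    tree = species_tree(dist)
    labels = fcluster(tree, t=k, criterion="maxclust")
    return FunctionalGrouping(_relabel_by_size(labels, dist.labels), k=k,
                              major_threshold=major_threshold)


def cophenetic_fidelity(dist: DistanceMatrix, tree: np.ndarray | None = None) -> float:
    """Pearson correlation between original and tree cophenetic distances."""
    if tree is None:
        tree = species_tree(dist)
    c, _ = cophenet(tree, dist.condensed())
    return float(c)


def tree_to_newick(tree: np.ndarray, labels: list[str]) -> str:
    """Newick string of a linkage tree; branch lengths from merge heights."""
    root = to_tree(tree)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"


# ----------------------------------------------------------------------
# bootstrap stability

def clusterwise_jaccard(original: pd.Series, bootstrap: pd.Series) -> float:
    """Mean over original clusters of the best Jaccard match among
    bootstrap clusters (Hennig-style recovery of each original cluster)."""
    common = original.index.intersection(bootstrap.index)
    o, b = original.loc[common], bootstrap.loc[common]
    scores = []
    for g in o.unique():
        a = set(common[o == g])
        best = 0.0
        for h in b.unique():
            c = set(common[b == h])
            j = len(a & c) / len(a | c)
            best = max(best, j)
        scores.append(best)
    return float(np.mean(scores))


def bootstrap_stability(
    traits: pd.DataFrame,
    k_range=range(2, 31),
    n_boot: int = 1000,
    omit_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-stability profile over k under 5%-omission bootstrap.

    Returns one row per k with the across-iteration mean and standard
    deviation of: silhouette width of the bootstrap partition, clusterwise
    Jaccard of the original partition recovered in the bootstrap one, and
    the (unadjusted) Rand index between the two, plus the adjusted Rand.
    """
    k_range = list(k_range)
    n = len(traits)
    n_drop = int(np.ceil(omit_fraction * n))
    if n - n_drop < max(k_range) + 1:
        raise ValueError(
            f"omitting {n_drop} of {n} species leaves too few for k up to {max(k_range)}"
        )
    ranges = trait_ranges(traits)
    dist_full = gower_distance(traits, ranges=ranges)
    tree_full = species_tree(dist_full)
    species = np.array(dist_full.labels)
    original_at_k = {
        k: pd.Series(fcluster(tree_full, t=k, criterion="maxclust"), index=species)
        for k in k_range
    }

    rng = np.random.default_rng(seed)
    acc = {k: {"silhouette": [], "jaccard": [], "rand": [], "adjusted_rand": []}
           for k in k_range}
    for _ in range(n_boot):
        keep = np.sort(rng.choice(n, size=n - n_drop, replace=False))
        sub = traits.iloc[keep].reset_index(drop=True)
        dist_b = gower_distance(sub, ranges=ranges)
        tree_b = species_tree(dist_b)
        kept_species = np.array(dist_b.labels)
        for k in k_range:
            lab_b = fcluster(tree_b, t=k, criterion="maxclust")
            boot = pd.Series(lab_b, index=kept_species)
            orig = original_at_k[k].loc[kept_species]
            if len(np.unique(lab_b)) >= 2:
                sil = silhouette_score(dist_b.values, lab_b, metric="precomputed")
            else:
                sil = np.nan
            acc[k]["silhouette"].append(sil)
            acc[k]["jaccard"].append(clusterwise_jaccard(orig, boot))
            acc[k]["rand"].append(rand_score(orig.values, boot.values))
            acc[k]["adjusted_rand"].append(adjusted_rand_score(orig.values, boot.values))

    rows = []
    for k in k_range:
        row = {"k": k, "n_boot": n_boot, "omit_fraction": omit_fraction, "seed": seed}
        for name, vals in acc[k].items():
            v = np.asarray(vals, dtype=float)
            row[f"mean_{name}"] = float(np.nanmean(v))
            row[f"sd_{name}"] = float(np.nanstd(v))
        rows.append(row)
    return pd.DataFrame(rows)


def select_k(profile: pd.DataFrame, jaccard_threshold: float = 0.75) -> int:
    """Default stand-in for by-inspection choice of k.

    Returns the smallest k at a local maximum of mean silhouette whose mean
    clusterwise Jaccard meets the threshold; if no k qualifies, falls back
    to the global silhouette argmax with a warning.  The full profile
    should always be reported alongside, so the choice can be overridden.
    """
    if profile.empty:
        raise ValueError("empty stability profile")
    p = profile.sort_values("k").reset_index(drop=True)
    sil = p["mean_silhouette"].to_numpy()
    jac = p["mean_jaccard"].to_numpy()
    for i in range(len(p)):
        left_ok = i == 0 or sil[i] >= sil[i - 1]
        right_ok = i == len(p) - 1 or sil[i] >= sil[i + 1]
        strict = (i > 0 and sil[i] > sil[i - 1]) or (i < len(p) - 1 and sil[i] > sil[i + 1])
        if left_ok and right_ok and strict and jac[i] >= jaccard_threshold:
            return int(p["k"].iloc[i])
    warnings.warn("no k satisfies the selection rule; returning silhouette argmax")
    return int(p["k"].iloc[int(np.nanargmax(sil))])


# ----------------------------------------------------------------------
# group characterisation

def characterise_groups(grouping: FunctionalGrouping, traits: pd.DataFrame) -> pd.DataFrame:
    """Within-group trait-level frequencies (the word-cloud table).

    For each group and categorical trait (diet, habitat association,
    aggregation level), the frequency of each level among the group's
    species with that trait recorded; frequencies per (group, trait) sum
    to 1.  Dominant diet and habitat levels are flagged for group naming.
    """
    t = traits.set_index("species").reindex(grouping.species_group.index)
    t["group"] = grouping.species_group
    rows = []
    for col in ("diet", "habitat_association", "aggregation"):
        freq = (
            t.dropna(subset=[col])
            .groupby(["group", col], observed=True).size()
            .rename("n").reset_index()
        )
        freq["frequency"] = freq["n"] / freq.groupby("group")["n"].transform("sum")
        freq["trait"] = col
        freq = freq.rename(columns={col: "level"})
        freq["dominant"] = (
            freq["frequency"] == freq.groupby("group")["frequency"].transform("max")
        )
        rows.append(freq[["group", "trait", "level", "n", "frequency", "dominant"]])
    return pd.concat(rows, ignore_index=True)
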