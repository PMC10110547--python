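#!/usr/bin/env python
"""Identify functional groups from species traits.

Gower distances over the five traits, UPGMA dendrogram, bootstrap stability
profile over candidate group counts (silhouette / clusterwise Jaccard /
Rand under 5% omission), k selection, and per-group trait characterisation.
Writes species->group assignments (with thermal guild), the stability
profile, the dendrogram (Newick), and the trait frequency table.
"""

import argparse
from pathlib import Path

from tropicalize.io import read_traits
from tropicalize.grouping import (gower_distance, cluster_species, species_tree,
                                  cophenetic_fidelity, bootstrap_stability, select_k,
                                  characterise_groups, tree_to_newick)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--k", type=int, default=None,
                    help="override the bootstrap-selected group count")
    ap.add_argument("--k-max", type=int, default=30)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    traits = read_traits(args.out / "traits.csv")
    dist = gower_distance(traits)
    tree = species_tree(dist)
    print(f"cophenetic correlation of the UPGMA tree: "
          f"{cophenetic_fidelity(dist, tree):.3f}")

    profile = bootstrap_stability(traits, k_range=range(2, args.k_max + 1),
                                  n_boot=args.n_boot, seed=args.seed)
    profile.to_csv(args.out / "stability_profile.csv", index=False)
    k = args.k if args.k is not None else select_k(profile)
    print(f"clustering species at k = {k} "
          f"({'user override' if args.k is not None else 'selected from profile'})")

    grouping = cluster_species(dist, k)
    guilds = traits.set_index("species")["thermal_guild"]
    out = grouping.species_group.rename("group").reset_index()
    out["thermal_guild"] = out["species"].map(guilds)
    out["major"] = out["group"].isin(grouping.major_groups)
    out.to_csv(args.out / "species_groups.csv", index=False)
    (args.out / "dendrogram.nwk").write_text(tree_to_newick(tree, dist.labels))

    char = characterise_groups(grouping, traits)
    char.to_csv(args.out / "group_trait_frequencies.csv", index=False)
    print(f"{len(grouping.major_groups)} major groups hold "
          f"{grouping.sizes[grouping.major_groups].sum() / len(traits):.0%} of species")


if __name__ == "__main__":
    main()
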