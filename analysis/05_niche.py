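#!/usr/bin/env python
"""Kernel functional-niche areas and tropical-temperate overlaps.

Builds the Cailliez-corrected PCoA trait space (four axes, six axis-pair
functional spaces), computes 99% kernel-UD tropical niche areas and
tropical-temperate overlap per site and major group, and the Kendall
correlations (with zero-footprint removal) linking footprints to the niche
metrics.
"""

import argparse
from pathlib import Path

import pandas as pd

from tropicalize.grouping import gower_distance
from tropicalize.niche import pcoa_cailliez, site_group_niche_metrics
from tropicalize.drivers import footprint_niche_correlations

import importlib.util
import sys

spec = importlib.util.spec_from_file_location(
    "footprint_inputs", Path(__file__).parent / "04_footprints.py")
mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(mod)
load_inputs = mod.load_inputs


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--grid-cells", type=int, default=150)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    survey, traits, zones, grouping = load_inputs(args.out)
    space = pcoa_cailliez(gower_distance(traits), m=4)
    coords = space.coordinates.reset_index(names="species")
    coords.to_csv(args.out / "trait_space_coordinates.csv", index=False)
    print(f"Cailliez c = {space.cailliez_c:.3f}; axis variance fractions "
          f"{[round(100 * f, 1) for f in space.variance_fractions]}%")

    metrics = site_group_niche_metrics(survey, zones, grouping, traits, space,
                                       grid_cells=args.grid_cells)
    metrics.to_csv(args.out / "niche_metrics.csv", index=False)
    fp = pd.read_csv(args.out / "footprints.csv")
    corr = footprint_niche_correlations(fp, metrics)
    corr.to_csv(args.out / "footprint_niche_correlations.csv", index=False)

    by_group = metrics.groupby("group")[["overlap_proportion",
                                         "tropical_area_proportion"]].mean()
    print("site-mean niche metrics per group:")
    print(by_group.round(3).to_string())


if __name__ == "__main__":
    main()
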