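#!/usr/bin/env python
"""Test drivers of leading-edge differences across functional groups.

Assembles the per-(group, region) driver table (guild biomass maxima,
site-averaged niche metrics, richness, thermal limits, categorical traits)
and runs the battery: gamma GLMs, quasi-binomial GLMs, quasi-Poisson GLM,
linear model, and chi-square association tests against leading-edge class.
"""

import argparse
import importlib.util
import json
from pathlib import Path

import pandas as pd

from tropicalize.footprint import leading_edge
from tropicalize.drivers import build_driver_table, leading_edge_driver_tests

spec = importlib.util.spec_from_file_location(
    "footprint_inputs", Path(__file__).parent / "04_footprints.py")
mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(mod)
load_inputs = mod.load_inputs


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    survey, traits, zones, grouping = load_inputs(args.out)
    est = pd.read_csv(args.out / "zone_footprint_estimates.csv")
    edges = leading_edge(est, zones)
    metrics = pd.read_csv(args.out / "niche_metrics.csv")

    dt = build_driver_table(survey, zones, grouping, traits, edges, metrics)
    dt.to_csv(args.out / "driver_table.csv", index=False)
    res = leading_edge_driver_tests(dt)
    res.to_csv(args.out / "driver_tests.csv", index=False)
    (args.out / "driver_tests.json").write_text(
        json.dumps(res.set_index("test").to_dict(orient="index"), indent=1,
                   default=str))

    print(res[["test", "family", "statistic", "df1", "df2", "p_value"]]
          .round(4).to_string(index=False))
    sig = res[res["p_value"] < 0.05]["test"].tolist()
    print(f"drivers significant at alpha = 0.05: {sig}")


if __name__ == "__main__":
    main()
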