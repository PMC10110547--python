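import numpy as np
import pandas as pd
import pytest

from tropicalize import default_scenario, generate_metacommunity
from tropicalize.footprint import (footprints, transform_fourth_root, zone_mixed_model,
                                   zone_estimates, leading_edge, COMMUNITY,
                                   CLASS_AS_EXPECTED, CLASS_BELOW, CLASS_WELL_BELOW,
                                   CLASS_NO_DECLINE)
from tropicalize.zoning import zone_survey, ZonePartition
from tropicalize.grouping import FunctionalGrouping


def make_partition(site_zone: dict, site_lat: dict, region="R") -> ZonePartition:
    sz = pd.Series(site_zone, name="zone")
    lat = pd.Series(site_lat, name="latitude")
    zl = pd.DataFrame({"zone": sz, "lat": lat.abs()}).groupby("zone")["lat"].mean()
    return ZonePartition(region=region, site_zone=sz,
                         zone_latitude=zl.rename("zone_latitude"), site_latitude=lat)


def toy_tables():
    """Two-zone toy world: reference zone with b̄ = 40, poleward zone with 2."""
    rows = []
    for site, zone, lat, b in [("r1", 0, -24, 40.0), ("r2", 0, -24.5, 40.0),
                               ("p1", 1, -30, 2.0), ("p2", 1, -30.5, 0.0)]:
        for t in ("T1", "T2"):
            rows.append(dict(region="R", site=site, latitude=lat, transect=t,
                             year=2016, species="sp1", biomass=b))
            rows.append(dict(region="R", site=site, latitude=lat, transect=t,
                             year=2016, species="sp2", biomass=b / 2))
    survey = pd.DataFrame(rows)
    traits = pd.DataFrame(dict(
        species=["sp1", "sp2"], diet=["predator"] * 2,
        habitat_association=["benthic"] * 2, body_size=[10.0, 20.0],
        aggregation=[1, 2], depth_range=[5.0, 10.0],
        thermal_guild=["tropical", "tropical"],
    ))
    zones = {"R": make_partition({"r1": 0, "r2": 0, "p1": 1, "p2": 1},
                                 {"r1": -24, "r2": -24.5, "p1": -30, "p2": -30.5})}
    sg = pd.Series({"sp1": "G1", "sp2": "G2"}, name="group")
    sg.index.name = "species"
    return survey, traits, zones, FunctionalGrouping(sg, k=2, major_threshold=0.0)


class TestFootprints:
    def test_reference_transect_bt_is_one(self):
        survey, traits, zones, grouping = toy_tables()
        fp = footprints(survey, zones, grouping, traits)
        g1 = fp[fp["group"] == "G1"]
        ref = g1[g1["zone"] == 0]
        assert np.allclose(ref["bt"], 1.0)

    def test_reference_mean_exactly_one_per_group(self, small_world, true_grouping):
        survey, traits, _ = small_world
        zones = zone_survey(survey, 6)
        fp = footprints(survey, zones, true_grouping, traits)
        ref_means = fp[fp["zone"] == 0].groupby(["region", "group"])["bt"].mean()
        assert np.allclose(ref_means, 1.0, atol=1e-12)

    def test_zero_when_guild_absent(self):
        survey, traits, zones, grouping = toy_tables()
        fp = footprints(survey, zones, grouping, traits)
        g1_p2 = fp[(fp["group"] == "G1") & (fp["site"] == "p2")]
        assert (g1_p2["bt"] == 0.0).all()

    def test_twenty_fold_threshold_value(self):
        survey, traits, zones, grouping = toy_tables()
        fp = footprints(survey, zones, grouping, traits)
        row = fp[(fp["group"] == "G1") & (fp["site"] == "p1")].iloc[0]
        assert row["bt"] == pytest.approx(2.0 / 40.0)  # exactly the 20-fold point

    def test_scale_invariance(self):
        survey, traits, zones, grouping = toy_tables()
        fp1 = footprints(survey, zones, grouping, traits)
        scaled = survey.copy()
        scaled.loc[scaled["species"] == "sp1", "biomass"] *= 7.5
        fp2 = footprints(scaled, zones, grouping, traits)
        g = lambda f: f[f["group"] == "G1"].sort_values(["site", "transect"])["bt"].to_numpy()
        assert np.allclose(g(fp1), g(fp2))

    def test_community_is_biomass_weighted_sum_of_groups(self):
        survey, traits, zones, grouping = toy_tables()
        fp = footprints(survey, zones, grouping, traits)
        piv = fp.pivot_table(index=["site", "transect"], columns="group",
                             values="biomass")
        assert np.allclose(piv[COMMUNITY], piv["G1"] + piv["G2"])

    def test_group_without_reference_biomass_excluded(self):
        survey, traits, zones, grouping = toy_tables()
        traits2 = traits.copy()
        traits2.loc[traits2["species"] == "sp2", "thermal_guild"] = "temperate"
        sg = pd.Series({"sp1": "G1", "sp2": "G2"}, name="group")
        sg.index.name = "species"
        g2 = FunctionalGrouping(sg, k=2, major_threshold=0.0)
        fp = footprints(survey, zones, g2, traits2)
        assert "G2" not in set(fp["group"])  # no tropical members anywhere


class TestFourthRoot:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (0.0016, 0.2)])
    def test_values(self, x, expected):
        assert transform_fourth_root(x) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_fourth_root(np.array([-0.1]))


class TestZoneMixedModel:
    def test_collapsed_model_equals_group_means(self):
        survey, traits, zones, grouping = toy_tables()
        fp = footprints(survey, zones, grouping, traits)
        est = zone_mixed_model(fp, "R", 1)
        data = fp[fp["zone"] == 1]
        for g in ("G1", "G2", COMMUNITY):
            expected = data.loc[data["group"] == g, "bt_transformed"].mean()
            got = est.loc[est["group"] == g, "mean_transformed"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-6)

    def test_null_case_no_departures(self, rng):
        rows = []
        for site in ("a", "b", "c"):
            for t in range(4):
                bt = rng.uniform(0.2, 0.4)
                for g in (COMMUNITY, "G1", "G2"):
                    rows.append(dict(region="R", zone=1, site=site, transect=f"T{t}",
                                     year=0, latitude=-30, group=g, biomass=np.nan,
                                     reference_mean=1.0, bt=bt,
                                     bt_transformed=bt ** 0.25))
        fp = pd.DataFrame(rows)
        est = zone_mixed_model(fp, "R", 1)
        assert not est[est["group"] != COMMUNITY]["departure"].any()

    def test_reference_zone_rejected(self):
        survey, traits, zones, grouping = toy_tables()
        fp = footprints(survey, zones, grouping, traits)
        with pytest.raises(ValueError, match="reference zone"):
            zone_mixed_model(fp, "R", 0)

    def test_departure_power_with_site_effects(self, rng):
        """A group generated at five times the community footprint, with real
        between-site variation, is flagged as a positive departure in at
        least 90% of replicates."""
        detected = 0
        n_rep = 60
        for _ in range(n_rep):
            rows = []
            for site in "abcde":
                site_eff = rng.normal(0, 0.05)
                for t in range(4):
                    base = max(0.05, 0.2 + site_eff + rng.normal(0, 0.04))
                    for g, mult in ((COMMUNITY, 1.0), ("G1", 5.0), ("G2", 1.0)):
                        bt = base * mult * rng.lognormal(0, 0.1)
                        rows.append(dict(region="R", zone=1, site=site,
                                         transect=f"T{t}", year=0, latitude=-30,
                                         group=g, biomass=np.nan, reference_mean=1.0,
                                         bt=bt, bt_transformed=bt ** 0.25))
            est = zone_mixed_model(pd.DataFrame(rows), "R", 1)
            row = est[est["group"] == "G1"].iloc[0]
            detected += bool(row["departure"] and row["departure_sign"] > 0)
        assert detected / n_rep >= 0.9


class TestLeadingEdge:
    def estimates(self, profiles: dict) -> pd.DataFrame:
        rows = []
        for g, means in profiles.items():
            for z, m in enumerate(means, start=1):
                rows.append(dict(region="R", zone=z, group=g, mean_bt=m))
        return pd.DataFrame(rows)

    def partition(self):
        return {"R": make_partition(
            {f"s{z}": z for z in range(6)},
            {f"s{z}": -(24 + 2 * z) for z in range(6)})}

    def test_classes_by_zone_gap(self):
        est = self.estimates({
            COMMUNITY: [0.8, 0.5, 0.3, 0.1, 0.04],
            "same": [0.9, 0.4, 0.2, 0.09, 0.01],
            "one_early": [0.5, 0.3, 0.1, 0.04, 0.01],
            "two_early": [0.4, 0.2, 0.04, 0.01, 0.001],
            "never": [0.9, 0.8, 0.7, 0.6, 0.5],
        })
        edges = leading_edge(est, self.partition())
        cls = edges.set_index("group")["edge_class"]
        assert cls["same"] == CLASS_AS_EXPECTED
        assert cls["one_early"] == CLASS_BELOW
        assert cls["two_early"] == CLASS_WELL_BELOW
        assert cls["never"] == CLASS_NO_DECLINE

    def test_edge_poleward_of_community_counts_as_expected(self):
        est = self.estimates({COMMUNITY: [0.5, 0.2, 0.04, 0.01, 0.001],
                              "late": [0.9, 0.6, 0.3, 0.1, 0.04]})
        edges = leading_edge(est, self.partition())
        assert edges.set_index("group")["edge_class"]["late"] == CLASS_AS_EXPECTED

    def test_threshold_monotonicity(self):
        est = self.estimates({COMMUNITY: [0.8, 0.4, 0.2, 0.08, 0.01],
                              "g": [0.6, 0.25, 0.12, 0.06, 0.02]})
        zones = self.partition()
        prev = None
        for thr in (0.20, 0.10, 0.05, 0.02):
            e = leading_edge(est, zones, threshold=thr)
            z = e.set_index("group")["edge_zone"]["g"]
            if prev is not None and not (pd.isna(z) or pd.isna(prev)):
                assert z >= prev  # smaller threshold never more equatorward
            prev = z

    def test_missing_community_is_error(self):
        est = self.estimates({"g": [0.5, 0.2, 0.04, 0.01, 0.001]})
        with pytest.raises(ValueError, match="community"):
            leading_edge(est, self.partition())

    def test_default_scenario_edges_match_truth(self, small_world, true_grouping):
        survey, traits, truth = small_world
        zones = zone_survey(survey, 6)
        fp = footprints(survey, zones, true_grouping, traits)
        edges = leading_edge(zone_estimates(fp, zones), zones)
        for _, e in edges.iterrows():
            if e["group"] == COMMUNITY:
                continue
            got = None if pd.isna(e["edge_zone"]) else int(e["edge_zone"])
            assert got == truth.group_edge_zone[e["group"]]
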