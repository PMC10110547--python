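"""Tropicalisation footprints, zone models and leading edges.

The tropicalisation footprint of functional group *i* at transect *j* is

    BT_ij = b_ij / b̄_i

where b_ij is the summed biomass of the group's *tropical* species on the
transect and b̄_i is the mean of b_ij over all transects of the region's
reference (lowest-latitude) zone — zeros included, so the reference-zone
mean footprint of every group is exactly 1.  A "community" pseudo-group
uses all tropical species regardless of group and provides the expectation
that group footprints are tested against.

Footprints are fourth-root transformed (monotone, 0 -> 0, 1 -> 1; damps
huge proportional changes while respecting zeros from group absence) and
modelled within each non-reference zone by a linear mixed model with group
as a fixed categorical (community as baseline) and a site random intercept.
The leading edge of a group is the first zone, scanning poleward, whose
modelled mean footprint falls below 1/20.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

COMMUNITY = "community"
EDGE_THRESHOLD = 0.05  # the 20-fold decline

CLASS_AS_EXPECTED = "as_expected"
CLASS_BELOW = "below_expectation"
CLASS_WELL_BELOW = "well_below_expectation"
CLASS_NO_DECLINE = "does_not_decline"


def transform_fourth_root(bt):
    """Fourth-root transform of footprints; domain error on negatives."""
    bt = np.asarray(bt, dtype=float)
    if (bt < 0).any():
        raise ValueError("footprints must be non-negative")
    return bt ** 0.25


def footprints(
    survey: pd.DataFrame,
    zones: dict,
    grouping,
    traits: pd.DataFrame,
    guild: str = "tropical",
    groups: list | None = None,
) -> pd.DataFrame:
    """Per-transect footprints (Eq. 1) for each major group and the community.

    Returns a long table (region, zone, site, transect, year, latitude,
    group, biomass, reference_mean, bt, bt_transformed) with one row per
    transect x group including explicit zeros where the group's guild
    members are absent.  Groups whose reference-zone mean biomass is zero
    are excluded with a warning.
    """
    guild_map = traits.set_index("species")["thermal_guild"]
    guild_species = set(guild_map.index[guild_map == guild])
    if groups is None:
        groups = grouping.major_groups
    member = {
        g: set(grouping.species_group.index[grouping.species_group == g]) & guild_species
        for g in groups
    }
    member[COMMUNITY] = guild_species

    out = []
    for region, part in zones.items():
        reg = survey[survey["region"] == region]
        transects = (
            reg[["site", "transect", "year", "latitude"]]
            .drop_duplicates(subset=["site", "transect", "year"])
            .reset_index(drop=True)
        )
        per = reg.pivot_table(index=["site", "transect", "year"], columns="species",
                              values="biomass", aggfunc="sum", fill_value=0.0)
        per = per.reindex(
            pd.MultiIndex.from_frame(transects[["site", "transect", "year"]]),
            fill_value=0.0,
        )
        zone_of = part.site_zone
        ref_rows = per.index.get_level_values("site").map(zone_of) == part.reference_zone
        for g, sp in member.items():
            cols = [s for s in per.columns if s in sp]
            b = per[cols].sum(axis=1) if cols else pd.Series(0.0, index=per.index)
            b_ref = float(b[ref_rows].mean()) if ref_rows.any() else 0.0
            if b_ref <= 0:
                log.warning("group %s has zero reference-zone %s biomass in %s; excluded",
                            g, guild, region)
                continue
            bt = b / b_ref
            df = transects.copy()
            df["region"] = region
            df["zone"] = df["site"].map(zone_of)
            df["group"] = g
            df["biomass"] = b.to_numpy()
            df["reference_mean"] = b_ref
            df["bt"] = bt.to_numpy()
            df["bt_transformed"] = transform_fourth_root(bt.to_numpy())
            out.append(df)
    if not out:
        raise ValueError("no group had positive reference-zone biomass")
    cols = ["region", "zone", "site", "transect", "year", "latitude", "group",
            "biomass", "reference_mean", "bt", "bt_transformed"]
    return pd.concat(out, ignore_index=True)[cols]


def zone_mixed_model(fp: pd.DataFrame, region: str, zone: int,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Zone-level footprint estimates with site random intercepts.

    Fits fourth-root footprints against group (community as the baseline
    level) with a site random effect; falls back to OLS — whose estimates
    are exactly the per-group means — when the mixed fit is singular or the
    zone has a single site.  Returns per group: mean and se on the
    transformed scale, the back-transformed mean, and the departure test
    (sign and p-value of the group-vs-community contrast).
    """
    data = fp[(fp["region"] == region) & (fp["zone"] == zone)].copy()
    if data.empty:
        raise ValueError(f"no footprint rows for {region} zone {zone}")
    if zone == 0:
        raise ValueError("reference zone is the normalisation baseline, not modelled")
    data["group"] = pd.Categorical(
        data["group"],
        categories=[COMMUNITY] + sorted(g for g in data["group"].unique() if g != COMMUNITY),
    )
    formula = "bt_transformed ~ C(group, Treatment('community'))"
    n_sites = data["site"].nunique()
    fit = None
    if n_sites >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = smf.mixedlm(formula, data, groups=data["site"]).fit(reml=True)
                if not np.isfinite(fit.params).all() or fit.cov_re.iloc[0, 0] < 1e-10:
                    fit = None  # singular: no usable site variance
            except Exception:
                fit = None
    if fit is None:
        log.warning("zone %s/%s: singular or unavailable mixed fit; using OLS", region, zone)
        fit = smf.ols(formula, data).fit()

    params, bse, pvals = fit.params, fit.bse, fit.pvalues
    cov = fit.cov_params().loc[params.index, params.index]
    rows = []
    intercept = params["Intercept"]
    for g in data["group"].cat.categories:
        if g == COMMUNITY:
            mean_t, se_t, p, sign = intercept, bse["Intercept"], np.nan, 0
        else:
            term = f"C(group, Treatment('community'))[T.{g}]"
            mean_t = intercept + params[term]
            se_t = float(np.sqrt(cov.loc["Intercept", "Intercept"] + cov.loc[term, term]
                                 + 2 * cov.loc["Intercept", term]))
            p = float(pvals[term])
            sign = int(np.sign(params[term]))
        rows.append(dict(region=region, zone=zone, group=g,
                         mean_transformed=float(mean_t), se_transformed=float(se_t),
                         mean_bt=float(max(mean_t, 0.0) ** 4),
                         departure_p=p, departure_sign=sign,
                         departure=bool(p < alpha) if np.isfinite(p) else False,
                         n_transects=int((data["group"] == g).sum()),
                         n_sites=n_sites))
    return pd.DataFrame(rows)


def zone_estimates(fp: pd.DataFrame, zones: dict) -> pd.DataFrame:
    """zone_mixed_model over every non-reference zone of every region."""
    out = []
    for region, part in zones.items():
        for z in part.zones():
            if z == part.reference_zone:
                continue
            if ((fp["region"] == region) & (fp["zone"] == z)).any():
                out.append(zone_mixed_model(fp, region, z))
    return pd.concat(out, ignore_index=True)


def leading_edge(estimates: pd.DataFrame, zones: dict,
                 threshold: float = EDGE_THRESHOLD) -> pd.DataFrame:
    """Locate each group's 20-fold-decline leading edge and class it.

    Scanning zones poleward, the edge is the first zone whose modelled mean
    footprint drops below ``threshold``; groups never crossing get the
    does-not-decline sentinel.  Classes compare the edge with the
    community's: same zone (or poleward of it) -> as expected, one zone
    equatorward -> below expectation, two or more -> well below.
    """
    rows = []
    for region, part in zones.items():
        est = estimates[estimates["region"] == region]
        if COMMUNITY not in set(est["group"]):
            raise ValueError(f"community estimates missing for region {region}")

        def first_crossing(g: str):
            sub = est[est["group"] == g].sort_values("zone")
            below = sub[sub["mean_bt"] < threshold]
            return int(below["zone"].iloc[0]) if len(below) else None

        ce = first_crossing(COMMUNITY)
        for g in sorted(est["group"].unique()):
            ge = first_crossing(g)
            if g == COMMUNITY:
                cls = CLASS_AS_EXPECTED if ce is not None else CLASS_NO_DECLINE
            elif ge is None:
                cls = CLASS_NO_DECLINE
            elif ce is None:
                cls = CLASS_AS_EXPECTED
            elif ge >= ce:
                cls = CLASS_AS_EXPECTED
            elif ce - ge == 1:
                cls = CLASS_BELOW
            else:
                cls = CLASS_WELL_BELOW
            rows.append(dict(
                region=region, group=g, edge_zone=ge,
                edge_latitude=float(part.zone_latitude[ge]) if ge is not None else np.nan,
                edge_class=cls,
            ))
    return pd.DataFrame(rows)
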