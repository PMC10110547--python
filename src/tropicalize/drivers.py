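"""Driver inference: what explains differences in tropicalisation?

Two strands:

* within functional groups, Kendall rank correlations relate site-level
  footprints to niche metrics (area proportion = environmental filtering,
  overlap = thermal-guild competition), with zero-footprint sites removed
  first — a zero footprint forces both niche metrics to zero as well and
  would inflate the correlation;
* across groups (both regions combined), a battery of models tests each
  candidate driver against the leading-edge class: gamma GLMs for maximum
  guild biomass, quasi-binomial GLMs for the proportions, a quasi-Poisson
  GLM for species richness, a linear model for realised upper thermal
  limits, and chi-square tests for the categorical traits.  Quasi-family
  inference uses analysis-of-deviance F with Pearson dispersion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .footprint import COMMUNITY, CLASS_NO_DECLINE

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Kendall correlations with the zero-removal rule

def kendall_with_zero_removal(footprint, metric, min_pairs: int = 5) -> dict:
    """Two-sided Kendall tau between site footprints and a niche metric.

    Pairs where the footprint is exactly zero are dropped (their metrics
    are forced zeros, not signal); NaN metrics are dropped too.  Fewer than
    ``min_pairs`` surviving pairs yields a flagged, not-computed result.
    """
    x = np.asarray(footprint, dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.shape != y.shape:
        raise ValueError("footprint and metric must be paired")
    keep = (x != 0) & np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < min_pairs:
        return dict(tau=np.nan, p_value=np.nan, n=len(x), computed=False)
    tau, p = stats.kendalltau(x, y)
    return dict(tau=float(tau), p_value=float(p), n=len(x), computed=True)


def footprint_niche_correlations(fp: pd.DataFrame, metrics: pd.DataFrame,
                                 min_pairs: int = 5) -> pd.DataFrame:
    """Per (region, group): Kendall tau of site-level footprint against the
    tropical area proportion and against the tropical-temperate overlap."""
    site_fp = (
        fp[fp["group"] != COMMUNITY]
        .groupby(["region", "group", "site"])["bt"].mean().rename("footprint")
        .reset_index()
    )
    merged = site_fp.merge(metrics, on=["region", "group", "site"], how="inner")
    rows = []
    for (region, group), df in merged.groupby(["region", "group"]):
        for metric in ("tropical_area_proportion", "overlap_proportion"):
            r = kendall_with_zero_removal(df["footprint"], df[metric], min_pairs)
            rows.append(dict(region=region, group=group, metric=metric, **r))
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# zone-wise guild biomass maxima

def zone_guild_biomass(survey: pd.DataFrame, zones: dict, grouping,
                       traits: pd.DataFrame) -> pd.DataFrame:
    """Mean transect-level guild biomass per (region, zone, group, guild)."""
    guild_map = traits.set_index("species")["thermal_guild"]
    rows = []
    for region, part in zones.items():
        reg = survey[survey["region"] == region]
        per = reg.pivot_table(index=["site", "transect", "year"], columns="species",
                              values="biomass", aggfunc="sum", fill_value=0.0)
        zone_of = per.index.get_level_values("site").map(part.site_zone)
        for g in grouping.major_groups:
            members = grouping.species_group.index[grouping.species_group == g]
            for guild in ("tropical", "temperate"):
                sp = [s for s in members
                      if s in per.columns and guild_map.get(s) == guild]
                tot = per[sp].sum(axis=1) if sp else pd.Series(0.0, index=per.index)
                means = tot.groupby(zone_of).mean()
                for z, m in means.items():
                    rows.append(dict(region=region, group=g, guild=guild,
                                     zone=int(z), mean_biomass=float(m),
                                     zone_latitude=float(part.zone_latitude[z])))
    return pd.DataFrame(rows)


def zone_guild_max_biomass(survey: pd.DataFrame, zones: dict, grouping,
                           traits: pd.DataFrame) -> pd.DataFrame:
    """Maximum over zones of mean guild biomass, with the attaining zone.

    Groups absent everywhere in a guild return zero with a flag.
    """
    zb = zone_guild_biomass(survey, zones, grouping, traits)
    idx = zb.groupby(["region", "group", "guild"])["mean_biomass"].idxmax()
    out = zb.loc[idx].rename(columns={"mean_biomass": "max_biomass"})
    out["absent"] = out["max_biomass"] <= 0
    return out.reset_index(drop=True)


# ----------------------------------------------------------------------
# the leading-edge driver battery

def _anova_deviance_f(y, classes, family) -> dict:
    """Analysis-of-deviance F test of a class effect in a GLM.

    F = ((D_null - D_full)/df_num) / (Pearson dispersion of the full
    model), the conventional quasi-family counterpart of an ANOVA.
    """
    X = pd.get_dummies(pd.Series(classes, name="cls"), drop_first=True, dtype=float)
    X_full = sm.add_constant(X)
    X_null = np.ones((len(y), 1))
    full = sm.GLM(y, X_full, family=family).fit()
    null = sm.GLM(y, X_null, family=family).fit()
    df_num = X.shape[1]
    df_den = int(full.df_resid)
    scale = full.pearson_chi2 / df_den
    f = float((null.deviance - full.deviance) / df_num / scale)
    p = float(stats.f.sf(f, df_num, df_den))
    return dict(statistic=f, statistic_name="F", df1=df_num, df2=df_den, p_value=p)


def _lm_anova_f(y, classes) -> dict:
    X = pd.get_dummies(pd.Series(classes, name="cls"), drop_first=True, dtype=float)
    full = sm.OLS(np.asarray(y, float), sm.add_constant(X)).fit()
    f, p = float(full.fvalue), float(full.f_pvalue)
    return dict(statistic=f, statistic_name="F", df1=int(full.df_model),
                df2=int(full.df_resid), p_value=p)


def _chi_square(values, classes) -> dict:
    table = pd.crosstab(pd.Series(values, name="v"), pd.Series(classes, name="cls"))
    if (table.to_numpy().sum(axis=1) == 0).any() or table.shape[0] < 2 or table.shape[1] < 2:
        return dict(statistic=np.nan, statistic_name="chi2", df1=0, df2=np.nan,
                    p_value=np.nan)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        log.warning("chi-square with expected counts < 5; interpret with care")
    return dict(statistic=float(chi2), statistic_name="chi2", df1=int(dof),
                df2=np.nan, p_value=float(p))


#: (test name, response column, kind) — the declared battery.
BATTERY = [
    ("max_tropical_biomass", "max_tropical_biomass", "gamma"),
    ("max_temperate_biomass", "max_temperate_biomass", "gamma"),
    ("niche_overlap", "overlap_proportion", "quasibinomial"),
    ("tropical_area_proportion", "tropical_area_proportion", "quasibinomial"),
    ("species_richness", "richness", "quasipoisson"),
    ("realised_thermal_limit", "thermal_limit", "lm"),
    ("diet", "diet", "chi2"),
    ("habitat_position", "position", "chi2"),
    ("region", "region", "chi2"),
]


def leading_edge_driver_tests(
    driver_table: pd.DataFrame,
    include_does_not_decline: bool = False,
    tests: list | None = None,
) -> pd.DataFrame:
    """Run the driver battery against leading-edge class.

    ``driver_table`` has one row per (group, region) with an ``edge_class``
    column and the response columns named in :data:`BATTERY`.  Rows with an
    undefined response are dropped per test; gamma responses must be
    positive (offending rows are reported and dropped); the
    does-not-decline class is excluded unless requested.
    """
    df = driver_table.copy()
    if not include_does_not_decline:
        df = df[df["edge_class"] != CLASS_NO_DECLINE]
    results = []
    for name, col, kind in (tests or BATTERY):
        if col not in df.columns:
            continue
        sub = df.dropna(subset=[col, "edge_class"])
        note = ""
        if kind == "gamma":
            bad = sub[pd.to_numeric(sub[col], errors="coerce") <= 0]
            if len(bad):
                note = f"dropped non-positive gamma rows: {list(bad.index)}"
                log.warning("%s: %s", name, note)
                sub = sub[pd.to_numeric(sub[col], errors="coerce") > 0]
        classes = sub["edge_class"].astype(str)
        if classes.nunique() < 2 or len(sub) < classes.nunique() + 2:
            results.append(dict(test=name, family=kind, statistic=np.nan,
                                statistic_name="", df1=0, df2=np.nan, p_value=np.nan,
                                n=len(sub), note="skipped: fewer than two usable classes"))
            continue
        y = sub[col]
        if kind == "gamma":
            r = _anova_deviance_f(y.astype(float), classes,
                                  sm.families.Gamma(link=sm.families.links.Log()))
        elif kind == "quasibinomial":
            r = _anova_deviance_f(np.clip(y.astype(float), 0.0, 1.0), classes,
                                  sm.families.Binomial())
        elif kind == "quasipoisson":
            r = _anova_deviance_f(y.astype(float), classes, sm.families.Poisson())
        elif kind == "lm":
            r = _lm_anova_f(y, classes)
        elif kind == "chi2":
            r = _chi_square(y, classes)
        else:  # pragma: no cover
            raise ValueError(f"unknown test kind {kind}")
        if kind in ("gamma", "quasibinomial", "quasipoisson", "lm"):
            summ = sub.groupby("edge_class")[col].agg(["mean", "std", "count"])
            note = (note + " " if note else "") + "; ".join(
                f"{c}: {m:.4g}±{s:.4g} (n={int(k)})"
                for c, (m, s, k) in summ.iterrows()
            )
        results.append(dict(test=name, family=kind, n=len(sub), note=note, **r))
    return pd.DataFrame(results)


def build_driver_table(survey, zones, grouping, traits, edges, metrics) -> pd.DataFrame:
    """Assemble the per-(group, region) driver table from upstream outputs."""
    from .grouping import characterise_groups

    maxima = zone_guild_max_biomass(survey, zones, grouping, traits)
    wide_max = maxima.pivot_table(index=["region", "group"], columns="guild",
                                  values="max_biomass")
    site_means = metrics.groupby(["region", "group"])[
        ["overlap_proportion", "tropical_area_proportion"]
    ].mean()
    guild_map = traits.set_index("species")["thermal_guild"]
    limits = traits.set_index("species")["realised_upper_thermal_limit"] \
        if "realised_upper_thermal_limit" in traits.columns else None
    char = characterise_groups(grouping, traits)
    dominant = {
        (t, g): lv
        for (g, t), lv in char[char["dominant"]]
        .groupby(["group", "trait"])["level"].first().items()
    }
    rows = []
    for _, e in edges.iterrows():
        g, region = e["group"], e["region"]
        if g == COMMUNITY:
            continue
        members = grouping.species_group.index[grouping.species_group == g]
        observed = set(survey.loc[survey["region"] == region, "species"]) & set(members)
        trop = [s for s in observed if guild_map.get(s) == "tropical"]
        rows.append(dict(
            region=region, group=g, edge_class=e["edge_class"],
            edge_zone=e["edge_zone"], edge_latitude=e["edge_latitude"],
            max_tropical_biomass=float(wide_max.loc[(region, g)].get("tropical", np.nan)),
            max_temperate_biomass=float(wide_max.loc[(region, g)].get("temperate", np.nan)),
            overlap_proportion=float(site_means.loc[(region, g), "overlap_proportion"])
            if (region, g) in site_means.index else np.nan,
            tropical_area_proportion=float(
                site_means.loc[(region, g), "tropical_area_proportion"])
            if (region, g) in site_means.index else np.nan,
            richness=len(observed),
            thermal_limit=float(limits.reindex(trop).mean()) if limits is not None and trop
            else np.nan,
            diet=dominant.get(("diet", g)),
            position=dominant.get(("habitat_association", g)),
        ))
    return pd.DataFrame(rows)


def null_rejection_rate(driver_table: pd.DataFrame, n_perm: int = 200,
                        alpha: float = 0.05, seed: int = 0,
                        tests: list | None = None) -> dict:
    """Empirical type-I error of the battery under permuted class labels.

    Permutes ``edge_class`` across rows, reruns the battery, and pools
    rejections over permutations and tests.  A calibrated battery rejects
    at about ``alpha``.
    """
    rng = np.random.default_rng(seed)
    labels = driver_table["edge_class"].to_numpy().copy()
    n_reject = n_total = 0
    for _ in range(n_perm):
        perm = driver_table.copy()
        perm["edge_class"] = rng.permutation(labels)
        res = leading_edge_driver_tests(perm, include_does_not_decline=True, tests=tests)
        p = res["p_value"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        n_reject += int((p[ok] < alpha).sum())
        n_total += int(ok.sum())
    return dict(rejection_rate=n_reject / max(n_total, 1),
                n_tests=n_total, n_perm=n_perm, alpha=alpha)
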