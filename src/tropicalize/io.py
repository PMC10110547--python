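"""Survey / trait table I-O, shared core types and validation.

Tables are plain :class:`pandas.DataFrame` objects with documented schemas;
this module owns the schemas and validates on every read and write, so any
file either yields a valid table or a row-numbered diagnostic — never a
silently coerced one.

Schemas
-------
SurveyTable
    columns ``region, site, latitude, transect, year, species, biomass``;
    one row per (region, site, transect, year, species); ``biomass`` is
    standardised g/m² per transect, ``latitude`` is signed degrees.
TraitTable
    indexed by species; columns ``diet, habitat_association, body_size,
    aggregation, depth_range, thermal_guild`` and optionally
    ``realised_upper_thermal_limit``.  ``diet`` and ``depth_range`` may be
    missing (rare); ``thermal_guild`` never.

CSV dialect: UTF-8, comma-separated, header row, '.' decimal, missing
values as empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SURVEY_COLUMNS = ["region", "site", "latitude", "transect", "year", "species", "biomass"]
SURVEY_KEY = ["region", "site", "transect", "year", "species"]
TRAIT_COLUMNS = [
    "species", "diet", "habitat_association", "body_size",
    "aggregation", "depth_range", "thermal_guild",
]
THERMAL_GUILDS = ("tropical", "temperate")


class SchemaError(ValueError):
    """A required column is absent or of the wrong kind."""


class ValidationError(ValueError):
    """Rows violate a table invariant; the message lists the offenders."""


# ----------------------------------------------------------------------
# validation

def _offenders(index, limit: int = 10) -> str:
    rows = list(index[:limit])
    more = "" if len(index) <= limit else f" (+{len(index) - limit} more)"
    return f"rows {rows}{more}"


def validate_survey(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey table missing required columns: {missing}")
    df = df[SURVEY_COLUMNS].copy()
    df["biomass"] = pd.to_numeric(df["biomass"], errors="coerce")
    df["latitude"] = pd.to_numeric(df["latitude"], errors="coerce")
    bad = df.index[df["biomass"].isna() | ~np.isfinite(df["biomass"])]
    if len(bad):
        raise ValidationError(f"non-numeric or non-finite biomass: {_offenders(bad)}")
    bad = df.index[df["biomass"] < 0]
    if len(bad):
        raise ValidationError(f"negative biomass: {_offenders(bad)}")
    bad = df.index[df["latitude"].isna() | (df["latitude"].abs() > 90)]
    if len(bad):
        raise ValidationError(f"latitude missing or outside ±90: {_offenders(bad)}")
    dup = df.index[df.duplicated(subset=SURVEY_KEY, keep=False)]
    if len(dup):
        raise ValidationError(
            f"duplicated (region, site, transect, year, species) key: {_offenders(dup)}"
        )
    return df


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trait table missing required columns: {missing}")
    df = df.copy()
    dup = df.index[df.duplicated(subset="species", keep=False)]
    if len(dup):
        raise ValidationError(f"duplicated species: {_offenders(dup)}")
    bad = df.index[~df["thermal_guild"].isin(THERMAL_GUILDS)]
    if len(bad):
        raise ValidationError(
            f"thermal_guild must be one of {THERMAL_GUILDS} and never missing: {_offenders(bad)}"
        )
    for col in ("body_size", "depth_range"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & (df[col] <= 0)]
        if len(bad):
            raise ValidationError(f"non-positive {col}: {_offenders(bad)}")
    bad = df.index[df["body_size"].isna()]
    if len(bad):
        raise ValidationError(f"missing body_size: {_offenders(bad)}")
    return df


# ----------------------------------------------------------------------
# round-trip I/O

def read_survey(path) -> pd.DataFrame:
    """Read and validate a survey CSV. Empty ``year`` fields become -1."""
    df = pd.read_csv(path)
    if "year" in df.columns:
        df["year"] = df["year"].fillna(-1).astype(int)
    return validate_survey(df)


def write_survey(df: pd.DataFrame, path) -> None:
    validate_survey(df).to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    return validate_traits(pd.read_csv(path))


def write_traits(df: pd.DataFrame, path) -> None:
    validate_traits(df).to_csv(path, index=False)


# ----------------------------------------------------------------------
# biomass standardisation

@dataclass(frozen=True)
class LengthWeightParams:
    """Allometric length-weight coefficients, B = a · length^b (g, cm)."""

    species: str
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"{self.species}: length-weight coefficient a must be > 0")
        if not 1.0 < self.b < 4.0:
            raise ValueError(f"{self.species}: length-weight exponent b must lie in (1, 4)")


def biomass_from_length(length_cm: float, params: LengthWeightParams) -> float:
    """Individual biomass in grams from length via B = a · length^b."""
    if length_cm <= 0:
        raise ValueError(f"length must be > 0, got {length_cm}")
    return params.a * length_cm ** params.b


def standardise_biomass(
    counts_and_lengths: pd.DataFrame,
    transect_length_m: float,
    transect_width_m: float,
    params: dict[str, LengthWeightParams],
) -> pd.DataFrame:
    """Convert raw counts-and-lengths to per-transect g/m² per species.

    ``counts_and_lengths`` needs columns ``transect, species, length, count``.
    Per-transect species biomass is summed over individuals then divided by
    transect area; species recorded on some transect but absent from another
    appear there as explicit zeros.
    """
    if transect_length_m <= 0 or transect_width_m <= 0:
        raise ValueError("transect dimensions must be positive")
    unknown = sorted(set(counts_and_lengths["species"]) - set(params))
    if unknown:
        raise ValueError(f"no length-weight parameters for species: {unknown}")
    area = transect_length_m * transect_width_m
    df = counts_and_lengths.copy()
    df["grams"] = [
        biomass_from_length(l, params[s]) * c
        for s, l, c in zip(df["species"], df["length"], df["count"])
    ]
    wide = (
        df.pivot_table(index="transect", columns="species", values="grams",
                       aggfunc="sum", fill_value=0.0)
        / area
    )
    out = wide.stack().rename("biomass").reset_index()
    return out


# ----------------------------------------------------------------------
# distance matrices

@dataclass
class DistanceMatrix:
    """A labelled square dissimilarity matrix (symmetric, zero diagonal)."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite values")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.values, checks=False)


# ----------------------------------------------------------------------
# deposited species-table summary

def species_table_summary(traits: pd.DataFrame, group: pd.Series) -> dict:
    """Headline descriptive statistics of a species/trait/group table.

    Given a validated trait table and a species→functional-group mapping,
    returns the share of species held by the nine largest groups (percent),
    and the counts of missing depth-range and diet values.
    """
    sizes = group.value_counts()
    nine = sizes.iloc[:9].sum() if len(sizes) >= 9 else sizes.sum()
    return {
        "nine_major_group_species_share_pct": 100.0 * nine / len(group),
        "n_missing_depth_range": int(traits["depth_range"].isna().sum()),
        "n_missing_diet": int(traits["diet"].isna().sum()),
    }
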