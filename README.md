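# tropicalize

Trait-based analysis of reef-fish **tropicalisation** — the progressive
invasion of temperate and transitional reef communities by warm-affinity
species as oceans warm.  The package implements, as a tested pipeline, the
full chain of analyses used to ask *which ecosystem functions tropicalise,
how fast, and why*:

1. **Zonation** — sites are grouped into latitudinal community zones by
   average-linkage clustering of Bray–Curtis distances between
   log-transformed site × species biomass profiles; the lowest-latitude
   zone is the Tropical Coral Reef reference.
2. **Functional groups** — species are clustered on Gower distances over
   five traits (diet, habitat association, body size, aggregation, depth
   range; missing values handled by pairwise exclusion), with a
   1000-iteration 5%-omission bootstrap profiling silhouette, clusterwise
   Jaccard and Rand stability over k = 2…30.
3. **Tropicalisation footprints** — per functional group *i* and transect
   *j*,

       BT_ij = b_ij / b̄_i

   the group's tropical biomass relative to the mean over reference-zone
   transects.  Fourth-root-transformed footprints are modelled per zone by
   linear mixed models (site random intercept) against the community
   baseline, and each group's **leading edge** is the first zone whose
   modelled footprint falls below 1/20.
4. **Functional niches** — species are embedded by Cailliez-corrected
   PCoA of the Gower matrix; in each of the six axis-pair planes the niche
   of a guild at a site is its 99% kernel utilisation distribution, giving
   a tropical niche area (relative to the reference zone — environmental
   filtering) and a tropical–temperate overlap (competition proxy), with
   variance-weighted averaging and a zero-forcing rule.
5. **Drivers** — Kendall correlations (zero-footprint sites removed) link
   footprints to niche metrics within groups, and a GLM/χ² battery (gamma,
   quasi-binomial, quasi-Poisson, linear, chi-square) tests what explains
   leading-edge differences across groups and regions.

Because the original surveys are controlled-access, the package ships a
**synthetic metacommunity generator** with known ground truth (configured
zones, group membership, 20-fold-decline latitudes, guild niche overlap),
so every stage is testable end to end.  It is intended for quantitative
ecologists who want to apply footprint/niche analyses to their own survey
+ trait tables, or to study the estimators' behaviour under a known model.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic scenario (2 regions × 30 sites × 4 transects, 300 species, 9
functional groups) and write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_zone.py
python analysis/03_functional_groups.py --k 9   # profile-supported override
python analysis/04_footprints.py
python analysis/05_niche.py
python analysis/06_drivers.py
```

`04_footprints.py` prints the leading-edge table (Australia shown):

```
   region     group  edge_zone  edge_latitude             edge_class
Australia       FG1          5       34.10302            as_expected
Australia       FG2          5       34.10302            as_expected
Australia       FG3          5       34.10302            as_expected
Australia       FG4          5       34.10302            as_expected
Australia       FG5          4       31.45918      below_expectation
Australia       FG6          1       26.07608 well_below_expectation
Australia       FG7          3       30.03456 well_below_expectation
Australia       FG8          3       30.03456 well_below_expectation
Australia community          5       34.10302            as_expected
```

The four species-rich generalist groups (FG1–FG4) lose 95% of their
tropical biomass only in the most poleward zone, matching the
community-wide leading edge; the specialist groups drop out one to four
zones earlier — exactly the zones implied by their configured 20-fold
latitudes.  `06_drivers.py` then prints the driver battery:

```
                    test        family  statistic  df1  df2  p_value
    max_tropical_biomass         gamma  3266.5373    2 13.0   0.0000
   max_temperate_biomass         gamma   292.6518    2 13.0   0.0000
           niche_overlap quasibinomial    73.8503    2 13.0   0.0000
tropical_area_proportion quasibinomial     5.3444    2 13.0   0.0202
        species_richness  quasipoisson    22.7782    2 13.0   0.0001
  realised_thermal_limit            lm     7.7288    2 13.0   0.0061
                    diet          chi2    16.4444    6  NaN   0.0116
        habitat_position          chi2     5.7778    4  NaN   0.2164
                  region          chi2     0.0000    2  NaN   1.0000
```

Groups with broad, occupied temperate niches (site-mean overlap 45–80%)
are the ones whose leading edges keep pace with the community, while the
zero-overlap groups fall behind — the "occupied temperate functional
niches promote tropicalisation" signal the scenario builds in.  The region
test is null by construction (both regions share one trend model).

To run your own data instead of the generator, write your survey and trait
tables in the CSV schemas of `tropicalize.io` (see docstrings) and start
from `analysis/02_zone.py`.

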