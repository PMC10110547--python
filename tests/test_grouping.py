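import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import pearsonr
from sklearn.metrics import rand_score

from tropicalize import default_scenario, generate_metacommunity
from tropicalize.grouping import (gower_distance, trait_ranges, cluster_species,
                                  cophenetic_fidelity, bootstrap_stability, select_k,
                                  characterise_groups, species_tree, tree_to_newick,
                                  clusterwise_jaccard)
from tropicalize.io import DistanceMatrix

from conftest import tiny_traits


# ----------------------------------------------------------------------
# brute-force Gower oracle: per-pair loop over traits, no vectorisation

def gower_oracle(traits: pd.DataFrame) -> np.ndarray:
    ranges = trait_ranges(traits)
    n = len(traits)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for col, kind in [("diet", "nom"), ("habitat_association", "nom"),
                              ("body_size", "log"), ("depth_range", "log"),
                              ("aggregation", "ord")]:
                a, b = traits[col].iloc[i], traits[col].iloc[j]
                if pd.isna(a) or pd.isna(b):
                    continue
                if kind == "nom":
                    num += float(a != b)
                else:
                    va, vb = (np.log(a), np.log(b)) if kind == "log" else (a, b)
                    num += abs(va - vb) / ranges[col] if ranges[col] > 0 else 0.0
                den += 1
            d[i, j] = num / den
    return d


@st.composite
def trait_frames(draw):
    n = draw(st.integers(3, 8))
    rows = []
    for _ in range(n):
        rows.append(dict(
            diet=draw(st.sampled_from(["herbivore", "predator", "omnivore"])),
            habitat_association=draw(st.sampled_from(["benthic", "demersal"])),
            body_size=draw(st.floats(1.0, 100.0)),
            aggregation=draw(st.integers(1, 5)),
            depth_range=draw(st.one_of(st.none(), st.floats(1.0, 80.0))),
        ))
    # ensure at least one pair is fully comparable
    rows[0]["depth_range"] = rows[1]["depth_range"] = 10.0
    return tiny_traits(rows)


class TestGower:
    def test_identical_rows_zero(self):
        t = tiny_traits([{}, {}])
        assert gower_distance(t).values[0, 1] == 0.0

    def test_single_nominal_mismatch_is_one_fifth(self):
        t = tiny_traits([{"diet": "herbivore"}, {"diet": "predator"}])
        assert gower_distance(t).values[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_missing_trait_renormalises(self):
        t = tiny_traits([{"diet": "herbivore"},
                         {"diet": "predator", "depth_range": np.nan}])
        assert gower_distance(t).values[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_no_comparable_traits_names_pair(self):
        t = tiny_traits([{}, {}])
        t.loc[0, ["diet", "habitat_association", "depth_range"]] = np.nan
        t.loc[1, ["body_size", "aggregation"]] = np.nan
        t["body_size"] = t["body_size"].astype(float)
        with pytest.raises(ValueError, match="s1.*s2"):
            gower_distance(t)

    @settings(deadline=None, max_examples=40)
    @given(trait_frames())
    def test_matches_bruteforce_oracle(self, traits):
        got = gower_distance(traits).values
        expected = gower_oracle(traits)
        assert np.allclose(got, expected, atol=1e-12)
        assert np.all((got >= 0) & (got <= 1 + 1e-12))

    def test_row_order_invariance(self):
        t = tiny_traits([{"diet": "herbivore", "body_size": 5.0},
                         {"diet": "predator", "body_size": 50.0},
                         {"diet": "omnivore", "aggregation": 4}])
        d1 = gower_distance(t)
        perm = [2, 0, 1]
        d2 = gower_distance(t.iloc[perm].reset_index(drop=True))
        reorder = [d2.labels.index(l) for l in d1.labels]
        assert np.allclose(d1.values, d2.values[np.ix_(reorder, reorder)])


class TestClusterSpecies:
    def two_archetype_traits(self):
        rows = [{"diet": "herbivore", "habitat_association": "benthic",
                 "body_size": 5.0, "depth_range": 5.0}] * 5
        rows += [{"diet": "predator", "habitat_association": "demersal",
                  "body_size": 80.0, "depth_range": 60.0, "aggregation": 5}] * 5
        return tiny_traits(rows)

    def test_two_archetypes_recovered_at_k2(self):
        g = cluster_species(gower_distance(self.two_archetype_traits()), 2)
        labels = g.species_group
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_k_equals_n_gives_singletons(self):
        t = tiny_traits([{"body_size": float(b)} for b in (1, 3, 9, 27)])
        g = cluster_species(gower_distance(t), 4)
        assert (g.sizes == 1).all()

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            cluster_species(gower_distance(self.two_archetype_traits()), 1)

    def test_default_scenario_recovery(self, small_world):
        _, traits, truth = small_world
        g = cluster_species(gower_distance(traits), 9)
        true_labels = [truth.species_group[s] for s in g.species_group.index]
        assert rand_score(true_labels, g.species_group.values) >= 0.95


class TestCophenetic:
    def test_ultrametric_input_perfect(self):
        # distances generated from an ultrametric tree: UPGMA reproduces them
        v = np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], float)
        d = DistanceMatrix(list("abcd"), v)
        assert cophenetic_fidelity(d) == pytest.approx(1.0)

    def test_matches_bruteforce_correlation(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, (6, 3))
        v = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))
        d = DistanceMatrix(list("abcdef"), v)
        tree = species_tree(d)
        from scipy.cluster.hierarchy import cophenet
        coph = cophenet(tree)
        r_expected, _ = pearsonr(d.condensed(), coph)
        assert cophenetic_fidelity(d, tree) == pytest.approx(r_expected, abs=1e-12)

    def test_newick_export_parses(self):
        t = tiny_traits([{"body_size": float(b)} for b in (1, 3, 9)])
        d = gower_distance(t)
        nwk = tree_to_newick(species_tree(d), d.labels)
        assert nwk.endswith(";") and all(s in nwk for s in d.labels)


class TestBootstrapStability:
    def separable(self):
        rows = [{"diet": "herbivore", "habitat_association": "benthic",
                 "body_size": 4.0 + i * 0.1, "depth_range": 5.0} for i in range(20)]
        rows += [{"diet": "predator", "habitat_association": "demersal",
                  "body_size": 70.0 + i, "depth_range": 60.0, "aggregation": 5}
                 for i in range(20)]
        return tiny_traits(rows)

    def test_separable_case_is_stable(self):
        prof = bootstrap_stability(self.separable(), k_range=[2], n_boot=30, seed=1)
        row = prof.iloc[0]
        assert row["mean_jaccard"] >= 0.99
        assert row["mean_rand"] >= 0.99

    def test_structured_beats_unstructured_at_k9(self, small_world, rng):
        _, traits, _ = small_world
        structured = bootstrap_stability(traits, k_range=[9], n_boot=15, seed=2)
        flat = traits.copy()
        for col in ("body_size", "depth_range"):
            flat[col] = rng.uniform(1.0, 100.0, len(flat))
        for col, levels in [("diet", 5), ("habitat_association", 3)]:
            flat[col] = rng.choice(flat[col].dropna().unique(), len(flat))
        flat["aggregation"] = rng.integers(1, 6, len(flat))
        unstructured = bootstrap_stability(flat, k_range=[9], n_boot=15, seed=2)
        assert structured["mean_jaccard"].iloc[0] > unstructured["mean_jaccard"].iloc[0]

    def test_same_seed_identical_profile(self):
        t = self.separable()
        p1 = bootstrap_stability(t, k_range=[2, 3], n_boot=10, seed=7)
        p2 = bootstrap_stability(t, k_range=[2, 3], n_boot=10, seed=7)
        pd.testing.assert_frame_equal(p1, p2)

    def test_insufficient_species_for_k_range(self):
        with pytest.raises(ValueError, match="too few"):
            bootstrap_stability(self.separable(), k_range=range(2, 45), n_boot=2)

    def test_clusterwise_jaccard_definition(self):
        orig = pd.Series([1, 1, 2, 2], index=list("abcd"))
        boot = pd.Series([5, 5, 5, 6], index=list("abcd"))
        # cluster {a,b}: best match {a,b,c} -> 2/3; cluster {c,d}: best 1/2
        assert clusterwise_jaccard(orig, boot) == pytest.approx((2 / 3 + 1 / 2) / 2)


class TestSelectK:
    def profile(self, sil, jac):
        return pd.DataFrame(dict(k=range(2, 2 + len(sil)),
                                 mean_silhouette=sil, mean_jaccard=jac))

    def test_unique_peak_selected(self):
        p = self.profile([0.2, 0.5, 0.9, 0.4, 0.3], [0.9] * 5)
        assert select_k(p) == 4  # peak at third entry, k=4

    def test_flat_profile_warns_argmax(self):
        p = self.profile([0.5] * 4, [0.9] * 4)
        with pytest.warns(UserWarning, match="argmax"):
            assert select_k(p) == 2

    def test_unsatisfiable_threshold_warns(self):
        p = self.profile([0.2, 0.9, 0.3], [0.9] * 3)
        with pytest.warns(UserWarning):
            select_k(p, jaccard_threshold=1.01)


class TestCharacteriseGroups:
    def test_uniform_group_frequency_one(self, small_world, true_grouping):
        _, traits, _ = small_world
        char = characterise_groups(true_grouping, traits)
        freq_sums = char.groupby(["group", "trait"])["frequency"].sum()
        assert np.allclose(freq_sums, 1.0)

    def test_dominant_levels_equal_archetypes(self, small_scenario, small_world,
                                              true_grouping):
        _, traits, _ = small_world
        char = characterise_groups(true_grouping, traits)
        dom = char[char["dominant"]].set_index(["group", "trait"])["level"]
        for g in small_scenario.groups:
            assert dom[(g.name, "diet")] == g.diet
            assert dom[(g.name, "habitat_association")] == g.habitat
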