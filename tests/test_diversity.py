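import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forestdyn.diversity import (
    INDEX_NAMES,
    NullModelSpec,
    change_values,
    community_matrix,
    diversity_profile,
    functional_dispersion,
    gower_distance,
    independent_swap,
    raw_mntd,
    raw_mpd,
    ses_metric,
    structural_indices,
    taxonomic_indices,
    trait_dendrogram,
)
from forestdyn.errors import InvalidConfigurationError


def dist_frame(values, labels):
    return pd.DataFrame(values, index=labels, columns=labels, dtype=float)


TINY = dist_frame([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ["s1", "s2", "s3"])


class TestTaxonomic:
    def test_monoculture(self):
        h, d, j = taxonomic_indices([7])
        assert h == 0 and d == 0 and np.isnan(j)

    def test_uniform_four_species(self):
        h, d, j = taxonomic_indices([5, 5, 5, 5])
        assert h == pytest.approx(math.log(4))
        assert d == pytest.approx(0.75)
        assert j == pytest.approx(1.0)

    def test_hand_computed_counts(self):
        h, d, j = taxonomic_indices([8, 2])
        assert h == pytest.approx(-(0.8 * math.log(0.8) + 0.2 * math.log(0.2)))
        assert d == pytest.approx(1 - 0.8**2 - 0.2**2)

    def test_empty_community_flagged_not_raised(self):
        assert all(np.isnan(v) for v in taxonomic_indices([]))

    def test_dominance_form_option(self):
        _, d_gini, _ = taxonomic_indices([8, 2])
        _, d_dom, _ = taxonomic_indices([8, 2], gini=False)
        assert d_dom == pytest.approx(1 - d_gini)

    @given(st.lists(st.integers(1, 500), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, counts):
        h, d, j = taxonomic_indices(counts)
        assert h >= 0 and 0 <= d < 1 and 0 <= j <= 1 + 1e-12


class TestStructural:
    def test_equal_dbh_zero_cv(self):
        assert structural_indices([5.0, 5.0, 5.0]) == (3, pytest.approx(0.0))

    def test_hand_computed_sample_sd(self):
        sd, cv = structural_indices([2.0, 4.0, 6.0])
        assert sd == 3 and cv == pytest.approx(0.5)  # sd=2 (n-1), mean=4

    def test_scale_invariance(self):
        cm = structural_indices([2.0, 7.0, 9.0])[1]
        mm = structural_indices([20.0, 70.0, 90.0])[1]
        assert cm == pytest.approx(mm)

    def test_singleton_missing(self):
        sd, cv = structural_indices([4.2])
        assert sd == 1 and np.isnan(cv)


class TestSes:
    def test_exhaustive_enumeration_of_tiny_pool(self):
        # pool {s1,s2,s3}, pairwise distances 1, 2, 3; community {s1,s2}
        # null distribution over the three possible pairs = {1, 2, 3}
        ses = ses_metric(["s1", "s2"], TINY, "MPD", exhaustive=True)
        assert ses == pytest.approx((1 - 2) / np.std([1, 2, 3]))

    def test_sign_flip_contract(self):
        plain = ses_metric(["s1", "s2"], TINY, "MPD", exhaustive=True)
        flipped = ses_metric(["s1", "s2"], TINY, "MPD", exhaustive=True, sign_flip=True)
        assert flipped == pytest.approx(-plain)

    def test_saturated_community_degenerate(self):
        ses = ses_metric(["s1", "s2", "s3"], TINY, "MPD", NullModelSpec(n_iterations=50, seed=1))
        assert np.isnan(ses)

    def test_richness_below_two_missing(self):
        assert np.isnan(ses_metric(["s1"], TINY, "MNTD"))

    def test_unknown_species_keyed(self):
        with pytest.raises(KeyError):
            ses_metric(["s1", "zz"], TINY, "MPD")

    def test_monte_carlo_converges_to_enumeration(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0.5, 3.0, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dist = dist_frame(d, [f"s{i}" for i in range(6)])
        for metric in ("MPD", "MNTD"):
            mc = ses_metric(["s0", "s2", "s4"], dist, metric,
                            NullModelSpec(n_iterations=30000, seed=2))
            ex = ses_metric(["s0", "s2", "s4"], dist, metric, exhaustive=True)
            assert mc == pytest.approx(ex, abs=0.03)

    def test_equal_abundances_match_presence_based(self):
        spec = NullModelSpec(n_iterations=200, seed=3)
        unweighted = ses_metric(["s1", "s3"], TINY, "MPD", spec)
        weighted = ses_metric(["s1", "s3"], TINY, "MPD", spec, abundances=[4, 4])
        assert weighted == pytest.approx(unweighted)

    def test_raw_mntd_bounded_by_max_pairwise(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(0, 5, (8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        for k in (2, 4, 6):
            idx = rng.choice(8, k, replace=False)
            sub = d[np.ix_(idx, idx)]
            assert raw_mntd(sub) <= sub.max() + 1e-12
            assert raw_mpd(sub) <= sub.max() + 1e-12


class TestTraitSpace:
    def test_identical_species_distance_zero(self, tiny_pool):
        traits = tiny_pool.traits.copy()
        traits.loc["s2"] = traits.loc["s1"]
        g = gower_distance(type(tiny_pool)(traits, tiny_pool.pooled_height))
        assert g.at["s1", "s2"] == pytest.approx(0.0)

    def test_life_form_only_difference_is_one_third(self, tiny_pool):
        traits = tiny_pool.traits.copy()
        traits.loc["s2"] = traits.loc["s1"]
        traits.at["s2", "life_form"] = "coniferous"
        g = gower_distance(type(tiny_pool)(traits, tiny_pool.pooled_height))
        assert g.at["s1", "s2"] == pytest.approx(1 / 3)

    def test_gower_bounds_and_symmetry(self, tiny_pool):
        g = gower_distance(tiny_pool)
        arr = g.to_numpy()
        assert np.allclose(arr, arr.T)
        assert arr.min() >= 0 and arr.max() <= 1 + 1e-12
        assert np.allclose(np.diag(arr), 0)

    def test_dendrogram_cophenetic_is_ultrametric(self, tiny_pool):
        coph, _ = trait_dendrogram(tiny_pool)
        c = coph.to_numpy()
        for i, j, k in itertools.permutations(range(len(c)), 3):
            assert c[i, j] <= max(c[i, k], c[j, k]) + 1e-9


class TestFunctionalDispersion:
    def test_monoculture_zero(self):
        fdis, raoq = functional_dispersion([5], np.zeros((1, 1)))
        assert fdis == 0 and raoq == 0

    def test_two_point_geometry(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        fdis, raoq = functional_dispersion([1, 1], d)
        assert raoq == pytest.approx(1.0)  # 2 * 0.25 * 2
        assert fdis == pytest.approx(1.0)  # centroid at the midpoint

    def test_raoq_abundance_scale_invariance(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 1, (5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        a = rng.integers(1, 9, 5)
        _, q1 = functional_dispersion(a, d)
        _, q2 = functional_dispersion(2 * a, d)
        assert q1 == pytest.approx(q2)

    def test_raoq_bounded_by_max_distance(self, tiny_pool):
        _, g = trait_dendrogram(tiny_pool)
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.integers(0, 10, 6)
            if a.sum() == 0:
                continue
            fdis, raoq = functional_dispersion(a, g)
            assert raoq <= g.to_numpy().max() + 1e-12
            assert fdis >= 0


class TestProfileAndChanges:
    def test_profile_columns_and_determinism(self, small_study):
        pool = small_study.species_pool
        from forestdyn.biomass import impute_wood_density
        from forestdyn.simulate import phylo_distance_matrix

        pool = impute_wood_density(pool)
        phylo = phylo_distance_matrix(pool.tree).loc[pool.species, pool.species]
        dendro, gower = trait_dendrogram(pool)
        spec = NullModelSpec(n_iterations=49, seed=9)
        quadrats = small_study.landscape.frame.index
        census = small_study.censuses[small_study.censuses["census"].isin([1])]
        p1 = diversity_profile(census, pool, phylo, dendro, gower, spec, quadrats=quadrats)
        p2 = diversity_profile(census, pool, phylo, dendro, gower, spec, quadrats=quadrats)
        pd.testing.assert_frame_equal(p1, p2)
        assert set(INDEX_NAMES) <= set(p1.columns)

    def test_change_values_identical_censuses_zero(self, tiny_pool):
        prof = pd.DataFrame({"quadrat": ["QA", "QA"], "census": [1, 2]})
        for n in INDEX_NAMES:
            prof[n] = [1.5, 1.5]
        ch = change_values(prof)
        assert (ch[[f"c{n}" for n in INDEX_NAMES]] == 0).all().all()

    def test_change_subtraction_and_missing_propagation(self):
        prof = pd.DataFrame({"quadrat": ["QA", "QA"], "census": [1, 2]})
        for n in INDEX_NAMES:
            prof[n] = [1.2, 1.5]
        prof.loc[prof["census"] == 1, "CV_DBH"] = np.nan
        ch = change_values(prof)
        assert ch["cH"].iloc[0] == pytest.approx(0.3)
        assert np.isnan(ch["cCV_DBH"].iloc[0])

    def test_community_matrix_counts_trees_once(self):
        census = pd.DataFrame({
            "tree_id": ["T1", "T1", "T2"], "stem_id": ["1", "2", "1"],
            "species": ["s1", "s1", "s2"], "quadrat": ["QA"] * 3,
            "dbh_cm": [10.0, 4.0, 8.0], "census": [1, 1, 1],
            "status": ["alive"] * 3,
        })
        mat = community_matrix(census)[1]
        assert mat.at["QA", "s1"] == 1 and mat.at["QA", "s2"] == 1

    def test_independent_swap_preserves_marginals(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame((rng.random((10, 8)) < 0.4).astype(int))
        sw = independent_swap(m, rng)
        assert (sw.sum(axis=0) == (m > 0).sum(axis=0)).all()
        assert (sw.sum(axis=1) == (m > 0).sum(axis=1)).all()

    def test_null_spec_validation(self):
        with pytest.raises(InvalidConfigurationError):
            NullModelSpec(n_iterations=1)
        with pytest.raises(InvalidConfigurationError):
            NullModelSpec(scheme="bogus")
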