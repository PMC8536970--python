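"""Null models: betaMNTD oracle, betaNTI, RC_bray, classification, summaries."""
import numpy as np
import pandas as pd
import pytest

import benthos as b
from benthos.nullmodels import ProcessLabel, summarize_counts


def brute_force_bmntd(counts: np.ndarray, dist: np.ndarray, weighted: bool) -> np.ndarray:
    """Independent double-loop betaMNTD for tiny instances."""
    n_samples, n_taxa = counts.shape
    out = np.zeros((n_samples, n_samples))
    for k in range(n_samples):
        for l in range(n_samples):
            if k == l:
                continue
            total = 0.0
            for direction in ((k, l), (l, k)):
                a, c = direction
                present_a = [i for i in range(n_taxa) if counts[a, i] > 0]
                present_c = [j for j in range(n_taxa) if counts[c, j] > 0]
                if weighted:
                    wsum = counts[a].sum()
                    acc = 0.0
                    for i in present_a:
                        nearest = min(dist[i, j] for j in present_c)
                        acc += counts[a, i] / wsum * nearest
                else:
                    acc = np.mean(
                        [min(dist[i, j] for j in present_c) for i in present_a]
                    )
                total += acc
            out[k, l] = total / 2.0
    return out


def random_instance(rng):
    n_taxa = int(rng.integers(3, 6))
    n_samples = int(rng.integers(2, 5))
    tree = b.simulate_tree(n_taxa, seed=int(rng.integers(1_000_000)))
    counts = rng.integers(0, 6, size=(n_samples, n_taxa))
    # every sample needs at least one taxon
    for row in counts:
        if row.sum() == 0:
            row[rng.integers(n_taxa)] = 1
    table = b.OtuTable(
        pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)],
                     columns=tree.tip_names)
    )
    return table, tree


class TestBetaMntd:
    def test_identical_communities_zero(self, cherry_tree):
        counts = pd.DataFrame([[1, 1, 1], [1, 1, 1]], index=["x", "y"],
                              columns=["A", "B", "C"])
        out = b.beta_mntd(b.OtuTable(counts), cherry_tree)
        assert out.values[0, 1] == pytest.approx(0.0)

    def test_single_taxon_pair_is_patristic_distance(self, cherry_tree):
        counts = pd.DataFrame([[4, 0, 0], [0, 7, 0]], index=["x", "y"],
                              columns=["A", "B", "C"])
        out = b.beta_mntd(b.OtuTable(counts), cherry_tree)
        assert out.values[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(42)
        for _ in range(40):
            table, tree = random_instance(rng)
            dist = tree.distance_matrix().loc[table.taxon_ids, table.taxon_ids].to_numpy()
            expected = brute_force_bmntd(table.counts.to_numpy(), dist, weighted)
            got = b.beta_mntd(table, tree, abundance_weighted=weighted).values
            assert np.allclose(got, expected, atol=1e-12)

    def test_taxon_missing_from_tree_rejected(self, cherry_tree):
        counts = pd.DataFrame([[1, 1]], index=["x"], columns=["A", "Z"])
        with pytest.raises(KeyError, match="Z"):
            b.beta_mntd(b.OtuTable(counts), cherry_tree)


class TestBetaNti:
    def test_star_phylogeny_degenerate_flagged_zero(self):
        tree = b.PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        counts = pd.DataFrame([[5, 1, 0, 0], [0, 0, 1, 5]], index=["x", "y"],
                              columns=list("ABCD"))
        res = b.beta_nti(b.OtuTable(counts), tree, reps=99, seed=0)
        assert res.values.loc["x", "y"] == 0.0
        assert bool(res.degenerate.loc["x", "y"])

    def test_identical_communities_degenerate(self, cherry_tree):
        # shared taxa stay shared under any consistent relabelling, so the
        # null distribution collapses at the observed value
        counts = pd.DataFrame([[3, 2, 1], [3, 2, 1]], index=["x", "y"],
                              columns=["A", "B", "C"])
        res = b.beta_nti(b.OtuTable(counts), cherry_tree, reps=99, seed=1)
        assert res.values.loc["x", "y"] == 0.0
        assert bool(res.degenerate.loc["x", "y"])

    def test_symmetric_and_seed_reproducible(self, sim_small):
        table = sim_small["table"].select_samples(sim_small["table"].sample_ids[:8])
        res1 = b.beta_nti(table, sim_small["tree"], reps=99, seed=5)
        res2 = b.beta_nti(table, sim_small["tree"], reps=99, seed=5)
        v = res1.values.to_numpy()
        assert np.allclose(v, v.T)
        pd.testing.assert_frame_equal(res1.values, res2.values)

    def test_too_few_reps_rejected(self, small_table, cherry_tree):
        with pytest.raises(ValueError):
            b.beta_nti(small_table, cherry_tree, reps=10)


class TestRaupCrick:
    def test_identical_samples_strongly_negative(self):
        # two copies of one sample drawn from a diverse pool sit below
        # essentially every richness/abundance-preserving null pair
        rng = np.random.default_rng(0)
        base = rng.multinomial(300, np.full(30, 1 / 30))
        counts = pd.DataFrame([base, base, rng.multinomial(300, np.full(30, 1 / 30))],
                              index=["a", "b", "c"],
                              columns=[f"t{j}" for j in range(30)])
        res = b.raup_crick_bray(b.OtuTable(counts), reps=199, seed=3)
        assert res.values.loc["a", "b"] <= -0.95

    def test_disjoint_pools_strongly_positive(self):
        rng = np.random.default_rng(1)
        half = 15
        a = np.concatenate([rng.multinomial(300, np.full(half, 1 / half)), np.zeros(half, int)])
        c = np.concatenate([np.zeros(half, int), rng.multinomial(300, np.full(half, 1 / half))])
        counts = pd.DataFrame([a, a, c, c], index=["a1", "a2", "c1", "c2"],
                              columns=[f"t{j}" for j in range(2 * half)])
        res = b.raup_crick_bray(b.OtuTable(counts), reps=199, seed=3)
        assert res.values.loc["a1", "c1"] >= 0.95

    def test_bounds_symmetry_reproducibility(self, sim_small):
        table = sim_small["table"].select_samples(sim_small["table"].sample_ids[:6])
        r1 = b.raup_crick_bray(table, reps=99, seed=2)
        r2 = b.raup_crick_bray(table, reps=99, seed=2)
        v = r1.values.to_numpy()
        assert v.min() >= -1.0 and v.max() <= 1.0
        assert np.allclose(v, v.T)
        pd.testing.assert_frame_equal(r1.values, r2.values)


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.5, 0.1, ProcessLabel.HETEROGENEOUS_SELECTION),
            (-2.5, 0.1, ProcessLabel.HOMOGENEOUS_SELECTION),
            (0.5, 0.97, ProcessLabel.DISPERSAL_LIMITATION),
            (0.5, -0.97, ProcessLabel.HOMOGENIZING_DISPERSAL),
            (0.0, 0.0, ProcessLabel.UNDOMINATED),
            (2.0, 0.99, ProcessLabel.HETEROGENEOUS_SELECTION),  # betaNTI precedence
            (-2.0, -0.99, ProcessLabel.HOMOGENEOUS_SELECTION),
            (1.99, 0.95, ProcessLabel.DISPERSAL_LIMITATION),
        ],
    )
    def test_decision_rule(self, bnti, rc, expected):
        assert b.classify_pair(bnti, rc) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            b.classify_pair(np.nan, 0.0)

    def test_classification_exhaustive_on_grid(self):
        for bnti in np.linspace(-4, 4, 33):
            for rc in np.linspace(-1, 1, 21):
                assert b.classify_pair(bnti, rc) in ProcessLabel


class TestSummaries:
    def test_regional_pair_count_four_by_eight(self):
        n = 32
        ids = [f"s{i}" for i in range(n)]
        z = pd.DataFrame(np.zeros((n, n)), index=ids, columns=ids)
        bnti = b.BetaNtiMatrix(z, z.astype(bool), reps=999, seed=0)
        rc = b.RcMatrix(z.copy(), reps=999, seed=0)
        groups = b.GroupMap({f"s{i}": f"G{i % 4}" for i in range(n)})
        s = b.summarize_contributions(bnti, rc, groups, "regional")
        assert s.n_pairs == 496

    def test_printed_counts_reproduce_percentages(self):
        s = summarize_counts(
            {
                "heterogeneous_selection": 216,
                "dispersal_limitation": 240,
                "homogenizing_dispersal": 5,
                "undominated": 35,
                "homogeneous_selection": 0,
            }
        )
        assert s.percentages["heterogeneous_selection"] == 43.5
        assert s.percentages["dispersal_limitation"] == 48.4
        assert s.percentages["homogenizing_dispersal"] == 1.0
        assert s.percentages["undominated"] == 7.1
        assert s.percentages["homogeneous_selection"] == 0.0
        assert abs(sum(s.percentages.values()) - 100.0) <= 0.2

    def test_single_label_hundred_percent(self):
        s = summarize_counts({"undominated": 12})
        assert s.percentages["undominated"] == 100.0
        assert sum(v for k, v in s.percentages.items() if k != "undominated") == 0.0

    def test_within_and_between_partition_all_pairs(self, sim_small):
        table = sim_small["table"].select_samples(sim_small["table"].sample_ids[:12])
        groups = b.GroupMap({s: sim_small["groups"].group_of(s) for s in table.sample_ids})
        bnti = b.beta_nti(table, sim_small["tree"], reps=99, seed=0)
        rc = b.raup_crick_bray(table, reps=99, seed=1)
        names = groups.group_names
        total = 0
        for g in names:
            total += b.summarize_contributions(bnti, rc, groups, ("within", g)).n_pairs
        for i, g1 in enumerate(names):
            for g2 in names[i + 1:]:
                total += b.summarize_contributions(bnti, rc, groups, ("between", g1, g2)).n_pairs
        regional = b.summarize_contributions(bnti, rc, groups, "regional")
        assert total == regional.n_pairs
        assert sum(regional.counts.values()) == regional.n_pairs

    def test_unknown_group_rejected(self, sim_small):
        table = sim_small["table"].select_samples(sim_small["table"].sample_ids[:8])
        groups = b.GroupMap({s: sim_small["groups"].group_of(s) for s in table.sample_ids})
        bnti = b.beta_nti(table, sim_small["tree"], reps=99, seed=0)
        rc = b.raup_crick_bray(table, reps=99, seed=1)
        with pytest.raises(KeyError):
            b.summarize_contributions(bnti, rc, groups, ("within", "nope"))


class TestKeystoneSubcommunity:
    def test_full_subset_is_identity(self, small_table):
        out = b.keystone_subcommunity(small_table, small_table.taxon_ids)
        pd.testing.assert_frame_equal(out.counts, small_table.counts)

    def test_subset_columns_and_totals(self, small_table):
        out = b.keystone_subcommunity(small_table, ["A", "B"])
        assert out.taxon_ids == ["A", "B"]
        assert (out.sample_totals() <= small_table.sample_totals()).all()

    def test_unknown_taxon_rejected(self, small_table):
        with pytest.raises(KeyError):
            b.keystone_subcommunity(small_table, ["A", "nope"])

    def test_empty_sample_excluded_with_warning(self):
        counts = pd.DataFrame([[5, 0], [0, 3]], index=["s1", "s2"], columns=["A", "B"])
        with pytest.warns(UserWarning, match="zero keystone total"):
            out = b.keystone_subcommunity(b.OtuTable(counts), ["A"])
        assert out.sample_ids == ["s1"]
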