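"""Spacer clustering, Jaccard/turnover statistics and protospacer matching."""

import numpy as np
import pytest

from defenseflux import simulate
from defenseflux.spacers import (
    _revcomp,
    cluster_spacers,
    jaccard_distance,
    match_spacers_to_genes,
    naive_match_spacers,
    spacer_turnover,
)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestClusterSpacers:
    def test_identical_spacers_share_a_cluster(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 32)
        per_genome, cluster_of = cluster_spacers({"g1": [s], "g2": [s]})
        assert per_genome["g1"] == per_genome["g2"]
        assert len(set(cluster_of.values())) == 1

    def test_unrelated_spacers_stay_apart(self):
        rng = np.random.default_rng(1)
        per_genome, cluster_of = cluster_spacers(
            {"g": [random_seq(rng, 32) for _ in range(30)]}
        )
        assert len(per_genome["g"]) == 30

    def test_short_substring_fails_mutual_coverage(self):
        # 22 nt inside 32 nt: coverage of the long spacer is 69% < 80%
        rng = np.random.default_rng(2)
        long = random_seq(rng, 32)
        short = long[5:27]
        per_genome, _ = cluster_spacers({"g": [long, short]})
        assert len(per_genome["g"]) == 2

    def test_reverse_complement_joins_cluster(self):
        rng = np.random.default_rng(3)
        s = random_seq(rng, 32)
        per_genome, _ = cluster_spacers({"g1": [s], "g2": [_revcomp(s)]})
        assert per_genome["g1"] == per_genome["g2"]

    def test_near_identical_with_two_mismatches_cluster(self):
        rng = np.random.default_rng(4)
        s = random_seq(rng, 32)
        mutated = list(s)
        for pos in (5, 20):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        per_genome, _ = cluster_spacers({"g": [s, "".join(mutated)]})
        assert len(per_genome["g"]) == 1  # 30/32 = 93.75% identity >= 90%

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        seqs = [random_seq(rng, 32) for _ in range(12)]
        seqs += [seqs[0], _revcomp(seqs[3])]
        a, map_a = cluster_spacers({"g": seqs})
        b, map_b = cluster_spacers({"g": seqs[::-1]})
        assert a == b
        assert map_a == map_b

    def test_non_acgt_spacers_excluded(self):
        rng = np.random.default_rng(6)
        good = random_seq(rng, 32)
        per_genome, _ = cluster_spacers({"g": [good, "ACGTNACGTNACGTNACGTNACGTNACGTNAC"]})
        assert len(per_genome["g"]) == 1


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_distance({"a", "b"}, {"a", "b"}) == 0.0

    def test_disjoint_sets(self):
        assert jaccard_distance({"a"}, {"b"}) == 1.0

    def test_partial_overlap(self):
        assert jaccard_distance({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)

    def test_empty_set_not_computable(self):
        with pytest.raises(ValueError):
            jaccard_distance(set(), {"a"})

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(7)
        universe = list(range(20))
        for _ in range(200):
            a, b, c = (
                set(rng.choice(universe, rng.integers(1, 10), replace=False))
                for _ in range(3)
            )
            dab = jaccard_distance(a, b)
            dbc = jaccard_distance(b, c)
            dac = jaccard_distance(a, c)
            assert dac <= dab + dbc + 1e-12
            assert dab == jaccard_distance(b, a)


class TestTurnover:
    def test_identical_twins_score_one(self, cherry):
        cherry.lengths[1:] = 0.0
        table = spacer_turnover(cherry, {"A": {"x"}, "B": {"x"}})
        assert table.loc[0, "turnover"] == 1.0

    def test_ratio_formula_value(self):
        from defenseflux.tree import read_newick

        tree = read_newick("(A:0.25,B:0.25);")  # patristic distance 0.5
        table = spacer_turnover(tree, {"A": {"x", "y"}, "B": {"y", "z"}})
        # J = 1 - 1/3, T = (1 + 2/3) / 1.5
        assert table.loc[0, "jaccard"] == pytest.approx(2 / 3)
        assert table.loc[0, "turnover"] == pytest.approx((1 + 2 / 3) / 1.5)

    def test_distant_pairs_excluded(self):
        from defenseflux.tree import read_newick

        tree = read_newick("(A:0.6,B:0.6);")  # distance 1.2 >= 1
        table = spacer_turnover(tree, {"A": {"x"}, "B": {"y"}})
        assert len(table) == 0

    def test_bounds_hold_on_simulated_arrays(self):
        tree = simulate.simulate_tree(30, seed=9)
        arrays = simulate.simulate_spacer_arrays(tree, 20.0, 1.0, seed=10)
        clusters, _ = cluster_spacers(arrays)
        table = spacer_turnover(tree, clusters)
        assert len(table) > 0
        assert (table["turnover"] >= 0.5).all()
        assert (table["turnover"] < 2.0).all()

    def test_product_reading_available_as_flag(self):
        from defenseflux.tree import read_newick

        tree = read_newick("(A:0.25,B:0.25);")
        t_prod = spacer_turnover(
            tree, {"A": {"x"}, "B": {"y"}}, formula="product"
        ).loc[0, "turnover"]
        assert t_prod == pytest.approx(2.0 * 1.5)


class TestMatcher:
    def test_exact_containment_is_a_hit(self):
        rng = np.random.default_rng(11)
        gene = random_seq(rng, 300)
        spacer = gene[100:130]
        hits = match_spacers_to_genes({"s": spacer}, {"g": gene})
        row = hits[hits["strand"] == "+"].iloc[0]
        assert row["identity"] == 1.0
        assert row["coverage"] == 1.0
        assert row["offset"] == 100

    def test_two_mismatches_fail_identity(self):
        rng = np.random.default_rng(12)
        gene = random_seq(rng, 300)
        spacer = list(gene[100:130])
        for pos in (4, 20):
            spacer[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[spacer[pos]]
        hits = match_spacers_to_genes({"s": "".join(spacer)}, {"g": gene})
        # 28/30 = 93.3% identity over the full window; shorter windows lose
        # coverage: no window reaches 95% at >= 90% coverage of 30 nt
        assert len(hits) == 0

    def test_partial_coverage_fails(self):
        rng = np.random.default_rng(13)
        gene = random_seq(rng, 300)
        spacer = gene[100:124] + random_seq(rng, 6)  # 24/30 = 80% coverage
        hits = match_spacers_to_genes({"s": spacer}, {"g": gene})
        assert len(hits) == 0

    def test_reverse_complement_hit_found(self):
        rng = np.random.default_rng(14)
        gene = random_seq(rng, 250)
        spacer = _revcomp(gene[50:80])
        hits = match_spacers_to_genes({"s": spacer}, {"g": gene})
        assert (hits["strand"] == "-").any()

    def test_agrees_with_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(15)
        n_pairs = 150
        for trial in range(n_pairs):
            gene = random_seq(rng, 200)
            kind = trial % 4
            if kind == 0:
                spacer = random_seq(rng, 30)  # mostly misses
            elif kind == 1:
                start = int(rng.integers(0, 170))
                spacer = gene[start : start + 30]  # plant
            elif kind == 2:
                start = int(rng.integers(0, 170))
                s = list(gene[start : start + 30])
                for pos in rng.choice(30, rng.integers(0, 3), replace=False):
                    s[pos] = "ACGT"[rng.integers(0, 4)]
                spacer = "".join(s)  # plant with up to 2 mutations
            else:
                start = int(rng.integers(0, 170))
                spacer = _revcomp(gene[start : start + 28]) + random_seq(rng, 2)
            fast = match_spacers_to_genes({"s": spacer}, {"g": gene})
            slow = naive_match_spacers({"s": spacer}, {"g": gene})
            key = ["spacer_id", "gene_id", "strand"]
            assert set(map(tuple, fast[key].values)) == set(map(tuple, slow[key].values))

    def test_boundary_overhang_hit(self):
        # spacer hangs one base off the gene end: 29/30 = 96.7% coverage window
        rng = np.random.default_rng(16)
        gene = random_seq(rng, 120)
        spacer = gene[91:120] + "A"
        fast = match_spacers_to_genes({"s": spacer}, {"g": gene})
        slow = naive_match_spacers({"s": spacer}, {"g": gene})
        assert len(fast[fast["strand"] == "+"]) == len(slow[slow["strand"] == "+"]) == 1
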