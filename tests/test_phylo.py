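"""Shared-variant distances, K2P, neighbor joining, consensus, bootstrap."""

import itertools
import math

import numpy as np
import pytest

from tribescan.formats_io import SiteKey
from tribescan.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_tree,
    flagged_distance_matrix,
    intergenome_distance,
    k2p_distance,
    majority_consensus,
    neighbor_joining,
    parse_newick,
    per_chromosome_distance_matrices,
)
from tribescan.synthetic_data import SimConfig, simulate_sequences


def sites(*pairs):
    return {SiteKey(str(c), p) for c, p in pairs}


def random_genomes(rng, n_genomes=10, n_sites=400, keep=0.6, contigs=4):
    universe = [
        SiteKey(str(1 + i % contigs), 100 * (i + 1)) for i in range(n_sites)
    ]
    return {
        f"G{k}": {s for s in universe if rng.random() < keep}
        for k in range(n_genomes)
    }


class TestIntergenomeDistance:
    def test_worked_example(self):
        i = sites((1, 100), (1, 200), (2, 50))
        j = sites((1, 100), (2, 50), (2, 60), (3, 10))
        r = intergenome_distance(i, j)
        assert (r.n_small, r.n_large, r.shared) == (3, 4, 2)
        assert r.distance == pytest.approx(1 / 3)

    def test_subset_gives_zero(self):
        i = sites((1, 100), (2, 50))
        j = i | sites((3, 10))
        assert intergenome_distance(i, j).distance == 0.0

    def test_disjoint_gives_one(self):
        assert (
            intergenome_distance(sites((1, 1)), sites((2, 2))).distance == 1.0
        )

    def test_symmetric_and_bounded(self, rng):
        genomes = random_genomes(rng, n_genomes=6)
        for a, b in itertools.combinations(genomes, 2):
            d1 = intergenome_distance(genomes[a], genomes[b]).distance
            d2 = intergenome_distance(genomes[b], genomes[a]).distance
            assert d1 == d2
            assert 0.0 <= d1 <= 1.0

    def test_self_distance_zero(self, rng):
        g = random_genomes(rng, n_genomes=1)["G0"]
        assert intergenome_distance(g, g).distance == 0.0

    def test_empty_smaller_set_rejected(self):
        with pytest.raises(ValueError):
            intergenome_distance(set(), sites((1, 1)))

    def test_matrix_entries_equal_brute_force(self, rng):
        """Every per-contig matrix entry equals direct set arithmetic."""
        genomes = random_genomes(rng)
        mats = per_chromosome_distance_matrices(genomes, contigs=["1", "2", "3", "4"])
        assert len(mats) == 4
        for contig, dm in mats:
            for a, b in itertools.combinations(dm.labels, 2):
                sa = {s for s in genomes[a] if s.chrom == contig}
                sb = {s for s in genomes[b] if s.chrom == contig}
                ns = min(len(sa), len(sb))
                expect = (ns - len(sa & sb)) / ns
                assert dm[a, b] == pytest.approx(expect, abs=1e-15)

    def test_duplicated_genome_zero_on_every_contig(self, rng):
        genomes = random_genomes(rng, n_genomes=3)
        genomes["copy"] = set(genomes["G0"])
        for _, dm in per_chromosome_distance_matrices(genomes, contigs=["1", "2"]):
            assert dm["G0", "copy"] == 0.0

    def test_empty_contig_skipped_with_warning(self, rng):
        genomes = random_genomes(rng, n_genomes=3, contigs=2)
        with pytest.warns(UserWarning):
            mats = per_chromosome_distance_matrices(genomes, contigs=["1", "2", "9"])
        assert [c for c, _ in mats] == ["1", "2"]


class TestFlaggedRestriction:
    def test_all_flagged_equals_unrestricted(self, rng):
        genomes = random_genomes(rng, n_genomes=4)
        flagged = set().union(*genomes.values())
        dm = flagged_distance_matrix(genomes, flagged)
        for a, b in itertools.combinations(genomes, 2):
            assert dm[a, b] == pytest.approx(
                intergenome_distance(genomes[a], genomes[b]).distance
            )

    def test_no_flagged_sites_all_pairs_skipped(self, rng):
        genomes = random_genomes(rng, n_genomes=3)
        with pytest.warns(UserWarning):
            dm = flagged_distance_matrix(genomes, set())
        assert np.all(dm.values == 0.0)

    def test_half_flagged_matches_brute_force(self, rng):
        genomes = random_genomes(rng, n_genomes=5)
        universe = sorted(set().union(*genomes.values()))
        flagged = {s for s in universe if rng.random() < 0.5}
        dm = flagged_distance_matrix(genomes, flagged)
        for a, b in itertools.combinations(genomes, 2):
            keep = (genomes[a] & flagged) | (genomes[b] & flagged)
            ra, rb = genomes[a] & keep, genomes[b] & keep
            ns = min(len(ra), len(rb))
            expect = (ns - len(ra & rb)) / ns
            assert dm[a, b] == pytest.approx(expect, abs=1e-15)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGT" * 50, "ACGT" * 50) == pytest.approx(0.0)

    def test_closed_form_transitions_only(self):
        # P = 0.1, Q = 0 over 100 sites
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        expect = -0.5 * math.log(0.8)
        assert k2p_distance(a, b) == pytest.approx(expect, abs=1e-12)

    def test_ambiguous_sites_pairwise_deleted(self):
        a = "ANGT" + "A" * 96
        b = "ACGT" + "A" * 96
        # site 2 dropped in both; remaining sites identical except none
        assert k2p_distance(a, b) == pytest.approx(0.0)

    def test_saturation_returns_configured_value(self):
        with pytest.warns(UserWarning):
            d = k2p_distance("A" * 10, "G" * 10, undefined_value=9.0)
        assert d == 9.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("ACG", "AC")

    def test_simulated_pair_estimate(self):
        ests = []
        for seed in range(15):
            seqs, _ = simulate_sequences(
                SimConfig(tree_newick="(A:0.02,B:0.03);", seq_len=10_000, seed=seed)
            )
            ests.append(k2p_distance(seqs["A"], seqs["B"]))
        se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.05) < 3 * se


def tree_distances(newick):
    """Leaf-to-leaf path lengths of a newick tree (independent oracle)."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    labels = [x.label for x in taxa]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.distance(taxa[i], taxa[j])
    return labels, m


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        """Exact topology and branch lengths from the additive matrix of
        ((A:1,B:2):1,(C:3,D:4):1)."""
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert set(map(tuple, map(sorted, bipartitions(tree)))) == {("C", "D")}
        lengths = {}

        def collect(node):
            for c in node.children:
                if c.is_leaf:
                    lengths[c.name] = c.length
                collect(c)

        collect(tree.root)
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        got = {c.name: c.length for c in tree.root.children}
        assert got == {"A": 0.0, "B": 2.0, "C": 3.0}

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_recovery_random_trees(self, n_taxa, rng):
        """NJ reconstructs the generating topology and path lengths from
        additive distances on random trees (checked against dendropy path
        lengths)."""
        for rep in range(10):
            newick = random_binary_newick(rng, n_taxa)
            labels, dm = tree_distances(newick)
            tree = neighbor_joining(DistanceMatrix(labels, dm))
            true = parse_newick(newick)
            assert set(map(frozenset, bipartitions(tree))) == set(
                map(frozenset, bipartitions(true))
            )
            # re-deriving the path-length matrix from the NJ tree reproduces it
            got_labels, got = tree_distances(tree.to_newick(include_support=False))
            order = [got_labels.index(l) for l in labels]
            assert np.allclose(got[np.ix_(order, order)], dm, atol=1e-9)

    def test_four_taxon_topology_matches_exhaustive_search(self, rng):
        """On 200 random 4-taxon tree metrics NJ picks the same topology as
        brute-force minimum evolution over the 3 topologies."""
        agree = 0
        for rep in range(200):
            newick = random_binary_newick(rng, 4)
            labels, dm = tree_distances(newick)
            nj = neighbor_joining(DistanceMatrix(labels, dm))
            (split,) = bipartitions(nj).keys()
            best = exhaustive_me_quartet(labels, dm)
            if frozenset(split) in (best, frozenset(labels) - best):
                agree += 1
        assert agree == 200

    def test_input_order_invariance(self, rng):
        genomes_labels = list("ABCDEF")
        newick = random_binary_newick(rng, 6)
        labels, dm = tree_distances(newick)
        base = set(map(frozenset, bipartitions(neighbor_joining(DistanceMatrix(labels, dm)))))
        for _ in range(10):
            perm = rng.permutation(len(labels))
            pl = [labels[i] for i in perm]
            pm = dm[np.ix_(perm, perm)]
            got = set(map(frozenset, bipartitions(neighbor_joining(DistanceMatrix(pl, pm)))))
            assert got == base

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


def random_binary_newick(rng, n_taxa):
    """A random binary tree over A.. with branch lengths in [0.1, 1]."""
    nodes = [f"{chr(65 + i)}:{rng.uniform(0.1, 1):.4f}" for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def exhaustive_me_quartet(labels, dm):
    """Minimum-evolution quartet topology by brute force: for each pairing
    {xy|zw}, total tree length from the four-point formulas; returns the
    cherry of the best topology (as a frozenset)."""
    idx = {l: k for k, l in enumerate(labels)}

    def total_length(a, b, c, d):
        # tree ((a,b),(c,d)); internal = (d_ac+d_ad+d_bc+d_bd)/4 - (d_ab+d_cd)/2
        dab, dcd = dm[idx[a], idx[b]], dm[idx[c], idx[d]]
        cross = (
            dm[idx[a], idx[c]] + dm[idx[a], idx[d]]
            + dm[idx[b], idx[c]] + dm[idx[b], idx[d]]
        )
        internal = cross / 4 - (dab + dcd) / 2
        return dab + dcd + internal

    a, b, c, d = labels
    options = [
        ((a, b, c, d), frozenset((a, b))),
        ((a, c, b, d), frozenset((a, c))),
        ((a, d, b, c), frozenset((a, d))),
    ]
    return min(options, key=lambda o: total_length(*o[0]))[1]


class TestConsensus:
    def test_unanimous_trees_full_support(self):
        trees = [parse_newick("((A,B),(C,D),(E,F));") for _ in range(22)]
        cons = majority_consensus(trees)
        bip = bipartitions(cons)
        assert len(bip) == 3
        assert all(node.support == 22 for node in bip.values())

    def test_majority_bipartition_included_with_count(self):
        trees = [
            parse_newick("((A,B),(C,D),E);"),
            parse_newick("((A,B),(C,E),D);"),
            parse_newick("((A,C),(B,D),E);"),
        ]
        cons = majority_consensus(trees)
        bip = {frozenset(k): v.support for k, v in bipartitions(cons).items()}
        assert bip[frozenset("CDE")] == 2  # the (A,B) cherry, keyed opposite A

    def test_consensus_of_single_tree_is_that_tree(self, rng):
        newick = random_binary_newick(rng, 7)
        t = parse_newick(newick)
        cons = majority_consensus([t])
        assert set(map(frozenset, bipartitions(cons))) == set(
            map(frozenset, bipartitions(t))
        )

    def test_differing_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus(
                [parse_newick("((A,B),C);"), parse_newick("((A,B),D);")]
            )

    def test_supports_equal_brute_force_tabulation(self, rng):
        """On random 6-taxon replicate sets, every consensus support equals
        the direct count of trees containing that bipartition, and every
        strict-majority bipartition is present."""
        for rep in range(20):
            trees = [
                parse_newick(random_binary_newick(rng, 6)) for _ in range(9)
            ]
            counts: dict = {}
            for t in trees:
                for s in bipartitions(t):
                    key = frozenset(s)
                    counts[key] = counts.get(key, 0) + 1
            cons = majority_consensus(trees)
            for split, node in bipartitions(cons).items():
                assert node.support == counts[frozenset(split)]
            for split, c in counts.items():
                if 2 * c > len(trees):
                    assert split in {
                        frozenset(s) for s in bipartitions(cons)
                    }

    def test_matches_dendropy_strict_majority(self, rng):
        """Strict (non-extended) majority rule agrees with dendropy's
        50%-rule consensus on random replicate sets."""
        import dendropy

        for rep in range(5):
            newicks = [random_binary_newick(rng, 6) for _ in range(7)]
            ours = majority_consensus(
                [parse_newick(n) for n in newicks], extended=False
            )
            tl = dendropy.TreeList.get(data="\n".join(newicks), schema="newick")
            dd = tl.consensus(min_freq=0.5001)
            dd_splits = set()
            dd.encode_bipartitions()
            taxa = {t.label for t in tl.taxon_namespace}
            ref = min(taxa)
            for edge in dd.preorder_edge_iter():
                if edge.head_node.is_leaf() or edge.head_node is dd.seed_node:
                    continue
                side = {
                    lf.taxon.label for lf in edge.head_node.leaf_iter()
                }
                if ref in side:
                    side = taxa - side
                if 1 < len(side) < len(taxa) - 1:
                    dd_splits.add(frozenset(side))
            assert {frozenset(s) for s in bipartitions(ours)} == dd_splits


class TestBootstrap:
    def test_zero_variation_alignment_star_consensus(self):
        aln = {name: "ACGT" * 25 for name in "ABCDE"}
        cons = bootstrap_tree(aln, n_reps=10, seed=1)
        assert bipartitions(cons) == {}

    def test_same_seed_reproducible(self):
        seqs, _ = simulate_sequences(SimConfig(seq_len=400, seed=2))
        t1 = bootstrap_tree(seqs, n_reps=20, seed=9)
        t2 = bootstrap_tree(seqs, n_reps=20, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_true_bipartitions_recovered_with_high_support(self):
        """Sequences simulated on a 6-taxon tree with long internal
        branches: 100 bootstrap replicates recover every true bipartition
        with support >= 90."""
        newick = "((A:0.05,B:0.05):0.15,(C:0.05,D:0.05):0.15,(E:0.05,F:0.05):0.15);"
        seqs, true = simulate_sequences(
            SimConfig(tree_newick=newick, seq_len=2000, seed=4)
        )
        cons = bootstrap_tree(seqs, n_reps=100, seed=8)
        got = {frozenset(s): n.support for s, n in bipartitions(cons).items()}
        for split in bipartitions(true):
            assert got.get(frozenset(split), 0) >= 90

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_tree({"A": "", "B": ""}, n_reps=5, seed=1)
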