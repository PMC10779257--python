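import itertools
import math

import numpy as np
import pytest

from genefamkit.io_formats import ValidationError
from genefamkit.phylogeny import (
    DistanceMatrix, MsaView, PhyloTree, assign_groups, bootstrap_support,
    nj_tree, poisson_distance,
)
from genefamkit.synthetic_data import simulate_divergent_pair
from genefamkit.genetics import translate_cds


class TestPoissonDistance:
    def test_identical_rows(self):
        msa = MsaView(("a", "b"), ("MKT", "MKT"))
        assert poisson_distance(msa).matrix[0, 1] == 0.0

    def test_half_different(self):
        msa = MsaView(("a", "b"), ("MKTA", "MKAG"))
        assert poisson_distance(msa).matrix[0, 1] == pytest.approx(math.log(2))

    def test_deletion_rules_match_hand_counts(self):
        #       col: 12345
        rows = ("MK-TA",
                "MKAT-",
                "MKATG")
        msa = MsaView(("a", "b", "c"), rows)
        # complete deletion keeps columns 1,2,4 only; a vs b differ in none
        dm_c = poisson_distance(msa, "complete")
        assert dm_c[("a", "b")] == 0.0
        # pairwise deletion for a vs b keeps cols 1,2,4 too; a vs c keeps 1,2,4,5
        dm_p = poisson_distance(msa, "pairwise")
        assert dm_p[("a", "b")] == 0.0
        assert dm_p[("a", "c")] == pytest.approx(-math.log(1 - 1 / 4))

    def test_no_comparable_columns_names_pair(self):
        msa = MsaView(("a", "b"), ("M-", "-K"))
        with pytest.raises(ValidationError, match="a.*b"):
            poisson_distance(msa, "pairwise")

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        rows = tuple("".join(rng.choice(list("MKTAG"), size=30)) for _ in range(5))
        ids = tuple("abcde")
        dm = poisson_distance(MsaView(ids, rows))
        perm = [3, 1, 4, 0, 2]
        dm2 = poisson_distance(MsaView(tuple(ids[i] for i in perm),
                                       tuple(rows[i] for i in perm)))
        for x in ids:
            for y in ids:
                if x != y:
                    assert dm[(x, y)] == dm2[(x, y)]


def build_additive_case(rng, n_leaves):
    """Random additive matrix plus the generating tree's non-trivial splits."""
    ids = [f"L{i}" for i in range(n_leaves)]
    n = n_leaves
    m = np.zeros((n, n))
    idx = {l: k for k, l in enumerate(ids)}
    clusters = [({l}, {l: 0.0}) for l in ids]
    splits = set()
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (sa, da), (sb, db) = clusters[i], clusters[j]
        if len(clusters) == 2:
            la = float(rng.uniform(0.05, 1.0))
            lb = 0.0  # root merge: one edge suffices for an unrooted tree
        else:
            la, lb = (float(x) for x in rng.uniform(0.05, 1.0, size=2))
        for x, dx in da.items():
            for y, dy in db.items():
                m[idx[x], idx[y]] = m[idx[y], idx[x]] = dx + la + dy + lb
        merged = {k: v + la for k, v in da.items()}
        merged.update({k: v + lb for k, v in db.items()})
        for side in (sa, sb):
            if 1 < len(side) < n - 1:
                splits.add(frozenset(side))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((sa | sb, merged))
    # normalize splits to the side not containing the first leaf
    anchor = min(ids)
    all_set = frozenset(ids)
    norm = set()
    for s in splits:
        s = all_set - s if anchor in s else s
        if 1 < len(s) < n - 1:
            norm.add(frozenset(s))
    return ids, m, norm


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        ids = ("a", "b", "c")
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, m))
        d = tree.dendropy_tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
        assert d.distance(taxa["a"], taxa["b"]) == pytest.approx(5.0)
        assert d.distance(taxa["a"], taxa["c"]) == pytest.approx(9.0)
        assert d.distance(taxa["b"], taxa["c"]) == pytest.approx(10.0)

    def test_additive_four_leaf_exact(self):
        rng = np.random.default_rng(2)
        ids, m, splits = build_additive_case(rng, 4)
        tree = nj_tree(DistanceMatrix(tuple(ids), m))
        assert tree.splits() == splits
        d = tree.dendropy_tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
        for x, y in itertools.combinations(ids, 2):
            assert d.distance(taxa[x], taxa[y]) == pytest.approx(
                m[ids.index(x), ids.index(y)], abs=1e-9)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_additive_recovery_oracle(self, n_leaves):
        """NJ recovers topology and path lengths exactly on additive inputs."""
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(10):
            ids, m, splits = build_additive_case(rng, n_leaves)
            tree = nj_tree(DistanceMatrix(tuple(ids), m))
            assert tree.splits() == splits
            d = tree.dendropy_tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
            for x, y in itertools.combinations(ids, 2):
                assert d.distance(taxa[x], taxa[y]) == pytest.approx(
                    m[ids.index(x), ids.index(y)], abs=1e-8)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b", "c"), m)

    def test_newick_round_trip(self):
        ids = ("a", "b", "c", "d")
        rng = np.random.default_rng(0)
        _, m, _ = build_additive_case(rng, 4)
        tree = nj_tree(DistanceMatrix(ids, m))
        again = PhyloTree.from_newick(tree.newick())
        assert again.splits() == tree.splits()
        assert again.leaf_ids == tree.leaf_ids


def planted_two_subfamily_msa(seed: int, n_per: int = 4):
    """Equal-length protein alignment with two planted subfamilies."""
    rng = np.random.default_rng(seed)
    anc_a, anc_b, _, _ = simulate_divergent_pair(250, 0.8, 0.4, rng)
    ids, rows = [], []
    from genefamkit.synthetic_data import diverge_cds
    for tag, anc in (("A", anc_a.sequence), ("B", anc_b.sequence)):
        for k in range(n_per):
            cds, _, _ = diverge_cds(anc, 0.05, 0.3, rng)
            ids.append(f"{tag}{k}")
            rows.append(translate_cds(cds))
    return MsaView(tuple(ids), tuple(rows))


class TestBootstrap:
    def test_degenerate_signal_gives_full_support(self):
        rows = ("AAAAAAAA", "AAAAAAAA", "TTTTTTTT", "TTTTTTTT")
        msa = MsaView(("a1", "a2", "b1", "b2"), rows)
        _, support = bootstrap_support(msa, replicates=50, seed=0)
        assert list(support.values()) == [100.0]

    def test_seed_reproducibility_and_point_topology_stability(self):
        msa = planted_two_subfamily_msa(4)
        t1, s1 = bootstrap_support(msa, replicates=30, seed=9)
        t2, s2 = bootstrap_support(msa, replicates=30, seed=9)
        assert s1 == s2
        t3, _ = bootstrap_support(msa, replicates=10, seed=1234)
        assert t3.splits() == t1.splits()

    def test_planted_subfamily_split_strongly_supported(self):
        msa = planted_two_subfamily_msa(7)
        tree, support = bootstrap_support(msa, replicates=100, seed=5)
        sub_a = frozenset(i for i in msa.ids if i.startswith("A"))
        anchor = min(tree.leaf_ids)
        key = tree.leaf_ids - sub_a if anchor in sub_a else sub_a
        assert support[key] >= 95.0

    def test_invalid_replicates(self):
        msa = planted_two_subfamily_msa(1)
        with pytest.raises(ValueError):
            bootstrap_support(msa, replicates=0, seed=0)


class TestAssignGroups:
    TREE = "(((m1:0.1,r1:0.1):0.5,(m2:0.1,r2:0.1):0.5):0.5,(r3:0.1,r4:0.1):1.5);"

    def test_nested_members_take_reference_group(self):
        tree = PhyloTree.from_newick(self.TREE)
        groups = assign_groups(tree, {"I": ["r1"], "II": ["r2"], "III": ["r3", "r4"]})
        assert groups["m1"] == "I" and groups["m2"] == "II"

    def test_missing_reference_rejected(self):
        tree = PhyloTree.from_newick(self.TREE)
        with pytest.raises(ValidationError):
            assign_groups(tree, {"I": ["ghost"]})

    def test_bundle_groups_fully_recovered(self, bundle, ref_records):
        from genefamkit.align import center_star_msa
        from genefamkit.synthetic_data import GROUP_OF_SUBFAMILY, SUBFAMILY_OF

        fam = [bundle.proteins[f] for f in bundle.family_ids] + ref_records
        ids, rows = center_star_msa(fam)
        tree, _ = bootstrap_support(MsaView(tuple(ids), tuple(rows)),
                                    replicates=1, seed=0)
        groups = assign_groups(tree, bundle.reference_groups)
        for gene in bundle.family_ids:
            assert groups[gene] == GROUP_OF_SUBFAMILY[SUBFAMILY_OF[gene]]
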