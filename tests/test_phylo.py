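import math

import dendropy
import numpy as np
import pytest

from parapep import (
    DistanceMatrix,
    FamilySpec,
    ValidationError,
    nj_tree,
    simulate_family,
    tn93_distance,
    tn93_matrix,
)


def tn93_reference(a, b):
    """Independent literal evaluation of the published TN93 estimator."""
    a, b = a.upper(), b.upper()
    valid = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(valid)
    from collections import Counter

    cnt = Counter(x for x, _ in valid) + Counter(y for _, y in valid)
    gA, gC, gG, gT = (cnt[x] / (2 * n) for x in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1 = sum(1 for x, y in valid if {x, y} == {"A", "G"}) / n
    P2 = sum(1 for x, y in valid if {x, y} == {"C", "T"}) / n
    Q = sum(1 for x, y in valid if x != y and {x, y} not in ({"A", "G"}, {"C", "T"})) / n
    return (
        -(2 * gA * gG / gR) * math.log(1 - gR * P1 / (2 * gA * gG) - Q / (2 * gR))
        - (2 * gT * gC / gY) * math.log(1 - gY * P2 / (2 * gT * gC) - Q / (2 * gY))
        - 2
        * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
        * math.log(1 - Q / (2 * gR * gY))
    )


def random_additive_tree(k, rng):
    """Random binary tree over taxa t0..t{k-1}; returns (distances, splits)."""
    import itertools

    next_id = [k]
    clusters = {i: f"t{i}" for i in range(k)}
    children = {}
    lengths = {}
    nodes = list(range(k))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        u = next_id[0]
        next_id[0] += 1
        children[u] = (a, b)
        lengths[(u, a)] = 0.05 + rng.random()
        lengths[(u, b)] = 0.05 + rng.random()
        nodes = [n for n in nodes if n not in (a, b)] + [u]

    leaves_under = {}

    def collect(v):
        if v < k:
            leaves_under[v] = frozenset([f"t{v}"])
        else:
            a, b = children[v]
            collect(a)
            collect(b)
            leaves_under[v] = leaves_under[a] | leaves_under[b]

    root = nodes[0]
    collect(root)
    all_taxa = frozenset(f"t{i}" for i in range(k))
    splits = set()
    for u in children:
        if u == root:
            continue
        ls = leaves_under[u]
        if 1 < len(ls) < k - 1:
            splits.add(frozenset((ls, all_taxa - ls)))
    # path distances via parent map
    parent = {}
    for u, (a, b) in children.items():
        parent[a] = u
        parent[b] = u

    def path_to_root(v):
        out = []
        while v in parent:
            out.append(v)
            v = parent[v]
        out.append(v)
        return out

    dist = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        pi, pj = path_to_root(i), path_to_root(j)
        common = set(pi) & set(pj)
        d = 0.0
        for path in (pi, pj):
            for v in path:
                if v in common:
                    break
                d += lengths[(parent[v], v)]
        dist[i, j] = dist[j, i] = d
    taxa = tuple(f"t{i}" for i in range(k))
    return DistanceMatrix(taxa=taxa, values=dist), splits


def tree_splits(tree):
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(leaves) < len(all_taxa) - 1:
            out.add(frozenset((leaves, all_taxa - leaves)))
    return out


class TestTN93:
    def test_identical_sequences(self):
        a = "ACGT" * 30
        assert tn93_distance(a, a) == 0.0

    def test_single_transition_matches_closed_form(self):
        a = "ACGT" * 25
        b = "G" + a[1:]
        assert tn93_distance(a, b) == pytest.approx(tn93_reference(a, b), abs=1e-12)

    def test_mixed_changes_match_closed_form(self):
        a = "ACGTTGCAACGGTTAC" * 10
        b = "GCGTCGCAACAGTTAT" * 10
        assert tn93_distance(a, b) == pytest.approx(tn93_reference(a, b), abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
            assert tn93_distance(a, b) == tn93_distance(b, a)

    def test_gaps_and_n_excluded_pairwise(self):
        a = "ACGTAC-TNACGT"
        b = "ACGTACGTTAC-T"
        comparable = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
        assert len(comparable) == 10
        assert tn93_distance(a, b) == pytest.approx(tn93_reference(a, b), abs=1e-12)

    def test_saturation_returns_infinity(self):
        a = "A" * 50 + "C" * 50
        b = "G" * 50 + "T" * 50
        assert math.isinf(tn93_distance(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tn93_distance("ACGT", "ACG")

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValidationError):
            tn93_distance("NNNN", "ACGT")


class TestNJ:
    def test_four_taxon_additive_recovery(self):
        taxa = ("A", "B", "C", "D")
        v = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(taxa, v))
        assert tree_splits(tree) == {frozenset((frozenset("AB"), frozenset("CD")))}

    def test_three_taxon_branch_lengths(self):
        dm = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        )
        tree = nj_tree(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    @pytest.mark.parametrize("k", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_topologies(self, k):
        rng = np.random.default_rng(k)
        for _ in range(5):
            dm, splits = random_additive_tree(k, rng)
            tree = nj_tree(dm)
            assert tree_splits(tree) == splits

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(42)
        dm, splits = random_additive_tree(6, rng)
        perm = list(rng.permutation(6))
        taxa_p = tuple(dm.taxa[i] for i in perm)
        values_p = dm.values[np.ix_(perm, perm)]
        tree_p = nj_tree(DistanceMatrix(taxa_p, values_p))
        assert tree_splits(tree_p) == splits

    def test_outgroup_rooting(self):
        taxa = ("A", "B", "C", "D")
        v = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(taxa, v), outgroup="D")
        root_children = tree.seed_node.child_nodes()
        labels = [
            frozenset(l.taxon.label for l in c.leaf_iter()) for c in root_children
        ]
        assert frozenset(["D"]) in labels

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], dtype=float))
        with pytest.raises(ValidationError):
            nj_tree(dm)

    def test_agrees_with_dendropy_nj_topology(self):
        # independent cross-check: dendropy's own NJ on the same matrix
        rng = np.random.default_rng(11)
        dm, _ = random_additive_tree(7, rng)
        ours = tree_splits(nj_tree(dm))
        pdm_csv = "," + ",".join(dm.taxa) + "\n"
        for i, t in enumerate(dm.taxa):
            pdm_csv += t + "," + ",".join(str(x) for x in dm.values[i]) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO(pdm_csv), delimiter=","
        )
        theirs = tree_splits(pdm.nj_tree())
        assert ours == theirs


class TestOutgroupSeparation:
    def test_derived_copies_form_their_own_clade(self):
        hits = 0
        n = 20
        for seed in range(1, n + 1):
            family = simulate_family(FamilySpec(seed=seed))
            dm = tn93_matrix(family.cds_aligned)
            tree = nj_tree(dm, outgroup="outgroup_1")
            siblings = frozenset(
                t
                for t in family.cds_aligned
                if t != family.truth.coding_id and not t.startswith("outgroup")
            )
            hits += any(
                frozenset(l.taxon.label for l in node.leaf_iter()) == siblings
                for node in tree
            )
        assert hits >= 0.95 * n
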