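"""Distances, neighbor joining, bootstrap, rooting and clade reports."""

import numpy as np
import pytest

from nbsevol.phylo import (
    DistanceMatrix,
    Node,
    PhyloTree,
    SaturatedDistance,
    bootstrap_supports,
    clade_monophyly,
    midpoint_root,
    neighbor_joining,
    protein_distance,
    species_specific_clades,
)

from oracles import nj_oracle, random_additive_tree


def tree_leaf_distances(tree: PhyloTree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths of a PhyloTree (test helper)."""
    adj = {}

    def walk(node):
        for c in node.children:
            adj.setdefault(id(node), []).append((id(c), c.length))
            adj.setdefault(id(c), []).append((id(node), c.length))
            walk(c)

    walk(tree.root)
    leaves = {id(n): n.label for n in tree.root.leaves()}
    out = {}
    for start, label in leaves.items():
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, ln in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for other, lab2 in leaves.items():
            if other != start:
                out[frozenset((label, lab2))] = dist[other]
    return out


# --- protein distances -------------------------------------------------------

def test_identical_sequences_give_zero_distances():
    msa = {"a": "MKTAY", "b": "MKTAY", "c": "MKTAY"}
    dm = protein_distance(msa, model="p")
    assert (dm.matrix == 0).all()


def test_p_distance_counts_differing_compared_sites():
    msa = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAC", "c": "AAAAAAAAAA"}
    dm = protein_distance(msa, model="p")
    assert dm[("a", "b")] == pytest.approx(0.1)


def test_pairwise_deletion_ignores_gapped_columns():
    msa = {"a": "MK-AY", "b": "MKTAY", "c": "MKTCY"}
    dm = protein_distance(msa, model="p")
    assert dm[("a", "b")] == 0.0           # 4 compared, all equal
    assert dm[("a", "c")] == pytest.approx(0.25)


def test_poisson_correction_and_saturation():
    msa = {"a": "AAAA", "b": "AACC", "c": "ACCC"}
    dm = protein_distance(msa, model="poisson")
    assert dm[("a", "b")] == pytest.approx(-np.log(0.5))
    with pytest.raises(SaturatedDistance):
        protein_distance({"a": "AAAA", "b": "CCCC", "c": "AACC"})


def test_distance_matches_naive_recount_oracle():
    rng = np.random.default_rng(0)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY-")
    labels = [f"s{i}" for i in range(5)]
    msa = {l: "".join(rng.choice(alphabet, size=60)) for l in labels}
    dm = protein_distance(msa, model="p")
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            compared = differing = 0
            for x, y in zip(msa[a], msa[b]):
                if x != "-" and y != "-":
                    compared += 1
                    differing += x != y
            assert dm[(a, b)] == pytest.approx(differing / compared)


# --- neighbor joining --------------------------------------------------------

def test_three_taxon_closed_form():
    dm = DistanceMatrix(list("ABC"), np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float))
    tree = neighbor_joining(dm)
    lengths = {n.label: n.length for n in tree.root.children}
    assert lengths == pytest.approx({"A": 3.0, "B": 2.0, "C": 6.0})


def test_exact_recovery_of_additive_matrices():
    rng = np.random.default_rng(1)
    for _ in range(5):
        n = int(rng.integers(5, 9))
        labels, m, true_bps = random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(labels, m))
        assert set(tree.bipartitions()) == true_bps
        got = tree_leaf_distances(tree)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert got[frozenset((a, b))] == pytest.approx(
                    m[i, labels.index(b)], abs=1e-9)


def test_topology_matches_naive_oracle_on_random_matrices():
    rng = np.random.default_rng(2)
    for _ in range(5):
        n = int(rng.integers(5, 9))
        labels = [f"t{i:02d}" for i in range(n)]
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0.1, 3.0, size=len(iu[0]))
        m[iu] = vals
        m += m.T
        tree = neighbor_joining(DistanceMatrix(labels, m))
        oracle_bps, _ = nj_oracle(labels, m)
        assert set(tree.bipartitions()) == oracle_bps


def test_rejects_asymmetric_matrix_and_too_few_taxa():
    with pytest.raises(ValueError):
        DistanceMatrix(list("AB"), np.array([[0, 1], [2, 0]], float))
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(list("AB"), np.zeros((2, 2))))


# --- bootstrap ----------------------------------------------------------------

def _two_block_msa():
    """Every column identically separates {A,B} from {C,D,E}."""
    return {"A": "AAAAAAAAAA", "B": "AAAAAAAAAA",
            "C": "TTTTTTTTTT", "D": "TTTTTTTTTT", "E": "TTTTTTTTTT"}


def test_invariantly_supported_clade_gets_full_support():
    # identical sequences within blocks: distance ties, but the {A,B} vs rest
    # bipartition survives every resample
    msa = {"A": "AAAAAAAAAA", "B": "AAAAAAAAAC",
           "C": "TTTTTTTTTT", "D": "TTTTTTTTTG", "E": "TTTTTTTATT"}
    tree = bootstrap_supports(msa, replicates=50, seed=0, model="p")
    bps = tree.bipartitions()
    ab = frozenset(("C", "D", "E"))  # canonical side excludes the smallest leaf
    assert ab in bps
    assert bps[ab].support == 100.0


def test_single_replicate_supports_are_zero_or_hundred():
    rng = np.random.default_rng(3)
    msa = {f"s{i}": "".join(rng.choice(list("ACDEF"), size=30)) for i in range(5)}
    tree = bootstrap_supports(msa, replicates=1, seed=1, model="p")
    for node in tree.bipartitions().values():
        assert node.support in (0.0, 100.0)


def test_supports_reproducible_and_label_permutation_invariant():
    rng = np.random.default_rng(4)
    msa = {f"s{i}": "".join(rng.choice(list("ACDEFGH"), size=40)) for i in range(6)}
    t1 = bootstrap_supports(msa, replicates=30, seed=7, model="p")
    t2 = bootstrap_supports(msa, replicates=30, seed=7, model="p")
    s1 = {bp: n.support for bp, n in t1.bipartitions().items()}
    s2 = {bp: n.support for bp, n in t2.bipartitions().items()}
    assert s1 == s2
    # feeding the rows in a different order must not change the supports
    shuffled = dict(reversed(list(msa.items())))
    t3 = bootstrap_supports(shuffled, replicates=30, seed=7, model="p")
    assert {bp: n.support for bp, n in t3.bipartitions().items()} == s1


# --- rooting and clades -------------------------------------------------------

def _toy_tree(support_ab=80.0, support_cd=45.0):
    """((A,B)s1,(C,D)s2,E) with controllable supports."""
    ab = Node(support=support_ab, length=1.0,
              children=[Node(label="A", length=1.0), Node(label="B", length=1.0)])
    cd = Node(support=support_cd, length=1.0,
              children=[Node(label="C", length=1.0), Node(label="D", length=1.0)])
    e = Node(label="E", length=5.0)
    return PhyloTree(root=Node(children=[ab, cd, e]))


def test_midpoint_rooting_preserves_leaves_and_path_lengths():
    tree = _toy_tree()
    before = tree_leaf_distances(tree)
    rooted = midpoint_root(tree)
    assert rooted.root.leaf_labels() == tree.leaf_labels
    after = tree_leaf_distances(rooted)
    for pair, d in before.items():
        assert after[pair] == pytest.approx(d, abs=1e-9)


def test_species_clades_respect_strict_support_threshold():
    species = {"A": "x", "B": "x", "C": "x", "D": "x", "E": "y"}
    rep = species_specific_clades(_toy_tree(80.0, 45.0), species,
                                  support_threshold=50, focal_species="x")
    sides = {frozenset(c.leaves) for c in rep.clades}
    assert frozenset(("A", "B")) in sides
    assert frozenset(("C", "D")) not in sides      # 45 not > 50
    # clade at exactly the threshold is excluded too
    rep50 = species_specific_clades(_toy_tree(50.0, 45.0), species,
                                    support_threshold=50, focal_species="x")
    assert frozenset(("A", "B")) not in {frozenset(c.leaves) for c in rep50.clades}


def test_species_clade_report_conservation_and_maximality():
    species = {l: "x" for l in "ABCDE"}
    rep = species_specific_clades(_toy_tree(90.0, 90.0), species,
                                  support_threshold=50, focal_species="x")
    # maximal clades are disjoint and their sizes sum to n_genes
    seen = set()
    for c in rep.clades:
        assert not (c.leaves & seen)
        seen |= c.leaves
    assert rep.n_genes == sum(len(c.leaves) for c in rep.clades)
    assert rep.proportion_pct <= 100.0
    for c in rep.clades:
        assert len(c.leaves) >= 2


def test_unknown_leaf_species_is_a_keyed_error():
    with pytest.raises(KeyError, match="E"):
        species_specific_clades(_toy_tree(), {l: "x" for l in "ABCD"},
                                focal_species="x")


def test_monophyly_of_full_subtree_and_split_group():
    tree = _toy_tree(support_ab=77.0)
    mono, support = clade_monophyly(tree, ["A", "B"])
    assert mono and support == 77.0
    mono, _ = clade_monophyly(tree, ["A", "C"])
    assert not mono
    assert clade_monophyly(tree, ["A"])[0]          # trivial group
    with pytest.raises(ValueError):
        clade_monophyly(tree, ["A", "Z"])
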