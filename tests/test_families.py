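"""Pairwise alignment metrics, single-linkage families, family census."""

import numpy as np
import pytest

from nbsevol.align import AlignmentPair, align_pair, pairwise_metrics, progressive_msa
from nbsevol.families import build_families, family_census

from oracles import closure_components

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def test_identical_sequences_have_full_coverage_and_identity():
    m = pairwise_metrics("MKTAYIAKQR", "MKTAYIAKQR")
    assert m.coverage == 1.0 and m.identity == 1.0


def test_prefix_sequence_has_full_identity_and_half_coverage():
    b = "MKTAYIAKQRQISFVK"
    a = b[: len(b) // 2]
    m = pairwise_metrics(a, b)
    assert m.identity == 1.0
    assert m.coverage == pytest.approx(0.5)


def test_unknown_residue_never_counts_as_identical():
    m = pairwise_metrics("MKXA", "MKXA")
    assert m.identity == pytest.approx(3 / 4)


def test_metrics_are_symmetric():
    rng = np.random.default_rng(0)
    for _ in range(5):
        a, b = random_protein(rng, 40), random_protein(rng, 55)
        m1, m2 = pairwise_metrics(a, b), pairwise_metrics(b, a)
        assert m1.coverage == pytest.approx(m2.coverage)
        assert m1.identity == pytest.approx(m2.identity)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        pairwise_metrics("", "MKT")


def _gotoh_score(a, b, matrix, gap_open=-10.0, gap_extend=-0.5):
    """Independent affine-gap global alignment score (Gotoh), for the oracle."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def test_alignment_score_matches_independent_gotoh_dp():
    from Bio.Align import substitution_matrices
    from nbsevol.align import _ALIGNER

    b62 = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(1)
    for _ in range(5):
        a, b = random_protein(rng, 50), random_protein(rng, 60)
        expected = _gotoh_score(a, b, b62)
        got = _ALIGNER.align(a, b).score
        assert got == pytest.approx(expected)


def test_progressive_msa_rows_ungap_to_inputs():
    rng = np.random.default_rng(2)
    base = random_protein(rng, 60)
    seqs = {"a": base, "b": base[:40] + "W" + base[41:], "c": base[5:55]}
    msa = progressive_msa(seqs)
    widths = {len(r) for r in msa.values()}
    assert len(widths) == 1
    for gid, row in msa.items():
        assert row.replace("-", "") == seqs[gid]


def _pair(a, b, cov, ident):
    return AlignmentPair(gene_a=a, gene_b=b, aligned_length=100,
                         coverage=cov, identity=ident)


def test_single_linkage_joins_through_intermediate():
    genes = {"A": "M", "B": "M", "C": "M"}
    pairs = [_pair("A", "B", 0.9, 0.9), _pair("B", "C", 0.8, 0.8),
             _pair("A", "C", 0.5, 0.9)]
    fs = build_families(genes, 0.70, pairs=pairs)
    assert fs.families == [frozenset({"A", "B", "C"})]
    assert not fs.singletons


def test_no_passing_pair_gives_all_singletons():
    genes = {"A": "M", "B": "M"}
    fs = build_families(genes, 0.70, pairs=[_pair("A", "B", 0.6, 0.9)])
    assert fs.families == [] and fs.singletons == {"A", "B"}


def test_edge_requires_both_coverage_and_identity():
    genes = {"A": "M", "B": "M"}
    assert build_families(genes, 0.7, pairs=[_pair("A", "B", 0.9, 0.6)]).families == []
    assert build_families(genes, 0.7, pairs=[_pair("A", "B", 0.6, 0.9)]).families == []
    assert build_families(genes, 0.7, pairs=[_pair("A", "B", 0.7, 0.7)]).families


def test_components_match_transitive_closure_oracle():
    rng = np.random.default_rng(3)
    nodes = [f"g{i:02d}" for i in range(30)]
    genes = {n: "M" for n in nodes}
    pairs = []
    edges = []
    for i in range(30):
        for j in range(i + 1, 30):
            cov, ident = rng.uniform(0.4, 1.0), rng.uniform(0.4, 1.0)
            pairs.append(_pair(nodes[i], nodes[j], cov, ident))
            if cov >= 0.8 and ident >= 0.8:
                edges.append((nodes[i], nodes[j]))
    fs = build_families(genes, 0.80, pairs=pairs)
    got = {f for f in fs.families} | {frozenset([s]) for s in fs.singletons}
    assert got == closure_components(nodes, edges)


def test_threshold_monotonicity_on_synthetic_proteins(gene_records):
    nbs = {g: r.protein for g, r in gene_records.items()
           if any(h.domain == "NBS" for h in r.domain_hits)}
    from nbsevol.families import all_pairwise_metrics
    pairs = all_pairwise_metrics(nbs)
    sets = {t: build_families(nbs, t, pairs=pairs) for t in (0.70, 0.80, 0.90)}
    for hi, lo in ((0.90, 0.80), (0.80, 0.70)):
        for fam in sets[hi].families:
            assert any(fam <= parent for parent in sets[lo].families), \
                f"family at {hi} not nested within any family at {lo}"
    for t, fs in sets.items():
        assert fs.n_multi + len(fs.singletons) == len(nbs)


def test_family_census_published_arithmetic():
    # 273 multi / 246 single in 64 families, with 4 TIR multiples in 2 families
    families = [frozenset(f"t{i}_{j}" for j in range(2)) for i in range(2)]
    families += [frozenset(f"n{i}_{j}" for j in range(s))
                 for i, s in enumerate([19] + [5] * 26 + [4] * 25 + [2] * 10)]
    multi = sum(len(f) for f in families)
    singles = frozenset(f"s{i}" for i in range(519 - multi))
    from nbsevol.families import GeneFamilySet
    fs = GeneFamilySet(threshold=0.70, families=families, singletons=singles)
    assert fs.n_multi == 273 and len(fs.families) == 64
    tir = {g: g.startswith("t") for f in families for g in f}
    tir.update({s: False for s in singles})
    # 23 of the singletons are TIR so the TIR total is 27
    for s in list(singles)[:23]:
        tir[s] = True
    cen = family_census(fs, tir)
    assert cen.proportion_multi_pct == pytest.approx(52.60)
    assert cen.mean_members == pytest.approx(4.27)
    assert cen.max_members == 19
    assert cen.tir_multi == 4 and cen.tir_families == 2
    assert cen.proportion_tir_multi_pct == pytest.approx(14.81)


def test_family_census_empty_partition():
    from nbsevol.families import GeneFamilySet
    fs = GeneFamilySet(threshold=0.7, families=[], singletons=frozenset())
    cen = family_census(fs, {})
    assert cen.multi == 0 and cen.proportion_multi_pct == 0.0
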