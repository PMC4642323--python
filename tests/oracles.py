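"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles (standard genetic code via
Biopython, naive loops, no vectorization) and deliberately imports nothing
from the package's computational internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)


def ng_count_sites(codon: str) -> float:
    """Synonymous site count of one codon, naive enumeration."""
    s = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut in _STOPS:
                continue
            possible += 1
            if _AA[mut] == _AA[codon]:
                syn += 1
        if possible:
            s += syn / possible
    return s


def ng_count_differences(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaging over all orderings of the
    minimal mutational pathways; stop-traversing pathways excluded."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    valid, fallback = [], []
    for order in itertools.permutations(diffs):
        cur = a
        sd = nd = 0
        stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                stop = True
                nd += 1
            elif cur in _STOPS:
                nd += 1
            elif _AA[nxt] == _AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        fallback.append((sd, nd))
        if not stop:
            valid.append((sd, nd))
    paths = valid if valid else fallback
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def ng_pair(codons_a: list[str], codons_b: list[str]) -> dict:
    """Full Nei-Gojobori computation for two gap-free codon lists."""
    S = sum(ng_count_sites(c) for c in codons_a) / 2 + \
        sum(ng_count_sites(c) for c in codons_b) / 2
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sd, nd = ng_count_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N

    def jc(p):
        return -0.75 * math.log(1 - 4 * p / 3)

    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "Ks": jc(pS), "Ka": jc(pN)}


# --- neighbor joining, naive ---------------------------------------------------

def nj_oracle(labels: list[str], matrix: np.ndarray):
    """Naive O(n^3) neighbor joining; returns (bipartitions, edge lengths).

    Bipartitions are canonicalized as the side not containing the smallest
    label; ties in Q broken on the smallest contained leaf-label pair, as a
    deterministic convention.
    """
    import copy

    d = {(a, b): float(matrix[i, j]) for i, a in enumerate(labels)
         for j, b in enumerate(labels)}
    clusters = {l: frozenset([l]) for l in labels}
    active = sorted(labels)
    edges = {}  # frozenset(side) -> None, collected as joins happen
    all_leaves = frozenset(labels)
    lengths = {}
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * d[(a, b)] - r[a] - r[b]
            la = min(min(clusters[a]), min(clusters[b]))
            lb = max(min(clusters[a]), min(clusters[b]))
            cand = (round(q, 9), la, lb)
            if best is None or cand < best[0:3]:
                best = (*cand, a, b)
        _, _, _, a, b = best
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[(a, b)] - la
        if la < 0:
            la, lb = 0.0, d[(a, b)]
        elif lb < 0:
            la, lb = d[(a, b)], 0.0
        new = a + "|" + b
        clusters[new] = clusters[a] | clusters[b]
        lengths[clusters[a]] = la
        lengths[clusters[b]] = lb
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = max(
                0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)]), 0.0)
        active = sorted(set(active) - {a, b} | {new},
                        key=lambda x: min(clusters[x]))
    # terminal 3-star
    a, b, c = active
    dab, dac, dbc = d[(a, b)], d[(a, c)], d[(b, c)]
    lengths[clusters[a]] = max(0.5 * (dab + dac - dbc), 0.0)
    lengths[clusters[b]] = max(0.5 * (dab + dbc - dac), 0.0)
    lengths[clusters[c]] = max(0.5 * (dac + dbc - dab), 0.0)
    ref = min(labels)
    bps = set()
    for side in lengths:
        s = side if ref not in side else all_leaves - side
        if 2 <= len(s) <= len(labels) - 2:
            bps.add(s)
    return bps, lengths


def random_additive_tree(rng: np.random.Generator, n: int):
    """A random tip-labeled binary tree: returns (labels, exact distance
    matrix, set of non-trivial bipartitions canonicalized away from the
    smallest label)."""
    labels = [f"t{i:02d}" for i in range(n)]
    index = {l: i for i, l in enumerate(labels)}
    m = np.zeros((n, n))
    # subtree = (leafset, {leaf: distance to subtree root})
    subtrees = [(frozenset([l]), {l: 0.0}) for l in labels]
    bipartitions = set()
    all_leaves = frozenset(labels)
    ref = labels[0]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        (leaves_b, dist_b) = subtrees.pop(int(j))
        (leaves_a, dist_a) = subtrees.pop(int(i))
        la = float(rng.uniform(0.1, 2.0))
        lb = float(rng.uniform(0.1, 2.0))
        for a, da in dist_a.items():
            for b, db in dist_b.items():
                d = da + la + db + lb
                m[index[a], index[b]] = m[index[b], index[a]] = d
        merged = {**{a: da + la for a, da in dist_a.items()},
                  **{b: db + lb for b, db in dist_b.items()}}
        for side in (leaves_a, leaves_b):
            s = side if ref not in side else all_leaves - side
            if 2 <= len(s) <= n - 2:
                bipartitions.add(s)
        subtrees.append((leaves_a | leaves_b, merged))
    return labels, m, bipartitions


# --- pruning likelihood, brute force -------------------------------------------

SENSE = sorted(c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
               if c not in _STOPS)


def gy94_q(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    purine = {"A", "G"}
    n = len(SENSE)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE):
        for j, cj in enumerate(SENSE):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            rate = pi[j]
            if (ci[k] in purine) == (cj[k] in purine):
                rate *= kappa
            if _AA[ci] != _AA[cj]:
                rate *= omega
            q[i, j] = rate
    for i in range(n):
        q[i, i] = -q[i].sum()
    scale = -(pi * np.diag(q)).sum()
    return q / scale


def brute_force_likelihood(leaf_codons: dict[str, list[str]],
                           branch_lengths: dict[str, float],
                           kappa: float, omega: float, pi: np.ndarray) -> float:
    """Star-tree log-likelihood by explicit summation over root states."""
    from scipy.linalg import expm

    q = gy94_q(kappa, omega, pi)
    p = {leaf: expm(q * t) for leaf, t in branch_lengths.items()}
    idx = {c: i for i, c in enumerate(SENSE)}
    n_sites = len(next(iter(leaf_codons.values())))
    total = 0.0
    for s in range(n_sites):
        site = 0.0
        for r in range(len(SENSE)):
            term = pi[r]
            for leaf, codons in leaf_codons.items():
                term *= p[leaf][r, idx[codons[s]]]
            site += term
        total += math.log(site)
    return total


# --- motif scan, naive ---------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def naive_scan(seq: str, pattern: str) -> tuple[list[int], list[int]]:
    """(forward starts, reverse starts), 1-based, naive sliding window."""

    def matches(window: str, pat: str) -> bool:
        return len(window) == len(pat) and all(
            c in _IUPAC[p] for c, p in zip(window, pat))

    rc = "".join(_COMP[c] for c in reversed(pattern))
    fwd, rev = [], []
    for i in range(len(seq) - len(pattern) + 1):
        window = seq[i:i + len(pattern)]
        if matches(window, pattern):
            fwd.append(i + 1)
        if matches(window, rc):
            rev.append(i + 1)
    return fwd, rev


# --- single-linkage closure, naive ---------------------------------------------

def closure_components(nodes: list[str], edges: list[tuple[str, str]]):
    """Connected components by repeated transitive closure of the adjacency
    boolean matrix."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.eye(n, dtype=bool)
    for a, b in edges:
        adj[index[a], index[b]] = adj[index[b], index[a]] = True
    while True:
        nxt = adj @ adj
        if (nxt == adj).all():
            break
        adj = nxt
    comps = set()
    for i in range(n):
        comps.add(frozenset(nodes[j] for j in range(n) if adj[i, j]))
    return comps
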