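"""Protein alignment: pairwise global (Needleman-Wunsch) alignment with the
coverage/identity metrics used for family clustering, and a built-in
progressive multiple aligner (guide tree + profile-profile alignment) for the
family codon alignments and the NBS-domain phylogeny.

Scoring is fixed at BLOSUM62 with affine gaps (open -10, extend -0.5) and is
recorded in output metadata by the pipeline for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

SCORING = {"matrix": "BLOSUM62", "gap_open": -10.0, "gap_extend": -0.5}

_PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = SCORING["gap_open"]
    aligner.extend_gap_score = SCORING["gap_extend"]
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlignmentPair:
    """Coverage/identity metrics from one global pairwise alignment.

    ``aligned_length`` counts columns with a residue in both sequences;
    ``coverage`` divides it by the longer gene's length (symmetric,
    conservative); ``identity`` is identical residue pairs over aligned
    length, with 'X' never counted identical.
    """

    gene_a: str
    gene_b: str
    aligned_length: int
    coverage: float
    identity: float


def pairwise_metrics(a: str, b: str, *, id_a: str = "a", id_b: str = "b") -> AlignmentPair:
    """Global Needleman-Wunsch alignment metrics between two protein sequences."""
    a, b = a.upper(), b.upper()
    for name, seq in ((id_a, a), (id_b, b)):
        if not seq:
            raise ValueError(f"empty sequence for {name}")
        bad = set(seq) - set(_PROTEIN_ALPHABET + "X")
        if bad:
            raise ValueError(f"{name}: invalid residues {sorted(bad)}")
    alignment = next(iter(_ALIGNER.align(a, b)))
    row_a, row_b = str(alignment[0]), str(alignment[1])
    aligned = identical = 0
    for ra, rb in zip(row_a, row_b):
        if ra != "-" and rb != "-":
            aligned += 1
            if ra == rb and ra != "X":
                identical += 1
    coverage = aligned / max(len(a), len(b))
    identity = identical / aligned if aligned else 0.0
    return AlignmentPair(gene_a=id_a, gene_b=id_b, aligned_length=aligned,
                         coverage=coverage, identity=identity)


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Aligned rows of one optimal global alignment (deterministic first hit)."""
    alignment = next(iter(_ALIGNER.align(a.upper(), b.upper())))
    return str(alignment[0]), str(alignment[1])


# --- progressive multiple alignment -----------------------------------------

_AA_INDEX = {aa: i for i, aa in enumerate(_PROTEIN_ALPHABET)}
_B62 = substitution_matrices.load("BLOSUM62")
_SCORE = np.array([[float(_B62[a, b]) for b in _PROTEIN_ALPHABET]
                   for a in _PROTEIN_ALPHABET])
_X_SCORE = 0.0  # unknown residue scores 0 against everything


def _profile(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(20-dim residue frequency matrix, non-gap fraction) per column."""
    ncol = len(rows[0])
    freq = np.zeros((ncol, 20))
    occ = np.zeros(ncol)
    for row in rows:
        for c, ch in enumerate(row):
            if ch == "-":
                continue
            occ[c] += 1
            if ch in _AA_INDEX:
                freq[c, _AA_INDEX[ch]] += 1
    nrows = len(rows)
    return freq / nrows, occ / nrows


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    gap: float = -6.0) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment, sum-of-pairs BLOSUM62 expectation,
    linear gap penalty weighted by profile occupancy."""
    fa, occ_a = _profile(rows_a)
    fb, occ_b = _profile(rows_b)
    # expected substitution score between column pairs
    score = fa @ _SCORE @ fb.T
    n, m = score.shape
    gap_a = gap * occ_a   # cost of gapping profile A's column
    gap_b = gap * occ_b
    dp = np.empty((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up (gap in B), 2 left
    dp[0, 0] = 0.0
    dp[1:, 0] = np.cumsum(gap_a)
    dp[0, 1:] = np.cumsum(gap_b)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        diag = dp[i - 1, :m] + score[i - 1]
        up = dp[i - 1, 1:] + gap_a[i - 1]
        prev = dp[i]
        prev[0] = dp[i, 0]
        # left moves depend on current row; do a sequential pass
        row = np.maximum(diag, up)
        choice = np.where(diag >= up, 0, 1).astype(np.int8)
        acc = prev[0]
        for j in range(1, m + 1):
            left = acc + gap_b[j - 1]
            if row[j - 1] >= left:
                acc = row[j - 1]
                ptr[i, j] = choice[j - 1]
            else:
                acc = left
                ptr[i, j] = 2
            prev[j] = acc
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0 and i > 0 and j > 0:
            out_a.append("COL")
            out_b.append("COL")
            i -= 1
            j -= 1
        elif move == 1 and i > 0:
            out_a.append("COL")
            out_b.append("GAP")
            i -= 1
        else:
            out_a.append("GAP")
            out_b.append("COL")
            j -= 1
    out_a.reverse()
    out_b.reverse()

    def expand(rows: list[str], ops: list[str]) -> list[str]:
        result = []
        for row in rows:
            chars = []
            k = 0
            for op in ops:
                if op == "COL":
                    chars.append(row[k])
                    k += 1
                else:
                    chars.append("-")
            result.append("".join(chars))
        return result

    return expand(rows_a, out_a), expand(rows_b, out_b)


def progressive_msa(sequences: Mapping[str, str] | Sequence[tuple[str, str]]) -> dict[str, str]:
    """Progressive multiple alignment.

    Guide order comes from UPGMA on pairwise p-distances of global pairwise
    alignments; profiles are merged with profile-profile Needleman-Wunsch.
    Deterministic: ties broken on lexicographically smallest member labels.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    ids = [i for i, _ in items]
    seqs = {i: s.upper() for i, s in items}
    if len(ids) == 0:
        raise ValueError("no sequences")
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}
    # pairwise distance = 1 - identity of the global alignment
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = pairwise_metrics(seqs[ids[i]], seqs[ids[j]], id_a=ids[i], id_b=ids[j])
            dist[i, j] = dist[j, i] = 1.0 - m.identity
    # UPGMA merge order
    clusters: dict[int, dict] = {
        i: {"rows": {ids[i]: seqs[ids[i]]}, "size": 1, "min_label": ids[i]}
        for i in range(n)
    }
    d = {(min(i, j), max(i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        live = sorted(clusters)
        best = None
        for a_i, ca in enumerate(live):
            for cb in live[a_i + 1:]:
                key = (min(ca, cb), max(ca, cb))
                la = min(clusters[ca]["min_label"], clusters[cb]["min_label"])
                lb = max(clusters[ca]["min_label"], clusters[cb]["min_label"])
                cand = (d[key], la, lb, key)
                if best is None or cand < best:
                    best = cand
        _, _, _, (ca, cb) = best
        rows_a = clusters[ca]["rows"]
        rows_b = clusters[cb]["rows"]
        keys_a, keys_b = list(rows_a), list(rows_b)
        new_a, new_b = _align_profiles([rows_a[k] for k in keys_a],
                                       [rows_b[k] for k in keys_b])
        merged_rows = dict(zip(keys_a, new_a)) | dict(zip(keys_b, new_b))
        size = clusters[ca]["size"] + clusters[cb]["size"]
        new = {"rows": merged_rows, "size": size,
               "min_label": min(clusters[ca]["min_label"], clusters[cb]["min_label"])}
        for other in live:
            if other in (ca, cb):
                continue
            key_a = (min(ca, other), max(ca, other))
            key_b = (min(cb, other), max(cb, other))
            da, db = d.pop(key_a), d.pop(key_b)
            w_a, w_b = clusters[ca]["size"], clusters[cb]["size"]
            d[(min(next_id, other), max(next_id, other))] = (w_a * da + w_b * db) / (w_a + w_b)
        d.pop((min(ca, cb), max(ca, cb)))
        del clusters[ca], clusters[cb]
        clusters[next_id] = new
        next_id += 1
    final = next(iter(clusters.values()))["rows"]
    return {gid: final[gid] for gid in ids}
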