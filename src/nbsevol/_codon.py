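"""Shared codon-level machinery: the standard genetic code over the 61 sense
codons, the GY94-style codon substitution process, and cached helpers used by
both the simulator and the likelihood engine.

Conventions
-----------
* Codons are indexed 0..60 in lexicographic (A<C<G<T) order of the sense
  codons of the standard nuclear code; stop codons are excluded everywhere.
* Rate matrices are normalized so the expected substitution rate per codon
  site is 1 at stationarity; branch lengths are therefore expected
  substitutions per codon site.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_standard.stop_codons)

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
           if c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

#: amino acid encoded by each sense codon
CODON_AA: tuple[str, ...] = tuple(_standard.forward_table[c] for c in SENSE_CODONS)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return a != b and (a in _PURINES) == (b in _PURINES)


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide sequence into codons, validating length."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def encode_codons(seq: str) -> np.ndarray:
    """In-frame CDS -> array of sense-codon indices; stops are rejected."""
    idx = []
    for pos, codon in enumerate(codons_of(seq.upper())):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {pos + 1}")
        try:
            idx.append(CODON_INDEX[codon])
        except KeyError:
            raise ValueError(f"invalid codon {codon!r} at codon {pos + 1}") from None
    return np.asarray(idx, dtype=np.int64)


def decode_codons(indices: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in indices)


def translate_codons(indices: np.ndarray) -> str:
    return "".join(CODON_AA[i] for i in indices)


# --- single-step change classification, precomputed over 61x61 -------------

def _single_step_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(neighbor, transition, synonymous) boolean 61x61 tables for
    single-nucleotide codon changes."""
    nb = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros_like(nb)
    syn = np.zeros_like(nb)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            nb[i, j] = True
            ts[i, j] = is_transition(ci[k], cj[k])
            syn[i, j] = CODON_AA[i] == CODON_AA[j]
    return nb, ts, syn


NEIGHBOR, TRANSITION, SYNONYMOUS = _single_step_tables()


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94-style 61x61 generator: q_ij = pi_j * kappa^[ts] * omega^[nonsyn]
    for single-nucleotide changes, 0 otherwise, normalized to mean rate 1."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = np.asarray(pi, dtype=float)
    q = np.where(NEIGHBOR, pi[None, :], 0.0)
    q = q * np.where(TRANSITION, kappa, 1.0)
    q = q * np.where(NEIGHBOR & ~SYNONYMOUS, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (omega=0 with no synonymous rate?)")
    return q / scale


def transition_probabilities(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via symmetric eigendecomposition (Q is reversible)."""
    evals, left, right = _decompose(q, pi)
    return probabilities_from_decomposition(evals, left, right, t)


def decompose_rate_matrix(q: np.ndarray, pi: np.ndarray):
    """Eigendecompose a reversible Q once so P(t) is cheap for many t.

    Returns (evals, U, Uinv) with Q = U diag(evals) Uinv.
    """
    return _decompose(q, pi)


def _decompose(q: np.ndarray, pi: np.ndarray):
    pi = np.asarray(pi, dtype=float)
    d = np.sqrt(pi)
    sym = q * d[:, None] / d[None, :]
    sym = 0.5 * (sym + sym.T)  # symmetrize away rounding noise
    evals, vecs = np.linalg.eigh(sym)
    u = vecs / d[:, None]
    uinv = vecs.T * d[None, :]
    return evals, u, uinv


def probabilities_from_decomposition(evals, u, uinv, t: float) -> np.ndarray:
    if t < 0:
        raise ValueError("branch length must be >= 0")
    p = (u * np.exp(evals * t)[None, :]) @ uinv
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(codon_counts: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies from observed sense-codon counts.

    Positional nucleotide frequencies are multiplied per codon and
    renormalized over the 61 sense codons; a small floor keeps observed
    codons off exact zero probability.
    """
    pos_freq = np.zeros((3, 4))
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for idx, count in enumerate(codon_counts):
        codon = SENSE_CODONS[idx]
        for k in range(3):
            pos_freq[k, nt_index[codon[k]]] += count
    total = pos_freq.sum(axis=1, keepdims=True)
    if not np.all(total > 0):
        raise ValueError("no codons supplied")
    pos_freq /= total
    pi = np.array([
        pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]] * pos_freq[2, nt_index[c[2]]]
        for c in SENSE_CODONS
    ])
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


# --- Nei-Gojobori site and difference tables --------------------------------

@lru_cache(maxsize=1)
def ng_synonymous_sites() -> np.ndarray:
    """Per-codon synonymous site counts s_i (of 3 sites total).

    Each codon position contributes 1 site, apportioned by the fraction of
    its single-nucleotide changes that are synonymous; changes that create a
    stop codon are excluded from the possible-change count.
    """
    s = np.zeros(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        for k in range(3):
            syn = 0
            possible = 0
            for alt in NUCLEOTIDES:
                if alt == codon[k]:
                    continue
                mutant = codon[:k] + alt + codon[k + 1:]
                if mutant in STOP_CODONS:
                    continue
                possible += 1
                if _standard.forward_table[mutant] == CODON_AA[i]:
                    syn += 1
            if possible:
                s[i] += syn / possible
    return s


@lru_cache(maxsize=1)
def ng_difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """(Sd, Nd) 61x61 tables: synonymous / nonsynonymous differences between
    codon pairs, averaged over all orderings of minimal mutational pathways;
    pathways passing through a stop codon are excluded (all-stop fallback:
    average over every ordering)."""
    sd = np.zeros((N_CODONS, N_CODONS))
    nd = np.zeros((N_CODONS, N_CODONS))
    fwd = _standard.forward_table
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i >= j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if not diffs:
                continue
            valid: list[tuple[int, int]] = []
            all_paths: list[tuple[int, int]] = []
            for order in itertools.permutations(diffs):
                cur = ci
                s_count = n_count = 0
                through_stop = False
                for k in order:
                    nxt = cur[:k] + cj[k] + cur[k + 1:]
                    if nxt in STOP_CODONS:
                        through_stop = True
                        # amino-acid comparison undefined through a stop;
                        # count the step as nonsynonymous for the fallback
                        n_count += 1
                    else:
                        if fwd[nxt] == (fwd[cur] if cur not in STOP_CODONS else None):
                            s_count += 1
                        else:
                            n_count += 1
                    cur = nxt
                all_paths.append((s_count, n_count))
                if not through_stop:
                    valid.append((s_count, n_count))
            paths = valid if valid else all_paths
            sd[i, j] = sd[j, i] = sum(p[0] for p in paths) / len(paths)
            nd[i, j] = nd[j, i] = sum(p[1] for p in paths) / len(paths)
    return sd, nd
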