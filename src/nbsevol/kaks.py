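"""Nei-Gojobori (1986) Ka/Ks estimation with Jukes-Cantor correction,
codon-alignment back-translation, family-level averaging, and the
Ks-bin duplication-age profile.

Ks (synonymous substitutions per synonymous site) is the molecular clock
used to date duplication events; Ka/Ks < 1 indicates purifying selection,
> 1 positive selection.  Sites are counted by exhaustive single-nucleotide
mutation enumeration over the standard genetic code, and differences by
averaging over all orderings of minimal mutational pathways, excluding
pathways through stop codons — the method behind MEGA's default "Ka/Ks".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._codon import (
    CODON_INDEX,
    STOP_CODONS,
    codons_of,
    ng_difference_tables,
    ng_synonymous_sites,
)

GAP_CODON = "---"


class SaturatedDistance(ValueError):
    """Observed proportion of differences is at or beyond the Jukes-Cantor
    correction's domain (p >= 3/4)."""


def jukes_cantor(p: float) -> float:
    """JC multiple-hit correction d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturatedDistance(f"p = {p:.4f} >= 3/4: distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsEstimate:
    """Pairwise (or family-averaged) Nei-Gojobori estimate."""

    S: float          # synonymous sites
    N: float          # nonsynonymous sites
    Sd: float         # synonymous differences
    Nd: float         # nonsynonymous differences
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float | None = None  # None when Ks == 0 (undefined)

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


@dataclass
class CodonAlignment:
    """Codon rows gap-extended in whole codons from a protein alignment."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("codon alignment rows differ in length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("codon alignment length not a multiple of 3")

    def pair(self, i: int, j: int) -> tuple[str, str]:
        return self.rows[i], self.rows[j]


def backtranslate_alignment(protein_alignment: Mapping[str, str] | Sequence[tuple[str, str]],
                            cds_map: Mapping[str, str]) -> CodonAlignment:
    """Expand an aligned protein MSA to a codon alignment using each gene's CDS.

    Every residue becomes its source codon and every gap becomes ``---``;
    the ungapped row therefore reproduces the CDS exactly.  A CDS that does
    not translate to the ungapped protein row raises with the first
    offending position.
    """
    items = protein_alignment.items() if isinstance(protein_alignment, Mapping) \
        else list(protein_alignment)
    ids, rows = [], []
    from ._codon import _standard  # standard-code translation table
    for gene_id, aligned in items:
        try:
            cds = cds_map[gene_id]
        except KeyError:
            raise KeyError(f"no CDS supplied for {gene_id}") from None
        codons = codons_of(cds.upper())
        residues = [c for c in aligned if c != "-"]
        if len(codons) != len(residues):
            raise ValueError(
                f"{gene_id}: CDS encodes {len(codons)} codons but aligned protein "
                f"has {len(residues)} residues")
        out = []
        k = 0
        for col, residue in enumerate(aligned):
            if residue == "-":
                out.append(GAP_CODON)
                continue
            codon = codons[k]
            if codon in STOP_CODONS:
                raise ValueError(f"{gene_id}: internal stop codon at codon {k + 1}")
            aa = _standard.forward_table.get(codon)
            if aa is None:
                raise ValueError(f"{gene_id}: invalid codon {codon!r} at codon {k + 1}")
            if residue != "X" and aa != residue:
                raise ValueError(
                    f"{gene_id}: CDS codon {codon} (-> {aa}) does not match aligned "
                    f"residue {residue!r} at alignment column {col + 1}")
            out.append(codon)
            k += 1
        ids.append(gene_id)
        rows.append("".join(out))
    return CodonAlignment(ids=ids, rows=rows)


def nei_gojobori(row_a: str, row_b: str) -> KaKsEstimate:
    """Nei-Gojobori Ka/Ks between two aligned codon rows.

    Codon columns containing a gap in either row are dropped (pairwise
    deletion).  Site counts are averaged over the two sequences; the JC
    correction is applied to both proportions.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    syn_sites = ng_synonymous_sites()
    sd_table, nd_table = ng_difference_tables()
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    codons = 0
    for ca, cb in zip(codons_of(row_a.upper()), codons_of(row_b.upper())):
        if "-" in ca or "-" in cb:
            continue
        try:
            ia, ib = CODON_INDEX[ca], CODON_INDEX[cb]
        except KeyError:
            bad = ca if ca not in CODON_INDEX else cb
            raise ValueError(f"invalid or stop codon {bad!r} in aligned row") from None
        codons += 1
        S_a += syn_sites[ia]
        S_b += syn_sites[ib]
        Sd += sd_table[ia, ib]
        Nd += nd_table[ia, ib]
    if codons == 0:
        raise ValueError("no comparable (gap-free) codons between the two rows")
    S = 0.5 * (S_a + S_b)
    N = 3.0 * codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    ratio = (Ka / Ks) if Ks > 0 else None
    return KaKsEstimate(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio)


@dataclass
class FamilyKaKs:
    """Family-level summary: arithmetic means over all within-family pairs.

    The family ratio is mean(Ka)/mean(Ks) — robust to pairs whose own ratio
    is undefined — flagged None when mean Ks is 0.
    """

    family_id: str
    n_pairs: int
    Ka: float
    Ks: float
    ratio: float | None
    pair_estimates: list[tuple[str, str, KaKsEstimate]] = field(default_factory=list)
    n_saturated: int = 0


def family_kaks(family_id: str, alignment: CodonAlignment) -> FamilyKaKs:
    """Average pairwise Ka/Ks over all within-family pairs.

    Saturated pairs (p >= 3/4) are skipped and counted; if every pair is
    saturated the family is flagged with n_pairs == 0.
    """
    n = len(alignment.ids)
    if n < 2:
        raise ValueError("family must have at least 2 members")
    pairs: list[tuple[str, str, KaKsEstimate]] = []
    saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = nei_gojobori(alignment.rows[i], alignment.rows[j])
            except SaturatedDistance:
                saturated += 1
                continue
            pairs.append((alignment.ids[i], alignment.ids[j], est))
    if not pairs:
        return FamilyKaKs(family_id=family_id, n_pairs=0, Ka=float("nan"),
                          Ks=float("nan"), ratio=None, n_saturated=saturated)
    ka = float(np.mean([e.Ka for _, _, e in pairs]))
    ks = float(np.mean([e.Ks for _, _, e in pairs]))
    ratio = ka / ks if ks > 0 else None
    return FamilyKaKs(family_id=family_id, n_pairs=len(pairs), Ka=ka, Ks=ks,
                      ratio=ratio, pair_estimates=pairs, n_saturated=saturated)


@dataclass
class KsProfile:
    """Duplication-age profile: Ks histogram at 0.1 bins over [0, 1) with the
    mean Ka/Ks of each bin — the standard duplication-age summary figure."""

    bin_edges: np.ndarray            # 0.0, 0.1, ..., 1.0
    counts: np.ndarray               # per-bin pair counts, half-open [lo, hi)
    frequencies: np.ndarray          # counts / total pairs (incl. Ks > 1)
    mean_ratio: np.ndarray           # mean Ka/Ks per bin (nan when empty)
    n_pairs: int
    n_over_one: int                  # pairs with Ks >= 1, counted separately

    @property
    def modal_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.counts))
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])


def ks_profile(estimates: Sequence[KaKsEstimate], bin_width: float = 0.1) -> KsProfile:
    """Bin pairwise estimates by Ks over [0, 1); mean Ka/Ks per bin."""
    if not estimates:
        raise ValueError("no estimates to profile")
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    nbins = len(edges) - 1
    counts = np.zeros(nbins, dtype=int)
    ratio_sums = np.zeros(nbins)
    ratio_counts = np.zeros(nbins, dtype=int)
    over = 0
    for est in estimates:
        if est.Ks >= 1.0:
            over += 1
            continue
        b = min(int(est.Ks / bin_width), nbins - 1)
        counts[b] += 1
        if est.ratio is not None:
            ratio_sums[b] += est.ratio
            ratio_counts[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ratio = np.where(ratio_counts > 0, ratio_sums / np.maximum(ratio_counts, 1),
                              np.nan)
    total = len(estimates)
    return KsProfile(bin_edges=edges, counts=counts,
                     frequencies=counts / total, mean_ratio=mean_ratio,
                     n_pairs=total, n_over_one=over)
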