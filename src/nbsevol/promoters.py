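"""Promoter extraction and IUPAC-degenerate cis-element scanning.

Promoters are the ~1000 bp immediately upstream of each gene (strand-aware,
relative to the annotated gene feature, truncated and flagged at contig
edges).  Scanning reports every overlapping occurrence of each named IUPAC
pattern on both strands — SIGNALSCAN-like behaviour, so a palindromic site
yields one hit per strand.  An 'N' in the promoter only matches motif
positions that are themselves 'N'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """A named cis-element pattern over IUPAC nucleotide codes."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC code(s) {sorted(bad)}")

    def regex(self) -> re.Pattern:
        return re.compile(_pattern_to_regex(self.pattern))

    def reverse_regex(self) -> re.Pattern:
        return re.compile(_pattern_to_regex(reverse_complement(self.pattern)))

    def __len__(self) -> int:
        return len(self.pattern)


def _pattern_to_regex(pattern: str) -> str:
    # promoter N matches only motif N: add N to the class only when the
    # motif position is N itself
    parts = []
    for code in pattern.upper():
        chars = IUPAC[code]
        if code == "N":
            parts.append("[ACGTN]")
        elif len(chars) == 1:
            parts.append(chars)
        else:
            parts.append(f"[{chars}]")
    return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start`` is 1-based on the promoter's forward
    coordinate (for '-' hits, the reverse complement of the promoter
    substring starting there matches the pattern)."""

    gene_id: str
    motif: str
    strand: str
    start: int


@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str
    truncated: bool = False


def extract_promoters(genome: Mapping[str, str], genes: Sequence, length: int = 1000
                      ) -> list[PromoterRecord]:
    """Upstream promoter regions from a genome and gene coordinates.

    ``genes`` is a sequence of objects with ``gene_id``, ``seqid``, ``start``,
    ``end``, ``strand`` (1-based inclusive, as in GFF3).  For '+' genes the
    promoter is the ``length`` bases ending immediately before ``start``; for
    '-' genes it is the reverse complement of the ``length`` bases starting
    immediately after ``end``.  Promoters are emitted 5'->3' relative to the
    gene and flagged when truncated by a contig edge.
    """
    out = []
    for g in genes:
        try:
            contig = genome[g.seqid]
        except KeyError:
            raise KeyError(f"{g.gene_id}: contig {g.seqid!r} absent from genome") from None
        if g.strand == "+":
            lo = max(g.start - 1 - length, 0)
            seq = contig[lo:g.start - 1]
            truncated = len(seq) < length
        elif g.strand == "-":
            hi = min(g.end + length, len(contig))
            seq = reverse_complement(contig[g.end:hi])
            truncated = len(seq) < length
        else:
            raise ValueError(f"{g.gene_id}: strand must be '+' or '-'")
        out.append(PromoterRecord(gene_id=g.gene_id, sequence=seq.upper(),
                                  truncated=truncated))
    return out


def scan(promoters: Iterable[PromoterRecord | tuple[str, str]],
         motifs: Sequence[Motif]) -> list[MotifHit]:
    """All overlapping motif occurrences on both strands of each promoter."""
    compiled = [(m, m.regex(), m.reverse_regex()) for m in motifs]
    hits: list[MotifHit] = []
    for rec in promoters:
        gene_id, seq = (rec.gene_id, rec.sequence) if isinstance(rec, PromoterRecord) \
            else rec
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{gene_id}: invalid nucleotide(s) {sorted(bad)}")
        for motif, fwd, rev in compiled:
            # overlapping matches: restart one past each match start
            for strand, regex in (("+", fwd), ("-", rev)):
                pos = 0
                while True:
                    m = regex.search(seq, pos)
                    if m is None:
                        break
                    hits.append(MotifHit(gene_id=gene_id, motif=motif.name,
                                         strand=strand, start=m.start() + 1))
                    pos = m.start() + 1
    hits.sort(key=lambda h: (h.gene_id, h.motif, h.start, h.strand))
    return hits


@dataclass
class MotifCensus:
    """Per-motif totals: occurrences and genes with at least one hit.

    The published per-element "Number" column is ambiguous between the two,
    so both are reported; ordering is by gene count descending.
    """

    occurrences: dict[str, int]
    genes_with_hit: dict[str, int]
    n_genes: int

    def sorted_names(self) -> list[str]:
        return sorted(self.occurrences,
                      key=lambda n: (-self.genes_with_hit[n], -self.occurrences[n], n))


def motif_census(hits: Sequence[MotifHit], gene_ids: Iterable[str],
                 motifs: Sequence[Motif]) -> MotifCensus:
    gene_ids = list(gene_ids)
    occ = {m.name: 0 for m in motifs}
    genes = {m.name: set() for m in motifs}
    for h in hits:
        occ[h.motif] += 1
        genes[h.motif].add(h.gene_id)
    return MotifCensus(occurrences=occ,
                       genes_with_hit={n: len(s) for n, s in genes.items()},
                       n_genes=len(gene_ids))


def read_motif_file(path) -> list[Motif]:
    """Motif TSV: ``name<TAB>pattern`` per line, '#' comments allowed."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pattern = line.split("\t")[:2]
            motifs.append(Motif(name=name, pattern=pattern))
    return motifs
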