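"""Architecture classification of NBS-encoding resistance genes and the
genome census.

Plant NBS (NB-ARC) resistance genes are classified by their N-terminal domain
(TIR, coiled-coil CC, or neither, "X") and the presence of a C-terminal LRR:
TNL/TN, CNL/CN, XNL/XN.  The RPW8 powdery-mildew-resistance domain is flagged
orthogonally (an RPW8 gene keeps its six-way code; RNL is a flag, not a
seventh class), because RPW8 co-occurs with both TIR and CC architectures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .report import round_half_up

NBS_DOMAIN_LABELS = ("NBS", "TIR", "CC", "LRR", "RPW8")

#: six-way architecture codes, TIR-type first
CLASS_CODES = ("TNL", "TN", "CNL", "CN", "XNL", "XN")


class NotNbsEncoding(ValueError):
    """Raised when a gene lacks the NBS (NB-ARC) domain and therefore is not
    an NBS-encoding gene at all."""


@dataclass(frozen=True)
class DomainHit:
    """One domain annotation row (1-based inclusive amino-acid coordinates)."""

    gene_id: str
    domain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.domain not in NBS_DOMAIN_LABELS:
            raise ValueError(f"unknown domain label {self.domain!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates {self.start}..{self.end}")


@dataclass
class GeneRecord:
    """One gene: sequences, species, exon count and domain annotations."""

    gene_id: str
    species: str
    protein: str
    cds: str
    exon_count: int = 1
    domain_hits: list[DomainHit] = field(default_factory=list)

    @property
    def domain_labels(self) -> frozenset[str]:
        return frozenset(h.domain for h in self.domain_hits)


@dataclass(frozen=True)
class ArchitectureClass:
    code: str                  # one of CLASS_CODES
    rnl_flag: bool             # RPW8 present

    @property
    def is_tir(self) -> bool:
        return self.code in ("TNL", "TN")

    @property
    def has_lrr(self) -> bool:
        return self.code.endswith("L")


def classify_gene(hits: Iterable[str | DomainHit]) -> ArchitectureClass:
    """Assign the six-way architecture code from domain presence.

    Multiple hits of one domain collapse to presence/absence.  A gene
    without an NBS domain is not NBS-encoding and raises
    :class:`NotNbsEncoding` rather than receiving a code.
    """
    labels = {h.domain if isinstance(h, DomainHit) else h for h in hits}
    unknown = labels - set(NBS_DOMAIN_LABELS)
    if unknown:
        raise ValueError(f"unknown domain label(s): {sorted(unknown)}")
    if "NBS" not in labels:
        raise NotNbsEncoding("gene lacks the NBS (NB-ARC) domain")
    lrr = "LRR" in labels
    if "TIR" in labels:
        code = "TNL" if lrr else "TN"
    elif "CC" in labels:
        code = "CNL" if lrr else "CN"
    else:
        code = "XNL" if lrr else "XN"
    return ArchitectureClass(code=code, rnl_flag="RPW8" in labels)


@dataclass
class ClassCensus:
    """Survey-style census: per-code counts, aggregates, genome proportions
    (percent, displayed at 2 decimals) and mean exon counts per aggregate."""

    counts: dict[str, int]
    genome_gene_total: int
    rnl_count: int
    total_nbs: int
    nbs_lrr: int
    nbs_only: int
    tir: int
    non_tir: int
    proportions_pct: dict[str, float]
    mean_exons: dict[str, float]

    def formatted_proportion(self, key: str) -> str:
        return f"{round_half_up(self.proportions_pct[key], 2):.2f}%"


_AGGREGATES: Mapping[str, tuple[str, ...]] = {
    "NBS-encoding": CLASS_CODES,
    "NBS-LRR": ("TNL", "CNL", "XNL"),
    "NBS-only": ("TN", "CN", "XN"),
    "TNL": ("TNL",),
    "non-TNL": ("CNL", "XNL"),
    "CNL": ("CNL",),
    "TIR": ("TNL", "TN"),
    "non-TIR": ("CNL", "CN", "XNL", "XN"),
}


def census(genes: Sequence[GeneRecord], genome_gene_total: int) -> ClassCensus:
    """Census of classified NBS-encoding genes against a genome-wide total.

    The denominator (number of genes in the whole genome) is an explicit
    argument; percentages are reported on that basis.
    """
    if genome_gene_total <= 0:
        raise ValueError("genome_gene_total must be positive")
    if genome_gene_total < len(genes):
        raise ValueError("genome_gene_total smaller than the classified gene set")
    counts: Counter[str] = Counter()
    rnl = 0
    exons_by_code: dict[str, list[int]] = {c: [] for c in CLASS_CODES}
    for g in genes:
        cls = classify_gene(g.domain_labels)
        counts[cls.code] += 1
        rnl += cls.rnl_flag
        exons_by_code[cls.code].append(g.exon_count)
    counts_full = {c: counts.get(c, 0) for c in CLASS_CODES}
    agg_counts = {name: sum(counts_full[c] for c in codes)
                  for name, codes in _AGGREGATES.items()}
    proportions = {name: 100.0 * n / genome_gene_total for name, n in agg_counts.items()}
    mean_exons = {}
    for name, codes in _AGGREGATES.items():
        values = [e for c in codes for e in exons_by_code[c]]
        mean_exons[name] = sum(values) / len(values) if values else 0.0
    return ClassCensus(
        counts=counts_full,
        genome_gene_total=genome_gene_total,
        rnl_count=rnl,
        total_nbs=agg_counts["NBS-encoding"],
        nbs_lrr=agg_counts["NBS-LRR"],
        nbs_only=agg_counts["NBS-only"],
        tir=agg_counts["TIR"],
        non_tir=agg_counts["non-TIR"],
        proportions_pct=proportions,
        mean_exons=mean_exons,
    )


def exon_stats(exon_counts: Mapping[str, int], subset: Iterable[str]) -> float:
    """Arithmetic mean exon count over a gene subset.

    ``exon_counts`` maps gene id -> exon count (as parsed from GFF3).
    Missing genes raise a keyed error listing all absentees.
    """
    subset = list(subset)
    missing = [g for g in subset if g not in exon_counts]
    if missing:
        raise KeyError(f"genes absent from gene models: {sorted(missing)}")
    if not subset:
        raise ValueError("empty gene subset")
    return sum(exon_counts[g] for g in subset) / len(subset)
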