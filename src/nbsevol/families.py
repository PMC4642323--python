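"""Gene-family construction from pairwise alignment coverage/identity.

Two genes are joined when both the coverage (aligned length over the longer
gene's length) and the identity of their global protein alignment reach the
threshold (0.70, 0.80 or 0.90 in the standard analysis); families are the
connected components of that graph with at least two members (single
linkage), everything else is a singleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .align import AlignmentPair, pairwise_metrics
from .report import mean_per_group, percentage


@dataclass
class GeneFamilySet:
    """Partition of the input genes at one coverage/identity threshold."""

    threshold: float
    families: list[frozenset[str]]          # disjoint sets of size >= 2
    singletons: frozenset[str]
    pairs: list[AlignmentPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(len(f) < 2 for f in self.families):
            raise ValueError("families must have >= 2 members")

    @property
    def multi_gene_ids(self) -> frozenset[str]:
        return frozenset(g for fam in self.families for g in fam)

    @property
    def n_multi(self) -> int:
        return sum(len(f) for f in self.families)

    def family_of(self, gene_id: str) -> frozenset[str] | None:
        for fam in self.families:
            if gene_id in fam:
                return fam
        return None

    def sorted_families(self) -> list[frozenset[str]]:
        """Deterministic order: by size descending, then smallest member id."""
        return sorted(self.families, key=lambda f: (-len(f), min(f)))


def all_pairwise_metrics(genes: Mapping[str, str]) -> list[AlignmentPair]:
    """Global-alignment metrics for every unordered gene pair."""
    ids = sorted(genes)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            out.append(pairwise_metrics(genes[a], genes[b], id_a=a, id_b=b))
    return out


def build_families(genes: Mapping[str, str], threshold: float,
                   pairs: Sequence[AlignmentPair] | None = None) -> GeneFamilySet:
    """Single-linkage families at a coverage AND identity threshold.

    ``genes`` maps gene id -> protein sequence.  Precomputed pairwise metrics
    can be passed to reuse one all-vs-all alignment across thresholds.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if pairs is None:
        pairs = all_pairwise_metrics(genes)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for p in pairs:
        if p.coverage >= threshold and p.identity >= threshold:
            graph.add_edge(p.gene_a, p.gene_b)
    families, singles = [], []
    for comp in nx.connected_components(graph):
        (families if len(comp) > 1 else singles).append(comp)
    return GeneFamilySet(
        threshold=threshold,
        families=[frozenset(c) for c in families],
        singletons=frozenset(g for c in singles for g in c),
        pairs=list(pairs),
    )


@dataclass
class FamilyCensus:
    """Family-partition statistics: overall and restricted to TIR / non-TIR."""

    threshold: float
    multi: int
    single: int
    proportion_multi_pct: float
    n_families: int
    mean_members: float
    max_members: int
    tir_multi: int
    tir_families: int
    tir_total: int
    proportion_tir_multi_pct: float
    non_tir_multi: int
    non_tir_families: int
    non_tir_total: int
    proportion_non_tir_multi_pct: float


def family_census(fs: GeneFamilySet, tir_flags: Mapping[str, bool]) -> FamilyCensus:
    """Summarize a family partition; ``tir_flags`` maps every gene id to
    whether it is TIR-type (TNL/TN)."""
    all_genes = set(fs.multi_gene_ids) | set(fs.singletons)
    missing = all_genes - set(tir_flags)
    if missing:
        raise KeyError(f"TIR flags missing for: {sorted(missing)}")
    multi = fs.n_multi
    single = len(fs.singletons)
    sizes = [len(f) for f in fs.families]

    def _subset(flag: bool) -> tuple[int, int, int]:
        members = sum(1 for f in fs.families for g in f if tir_flags[g] == flag)
        # a family counts toward a subset if it contains >= 2 genes of it
        fams = sum(1 for f in fs.families
                   if sum(1 for g in f if tir_flags[g] == flag) >= 2)
        total = sum(1 for g in all_genes if tir_flags[g] == flag)
        return members, fams, total

    tir_multi, tir_fams, tir_total = _subset(True)
    nt_multi, nt_fams, nt_total = _subset(False)
    return FamilyCensus(
        threshold=fs.threshold,
        multi=multi,
        single=single,
        proportion_multi_pct=percentage(multi, multi + single),
        n_families=len(fs.families),
        mean_members=mean_per_group(multi, len(fs.families)),
        max_members=max(sizes) if sizes else 0,
        tir_multi=tir_multi,
        tir_families=tir_fams,
        tir_total=tir_total,
        proportion_tir_multi_pct=percentage(tir_multi, tir_total),
        non_tir_multi=nt_multi,
        non_tir_families=nt_fams,
        non_tir_total=nt_total,
        proportion_non_tir_multi_pct=percentage(nt_multi, nt_total),
    )
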