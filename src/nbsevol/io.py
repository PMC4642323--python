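"""File formats used across the pipeline: FASTA (via Biopython), a compact
GFF3 gene-model reader/writer covering gene/mRNA/exon/CDS features, the
domain-annotation and species-map TSVs, and the ground-truth manifest JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domains import DomainHit


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: sequence}, preserving file order (dict is ordered)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, sequences: Mapping[str, str], width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    # Biopython wraps at 60 by default; width kept for interface clarity
    assert width == 60


@dataclass
class GeneModel:
    """One gene as read from GFF3 (1-based inclusive coordinates)."""

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str
    mrnas: dict[str, dict] = field(default_factory=dict)  # mrna_id -> {exons, cds}

    def exon_count(self) -> int:
        """Exon count of the canonical mRNA (the one with the longest summed
        CDS; ties broken on mRNA id)."""
        if not self.mrnas:
            return 1
        def cds_len(m):  # noqa: E306
            return sum(e - s + 1 for s, e in m["cds"])
        canonical = max(sorted(self.mrnas), key=lambda mid: cds_len(self.mrnas[mid]))
        n = len(self.mrnas[canonical]["exons"])
        return n if n else 1


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> dict[str, GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModel objects."""
    genes: dict[str, GeneModel] = {}
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            attrs = _gff_attributes(attrs)
            if ftype == "gene":
                gid = attrs["ID"]
                genes[gid] = GeneModel(gene_id=gid, seqid=seqid, start=int(start),
                                       end=int(end), strand=strand)
            elif ftype == "mRNA":
                mid, parent = attrs["ID"], attrs["Parent"]
                mrna_parent[mid] = parent
                genes[parent].mrnas[mid] = {"exons": [], "cds": []}
            elif ftype in ("exon", "CDS"):
                parent = attrs["Parent"]
                gid = mrna_parent[parent]
                key = "exons" if ftype == "exon" else "cds"
                genes[gid].mrnas[parent][key].append((int(start), int(end)))
    return genes


def write_gff3(path, genes: Iterable[GeneModel]) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append("\t".join([g.seqid, "nbsevol", "gene", str(g.start), str(g.end),
                                ".", g.strand, ".", f"ID={g.gene_id}"]))
        for mid, m in g.mrnas.items():
            lines.append("\t".join([g.seqid, "nbsevol", "mRNA", str(g.start),
                                    str(g.end), ".", g.strand, ".",
                                    f"ID={mid};Parent={g.gene_id}"]))
            for i, (s, e) in enumerate(m["exons"], 1):
                lines.append("\t".join([g.seqid, "nbsevol", "exon", str(s), str(e),
                                        ".", g.strand, ".",
                                        f"ID={mid}.exon{i};Parent={mid}"]))
            for i, (s, e) in enumerate(m["cds"], 1):
                lines.append("\t".join([g.seqid, "nbsevol", "CDS", str(s), str(e),
                                        ".", g.strand, "0",
                                        f"ID={mid}.cds{i};Parent={mid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_tsv(path) -> dict[str, list[DomainHit]]:
    """Domain table: ``gene_id<TAB>domain<TAB>start<TAB>end`` (header allowed)."""
    hits: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene_id\t"):
                continue
            gene_id, domain, start, end = line.split("\t")[:4]
            hits.setdefault(gene_id, []).append(
                DomainHit(gene_id=gene_id, domain=domain, start=int(start), end=int(end)))
    return hits


def write_domain_tsv(path, hits: Iterable[DomainHit]) -> None:
    lines = ["gene_id\tdomain\tstart\tend"]
    for h in hits:
        lines.append(f"{h.gene_id}\t{h.domain}\t{h.start}\t{h.end}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_species_map(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene_id\t"):
                continue
            gene_id, species = line.split("\t")[:2]
            out[gene_id] = species
    return out


def write_species_map(path, species: Mapping[str, str]) -> None:
    lines = ["gene_id\tspecies"]
    lines += [f"{g}\t{s}" for g, s in species.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_tsv(path, header: list[str], rows: Iterable[Iterable]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")
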