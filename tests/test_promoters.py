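"""Promoter extraction and IUPAC motif scanning."""

import numpy as np
import pytest

from nbsevol.io import GeneModel
from nbsevol.promoters import (
    Motif,
    PromoterRecord,
    extract_promoters,
    motif_census,
    reverse_complement,
    scan,
)

from oracles import naive_scan


def hits_of(seq, pattern, name="m"):
    return scan([PromoterRecord(gene_id="g", sequence=seq)],
                [Motif(name=name, pattern=pattern)])


def test_forward_and_reverse_hits_of_worked_example():
    hits = hits_of("AAAGCTTT", "AAAG")
    assert [(h.strand, h.start) for h in hits] == [("+", 1), ("-", 5)]


def test_degenerate_code_semantics():
    assert len(hits_of("TAAAG", "WAAAG")) >= 1      # W = A/T
    assert hits_of("GAAAG", "WAAAG") == []
    # promoter N matches only motif N
    assert hits_of("ANAG", "AAAG") == []
    assert len(hits_of("ANAG", "ANAG")) >= 1


def test_overlapping_occurrences_are_all_reported():
    hits = [h for h in hits_of("AAAAA", "AA") if h.strand == "+"]
    assert [h.start for h in hits] == [1, 2, 3, 4]


def test_palindrome_counts_once_per_strand():
    hits = hits_of("GGTACCG", "GTAC")
    assert {(h.strand, h.start) for h in hits} == {("+", 2), ("-", 2)}


def test_invalid_codes_rejected():
    with pytest.raises(ValueError):
        Motif(name="bad", pattern="AXG")
    with pytest.raises(ValueError):
        scan([PromoterRecord(gene_id="g", sequence="AUGC")],
             [Motif(name="m", pattern="A")])


def test_scan_matches_naive_sliding_window_oracle():
    rng = np.random.default_rng(0)
    motifs = [Motif("m1", "AAAG"), Motif("m2", "WAAAG"), Motif("m3", "CANNTG"),
              Motif("m4", "TGAC"), Motif("m5", "RYCGAC")]
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        hits = scan([PromoterRecord(gene_id="g", sequence=seq)], motifs)
        for m in motifs:
            fwd, rev = naive_scan(seq, m.pattern)
            assert [h.start for h in hits if h.motif == m.name and h.strand == "+"] == fwd
            assert [h.start for h in hits if h.motif == m.name and h.strand == "-"] == rev


def test_strand_symmetry_of_counts():
    rng = np.random.default_rng(1)
    motifs = [Motif("m", "GRWAAW")]
    seq = "".join(rng.choice(list("ACGT"), size=500))
    fwd1 = [h for h in scan([("g", seq)], motifs) if h.strand == "+"]
    rev1 = [h for h in scan([("g", seq)], motifs) if h.strand == "-"]
    flipped = reverse_complement(seq)
    fwd2 = [h for h in scan([("g", flipped)], motifs) if h.strand == "+"]
    rev2 = [h for h in scan([("g", flipped)], motifs) if h.strand == "-"]
    assert len(fwd1) == len(rev2) and len(rev1) == len(fwd2)


def _model(gid, seqid, start, end, strand):
    return GeneModel(gene_id=gid, seqid=seqid, start=start, end=end, strand=strand)


def test_promoter_extraction_coordinates_and_strands():
    contig = "ACGTACGTACGTACGTACGT"  # 20 bp
    genome = {"c1": contig}
    plus = _model("gp", "c1", 11, 20, "+")
    recs = extract_promoters(genome, [plus], length=10)
    assert recs[0].sequence == contig[:10] and not recs[0].truncated
    minus = _model("gm", "c1", 1, 10, "-")
    recs = extract_promoters(genome, [minus], length=10)
    assert recs[0].sequence == reverse_complement(contig[10:20])


def test_truncated_promoter_is_flagged():
    genome = {"c1": "A" * 250}
    rec = extract_promoters(genome, [_model("g", "c1", 200, 250, "+")], length=1000)[0]
    assert rec.truncated and len(rec.sequence) == 199


def test_missing_contig_is_keyed_error():
    with pytest.raises(KeyError, match="g1"):
        extract_promoters({}, [_model("g1", "nope", 5, 10, "+")])


def test_census_conservation_and_ordering():
    motifs = [Motif("x", "AAAG"), Motif("y", "TTTT")]
    hits = scan([("g1", "AAAGAAAG"), ("g2", "AAAGCCCC"), ("g3", "CCCCCCCC")], motifs)
    cen = motif_census(hits, ["g1", "g2", "g3"], motifs)
    for m in motifs:
        assert cen.occurrences[m.name] == sum(1 for h in hits if h.motif == m.name)
        assert cen.genes_with_hit[m.name] <= cen.occurrences[m.name]
        assert cen.genes_with_hit[m.name] <= 3
    assert cen.sorted_names()[0] == "x"


def test_planted_motifs_recovered_exactly_from_dataset(dataset):
    outdir, manifest = dataset
    from nbsevol.io import read_fasta
    from nbsevol.simulate import default_motifs
    promoters = read_fasta(outdir / "promoters.fna")
    motifs = [m for m in default_motifs() if m.name == "WRKY71OS"]
    hits = scan(list(promoters.items()), motifs)
    from collections import Counter
    got = Counter(h.gene_id for h in hits if h.strand == "+")
    for gid in promoters:
        want = manifest.promoters[gid]["motif_counts"].get("WRKY71OS", 0)
        assert got.get(gid, 0) == want, gid
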