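"""The synthetic-data generator: determinism, conservation, calibration,
codon-process correctness, and manifest round-trips."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from nbsevol._codon import (
    N_CODONS,
    encode_codons,
    rate_matrix,
    translate_codons,
    uniform_codon_frequencies,
)
from nbsevol.io import read_fasta, read_gff3, read_manifest
from nbsevol.simulate import (
    FamilySpec,
    SimulationConfig,
    calibrate_separation,
    evolve_codon_sequence,
    expected_ng_plugin,
    safe_background_alphabet,
    simulate_dataset,
)
from nbsevol.promoters import Motif

PI = uniform_codon_frequencies()


def test_manifest_counts_conserve_config(tmp_path):
    config = SimulationConfig(
        seed=3, family_specs=(FamilySpec(size=4), FamilySpec(size=3)),
        singleton_count=1, filler_gene_count=0, genome_gene_total=50)
    manifest = simulate_dataset(config, tmp_path)
    nbs = [g for g, info in manifest.genes.items() if info["is_nbs"]]
    assert len(nbs) == 8
    assert len(manifest.families) == 2
    assert sum(1 for g in nbs if manifest.genes[g]["family"] is None) == 1
    # file-level conservation
    assert len(read_fasta(tmp_path / "proteins.faa")) == len(manifest.genes)
    assert len(read_fasta(tmp_path / "cds.fna")) == len(manifest.genes)
    assert len(read_gff3(tmp_path / "genes.gff3")) == len(manifest.genes)


def test_identical_config_and_seed_are_byte_identical(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_dataset(SimulationConfig(seed=9), a)
    simulate_dataset(SimulationConfig(seed=9), b)
    for f in sorted(Path(a).iterdir()):
        assert filecmp.cmp(f, b / f.name, shallow=False), f.name
    c = tmp_path / "c"
    simulate_dataset(SimulationConfig(seed=10), c)
    assert not filecmp.cmp(a / "cds.fna", c / "cds.fna", shallow=False)


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError):
        FamilySpec(size=0)
    with pytest.raises(ValueError):
        FamilySpec(size=2, architecture="QQQ")
    with pytest.raises(ValueError):
        FamilySpec(size=2, topology="ladder")
    with pytest.raises(ValueError):
        SimulationConfig(genome_gene_total=3)
    with pytest.raises(ValueError):
        SimulationConfig(planted_motifs=(("NOPE", 2),))


def test_zero_branch_returns_root_unchanged():
    root = "ATGGCTAAACCTGGG"
    assert evolve_codon_sequence(root, 0.0, 2.0, 0.5) == root


def test_omega_zero_forbids_nonsynonymous_change():
    rng = np.random.default_rng(1)
    root_idx = rng.choice(N_CODONS, size=200, p=PI)
    out = evolve_codon_sequence(root_idx, 3.0, 2.0, 0.0, PI, rng)
    assert translate_codons(encode_codons(out)) == translate_codons(root_idx)
    # synonymous substitutions must still happen on a long branch
    from nbsevol._codon import decode_codons
    assert out != decode_codons(root_idx)


def test_long_branch_converges_to_stationary_distribution():
    rng = np.random.default_rng(2)
    root_idx = np.zeros(30000, dtype=int)  # all one codon: worst case start
    out = evolve_codon_sequence(root_idx, 60.0, 2.0, 0.8, PI, rng)
    freqs = np.bincount(encode_codons(out), minlength=N_CODONS) / 30000
    # multinomial sampling error at n=30000: sd ~ sqrt(p/n) ~ 7e-4 per codon
    assert np.abs(freqs - PI).max() < 0.005


def test_stop_codons_and_negative_branch_rejected():
    with pytest.raises(ValueError):
        evolve_codon_sequence("ATGTAA", 0.1, 2.0, 0.5)
    with pytest.raises(ValueError):
        evolve_codon_sequence("ATG", -0.1, 2.0, 0.5)
    with pytest.raises(ValueError):
        rate_matrix(0.0, 0.5, PI)


def test_calibration_inverts_expected_plugin_ks():
    for ks in (0.1, 0.2, 0.45):
        sep = calibrate_separation(ks, 1.0, 0.3, PI)
        got, _ = expected_ng_plugin(sep, 1.0, 0.3, PI)
        assert got == pytest.approx(ks, abs=1e-8)
    assert calibrate_separation(0.0, 1.0, 0.3, PI) == 0.0


def test_background_alphabet_provably_excludes_motifs():
    alphabet = safe_background_alphabet([Motif("w", "TGAC")])
    assert len(alphabet) == 3
    assert set("TGAC") - set(alphabet)  # at least one required base removed
    # AAAG needs its reverse complement CTTT blocked too
    alphabet = safe_background_alphabet([Motif("d", "AAAG")])
    for pattern in ("AAAG", "CTTT"):
        assert any(base not in alphabet for base in pattern)


def test_manifest_round_trips_through_json(dataset):
    outdir, manifest = dataset
    loaded = read_manifest(outdir / "manifest.json")
    assert loaded["seed"] == manifest.seed
    assert set(loaded["genes"]) == set(manifest.genes)
    assert loaded["genome_gene_total"] == manifest.genome_gene_total


def test_cds_translates_to_protein_and_has_no_stops(dataset):
    outdir, _ = dataset
    proteins = read_fasta(outdir / "proteins.faa")
    cds = read_fasta(outdir / "cds.fna")
    for gid, seq in cds.items():
        assert len(seq) % 3 == 0
        assert translate_codons(encode_codons(seq)) == proteins[gid]


def test_birth_topology_produces_nested_divergences(tmp_path):
    config = SimulationConfig(
        seed=5, family_specs=(FamilySpec(size=6, target_ks=0.4, omega=0.2,
                                         topology="birth"),),
        singleton_count=0, filler_gene_count=0, genome_gene_total=10)
    manifest = simulate_dataset(config, tmp_path)
    from nbsevol.kaks import nei_gojobori
    cds = read_fasta(tmp_path / "cds.fna")
    members = manifest.families["fam01"]["members"]
    ks = [nei_gojobori(cds[a], cds[b]).Ks
          for i, a in enumerate(members) for b in members[i + 1:]]
    # a birth genealogy has young nested pairs and old root-spanning pairs
    assert min(ks) < max(ks)
    assert max(ks) < 0.7  # bounded by the calibrated root separation regime
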