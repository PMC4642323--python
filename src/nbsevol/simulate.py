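"""Seeded synthetic-data generator.

Emits a miniature two-species dataset with the statistical structure the
analysis assumes: multi-member gene families whose coding sequences diverged
under a GY94-style codon process to a target pairwise Ks at a chosen omega,
planted domain architectures (emitted as annotation rows, mirroring how
upstream domain scanners feed the real pipeline), exon structures, and
promoters with planted cis-element occurrences — all recorded in a
ground-truth manifest.

Families evolve on a star tree (tip branch = half the pairwise separation);
the separation is calibrated numerically so the *expected* Nei-Gojobori
estimate between a pair equals ``target_ks``, which makes the generating
parameters a valid oracle for the estimators downstream.  Promoter
backgrounds are drawn from a reduced alphabet that provably cannot contain
a planted motif on either strand (when ``provable_motif_counts`` is set),
so planted counts are exactly recoverable by scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import optimize

from ._codon import (
    N_CODONS,
    decompose_rate_matrix,
    encode_codons,
    decode_codons,
    ng_difference_tables,
    ng_synonymous_sites,
    probabilities_from_decomposition,
    rate_matrix,
    translate_codons,
    uniform_codon_frequencies,
)
from .domains import DomainHit
from .io import (
    GeneModel,
    write_domain_tsv,
    write_fasta,
    write_gff3,
    write_manifest,
    write_species_map,
)
from .kaks import jukes_cantor
from .promoters import IUPAC, Motif, PromoterRecord, reverse_complement, scan

INTRON_LENGTH = 20


def default_motifs() -> list[Motif]:
    """The bundled subset of named PLACE-style cis-element patterns."""
    text = resources.files("nbsevol.data").joinpath("motifs_place_subset.tsv").read_text()
    motifs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, pattern = line.split("\t")[:2]
        motifs.append(Motif(name=name, pattern=pattern))
    return motifs


def parse_architecture(code: str) -> tuple[list[str], bool]:
    """Architecture string -> (domain labels, rnl_flag).

    ``code`` is one of TNL/TN/CNL/CN/XNL/XN, optionally '+RPW8'.
    """
    parts = code.split("+")
    base = parts[0]
    rnl = "RPW8" in parts[1:]
    unknown = [p for p in parts[1:] if p != "RPW8"]
    if unknown:
        raise ValueError(f"unknown architecture suffix {unknown}")
    table = {
        "TNL": ["TIR", "NBS", "LRR"],
        "TN": ["TIR", "NBS"],
        "CNL": ["CC", "NBS", "LRR"],
        "CN": ["CC", "NBS"],
        "XNL": ["NBS", "LRR"],
        "XN": ["NBS"],
    }
    if base not in table:
        raise ValueError(f"unknown architecture code {base!r}")
    domains = list(table[base])
    if rnl:
        domains.append("RPW8")
    return domains, rnl



@dataclass(frozen=True)
class FamilySpec:
    """One simulated gene family."""

    size: int
    architecture: str = "XNL"      # e.g. "TNL", "CN", "XNL+RPW8"
    target_ks: float = 0.3
    omega: float = 0.3
    kappa: float = 1.0
    cds_codons: int = 300
    topology: str = "star"         # "star" | "birth"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("family size must be >= 1")
        if self.target_ks < 0 or self.omega < 0 or self.kappa <= 0:
            raise ValueError("target_ks/omega must be >= 0 and kappa > 0")
        if self.topology not in ("star", "birth"):
            raise ValueError("topology must be 'star' or 'birth'")
        parse_architecture(self.architecture)  # validates


@dataclass
class SimulationConfig:
    seed: int = 0
    species_names: tuple[str, ...] = ("speciesA", "speciesB")
    family_specs: tuple[FamilySpec, ...] = (
        # two ancient purifying families at the Ks-profile main mode, two
        # recent families (one under positive selection), one RPW8-flagged —
        # omegas keep within-family protein identity above the 70% family
        # criterion, as the family definition itself requires
        FamilySpec(size=5, architecture="XNL", target_ks=0.45, omega=0.2),
        FamilySpec(size=4, architecture="CNL", target_ks=0.45, omega=0.2),
        FamilySpec(size=4, architecture="TNL", target_ks=0.15, omega=0.3),
        FamilySpec(size=3, architecture="CN", target_ks=0.10, omega=1.5),
        FamilySpec(size=3, architecture="XNL+RPW8", target_ks=0.15, omega=0.2),
    )
    singleton_count: int = 6
    singleton_cds_codons: int = 300
    promoter_length: int = 1000
    planted_motifs: tuple[tuple[str, int], ...] = (("WRKY71OS", 3),)
    motifs: tuple[Motif, ...] = ()          # defaults to the bundled subset
    provable_motif_counts: bool = True
    filler_gene_count: int = 4              # non-NBS genes emitted to files
    genome_gene_total: int = 400            # census denominator
    exon_count_range: tuple[int, int] = (1, 6)

    def __post_init__(self) -> None:
        if not self.motifs:
            self.motifs = tuple(default_motifs())
        if len(self.species_names) < 1:
            raise ValueError("at least one species label required")
        n_nbs = sum(f.size for f in self.family_specs) + self.singleton_count
        if n_nbs + self.filler_gene_count > self.genome_gene_total:
            raise ValueError("genome_gene_total smaller than emitted gene count")
        names = {m.name for m in self.motifs}
        missing = [n for n, _ in self.planted_motifs if n not in names]
        if missing:
            raise ValueError(f"planted motifs without patterns: {missing}")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be >= 1")


def domain_cassette(gene_id: str, architecture: str, protein_length: int) -> list[DomainHit]:
    """Annotation rows implementing an architecture on a protein of given length."""
    labels, _ = parse_architecture(architecture)
    n_end = max(2, protein_length // 5)
    hits = []
    for label in labels:
        if label in ("TIR", "CC"):
            hits.append(DomainHit(gene_id, label, 1, n_end))
        elif label == "RPW8":
            hits.append(DomainHit(gene_id, label, 1, max(2, n_end // 2)))
        elif label == "NBS":
            hits.append(DomainHit(gene_id, "NBS", n_end + 1,
                                  min(protein_length, n_end + max(2, protein_length // 3))))
        elif label == "LRR":
            start = max(1, protein_length - max(2, protein_length // 4))
            hits.append(DomainHit(gene_id, "LRR", start, protein_length))
    return hits


# --- codon evolution ---------------------------------------------------------

def evolve_codon_sequence(root: str | np.ndarray, branch_length: float,
                          kappa: float, omega: float,
                          pi: np.ndarray | None = None,
                          rng: np.random.Generator | int | None = None) -> str:
    """Evolve a codon sequence along one branch of the GY94-style process.

    ``branch_length`` is in expected substitutions per codon site (matrix
    normalized to rate 1); sites evolve independently via the matrix
    exponential of the generator.  branch_length 0 returns the root
    unchanged.  The root must be free of stop codons.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    idx = encode_codons(root) if isinstance(root, str) else np.asarray(root)
    if branch_length == 0:
        return decode_codons(idx)
    if pi is None:
        pi = uniform_codon_frequencies()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    q = rate_matrix(kappa, omega, pi)
    p = probabilities_from_decomposition(*decompose_rate_matrix(q, pi), branch_length)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(idx))
    new = np.array([np.searchsorted(cum[i], x, side="right") for i, x in zip(idx, u)])
    new = np.minimum(new, N_CODONS - 1)
    return decode_codons(new)


def expected_ng_plugin(separation: float, kappa: float, omega: float,
                       pi: np.ndarray | None = None) -> tuple[float, float]:
    """Expected Nei-Gojobori (Ks, Ka) for a pair at a given separation.

    Plug-in expectation under the stationary joint codon distribution
    pi_i * P(t)_ij, with the NG site/difference tables; this is what the
    estimator converges to as the number of codons grows.
    """
    if pi is None:
        pi = uniform_codon_frequencies()
    q = rate_matrix(kappa, omega, pi)
    p = probabilities_from_decomposition(*decompose_rate_matrix(q, pi), separation)
    joint = pi[:, None] * p
    sd_table, nd_table = ng_difference_tables()
    syn_sites = ng_synonymous_sites()
    e_sd = float((joint * sd_table).sum())
    e_nd = float((joint * nd_table).sum())
    s_bar = float((pi * syn_sites).sum())
    from .kaks import SaturatedDistance
    try:
        ks = jukes_cantor(e_sd / s_bar)
    except SaturatedDistance:
        ks = float("inf")
    try:
        ka = jukes_cantor(e_nd / (3.0 - s_bar))
    except SaturatedDistance:
        ka = float("inf")
    return ks, ka


def calibrate_separation(target_ks: float, kappa: float, omega: float,
                         pi: np.ndarray | None = None) -> float:
    """Pairwise separation t (subs/codon site) whose expected NG Ks equals
    target_ks."""
    if target_ks == 0:
        return 0.0

    def f(t: float) -> float:
        return expected_ng_plugin(t, kappa, omega, pi)[0] - target_ks

    return float(optimize.brentq(f, 1e-9, 30.0, xtol=1e-10))


def _evolve_indices(idx: np.ndarray, t: float, decomp, rng: np.random.Generator
                    ) -> np.ndarray:
    """Evolve codon indices along one branch given a rate-matrix decomposition."""
    if t <= 0:
        return idx.copy()
    p = probabilities_from_decomposition(*decomp, t)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(idx))
    out = np.array([np.searchsorted(cum[c], x, side="right")
                    for c, x in zip(idx, u)])
    return np.minimum(out, N_CODONS - 1)


def _birth_tips(node_idx: np.ndarray, height: float, n: int, decomp,
                rng: np.random.Generator) -> list[np.ndarray]:
    """Tips of a random ultrametric birth genealogy rooted ``height`` above
    the present; the deepest pairwise separation is 2*height (the calibrated
    target), nested pairs are younger."""
    if n == 1:
        return [_evolve_indices(node_idx, height, decomp, rng)]
    k = int(rng.integers(1, n))
    tips: list[np.ndarray] = []
    for size in (k, n - k):
        if size == 1:
            tips.append(_evolve_indices(node_idx, height, decomp, rng))
        else:
            child_h = height * float(rng.uniform(0.25, 0.75))
            child = _evolve_indices(node_idx, height - child_h, decomp, rng)
            tips.extend(_birth_tips(child, child_h, size, decomp, rng))
    return tips


# --- promoter construction ---------------------------------------------------

def safe_background_alphabet(motifs: list[Motif]) -> tuple[str, ...]:
    """Largest nucleotide subset on which none of ``motifs`` can occur on
    either strand (a motif matches within alphabet B iff every position's
    IUPAC set intersects B)."""

    def blocked(pattern: str, alphabet: set[str]) -> bool:
        return any(not (set(IUPAC[c]) & alphabet) for c in pattern.upper())

    from itertools import combinations
    for size in (3, 2, 1):
        for combo in combinations("ACGT", size):
            alphabet = set(combo)
            if all(blocked(m.pattern, alphabet) and
                   blocked(reverse_complement(m.pattern), alphabet)
                   for m in motifs):
                return combo
    raise ValueError("no background alphabet can exclude all planted motifs")


def _concrete_instance(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern.upper())


def _build_promoter(length: int, planted: list[tuple[Motif, int]],
                    alphabet: tuple[str, ...], rng: np.random.Generator,
                    max_tries: int = 50) -> tuple[str, dict[str, list[int]]]:
    """Background + planted motif instances at non-overlapping positions,
    verified by scanning so recorded counts are exactly recoverable."""
    motif_objs = [m for m, _ in planted]
    want = {m.name: k for m, k in planted}
    for _ in range(max_tries):
        seq = list(rng.choice(alphabet, size=length)) if alphabet else \
            list(rng.choice(list("ACGT"), size=length))
        positions: dict[str, list[int]] = {m.name: [] for m, _ in planted}
        occupied: list[tuple[int, int]] = []
        ok = True
        for motif, count in planted:
            w = len(motif)
            for _k in range(count):
                placed = False
                for _try in range(200):
                    pos = int(rng.integers(0, length - w + 1))
                    if all(pos + w <= s or pos >= e for s, e in occupied):
                        occupied.append((pos, pos + w))
                        positions[motif.name].append(pos + 1)
                        instance = _concrete_instance(motif.pattern, rng)
                        seq[pos:pos + w] = list(instance)
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        text = "".join(seq)
        hits = scan([PromoterRecord(gene_id="_", sequence=text)], motif_objs)
        got = {m.name: 0 for m in motif_objs}
        for h in hits:
            if h.strand == "+":
                got[h.motif] += 1
        strand_minus = any(h.strand == "-" for h in hits)
        if got == want and not strand_minus:
            return text, {k: sorted(v) for k, v in positions.items()}
    raise RuntimeError("could not build a promoter with exact planted counts")


# --- dataset assembly --------------------------------------------------------

@dataclass
class TruthManifest:
    seed: int
    species_names: tuple[str, ...]
    genome_gene_total: int
    genes: dict = field(default_factory=dict)
    families: dict = field(default_factory=dict)
    promoters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "species_names": list(self.species_names),
            "genome_gene_total": self.genome_gene_total,
            "genes": self.genes,
            "families": self.families,
            "promoters": self.promoters,
        }


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> TruthManifest:
    """Write the synthetic dataset to ``outdir`` and return its manifest.

    Files: proteins.faa, cds.fna, genome.fna, genes.gff3, promoters.fna,
    domains.tsv, species.tsv, manifest.json.  Identical (config, seed)
    produce byte-identical output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pi = uniform_codon_frequencies()
    motif_by_name = {m.name: m for m in config.motifs}
    planted = [(motif_by_name[n], k) for n, k in config.planted_motifs]
    if config.provable_motif_counts and planted:
        alphabet = safe_background_alphabet([m for m, _ in planted])
    else:
        alphabet = tuple("ACGT")

    manifest = TruthManifest(seed=config.seed, species_names=config.species_names,
                             genome_gene_total=config.genome_gene_total)
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    promoter_seqs: dict[str, str] = {}
    species_map: dict[str, str] = {}
    domain_rows: list[DomainHit] = []
    gene_models: list[GeneModel] = []
    genome: dict[str, str] = {}
    focal = config.species_names[0]

    def emit_gene(gene_id: str, species: str, codon_idx: np.ndarray,
                  architecture: str | None, family_id: str | None,
                  plant_motifs: bool) -> None:
        seq_cds = decode_codons(codon_idx)
        protein = translate_codons(codon_idx)
        proteins[gene_id] = protein
        cds[gene_id] = seq_cds
        species_map[gene_id] = species
        exon_count = int(rng.integers(config.exon_count_range[0],
                                      config.exon_count_range[1] + 1))
        if plant_motifs and planted:
            promoter, positions = _build_promoter(config.promoter_length, planted,
                                                  alphabet, rng)
        else:
            promoter = "".join(rng.choice(alphabet, size=config.promoter_length))
            positions = {}
        promoter_seqs[gene_id] = promoter
        rnl = False
        if architecture is not None:
            hits = domain_cassette(gene_id, architecture, len(protein))
            domain_rows.extend(hits)
            _, rnl = parse_architecture(architecture)
        strand = "+" if rng.random() < 0.5 else "-"
        model, contig_name, contig_seq = _layout_contig(
            gene_id, promoter, seq_cds, exon_count, strand, rng)
        gene_models.append(model)
        genome[contig_name] = contig_seq
        manifest.genes[gene_id] = {
            "species": species,
            "architecture": architecture,
            "rnl": rnl,
            "family": family_id,
            "exon_count": exon_count,
            "is_nbs": architecture is not None,
            "strand": strand,
        }
        manifest.promoters[gene_id] = {
            "motif_counts": {n: len(p) for n, p in positions.items()},
            "positions": positions,
        }

    def _layout_contig(gene_id, promoter, seq_cds, exon_count, strand, rng):
        pieces = _split_exons(len(seq_cds), exon_count, rng)
        introns = ["".join(rng.choice(alphabet, size=INTRON_LENGTH))
                   for _ in range(exon_count - 1)]
        gene_seq = []
        exon_coords = []
        cursor = len(promoter) + 1
        offset = 0
        for i, w in enumerate(pieces):
            exon_coords.append((cursor, cursor + w - 1))
            gene_seq.append(seq_cds[offset:offset + w])
            offset += w
            cursor += w
            if i < exon_count - 1:
                gene_seq.append(introns[i])
                cursor += INTRON_LENGTH
        contig_f = promoter + "".join(gene_seq)
        gene_start, gene_end = len(promoter) + 1, len(contig_f)
        contig_name = f"contig_{gene_id}"
        if strand == "+":
            contig = contig_f
            coords = exon_coords
            start, end = gene_start, gene_end
        else:
            contig = reverse_complement(contig_f)
            L = len(contig_f)
            coords = [(L - e + 1, L - s + 1) for s, e in reversed(exon_coords)]
            start, end = L - gene_end + 1, L - gene_start + 1
        model = GeneModel(gene_id=gene_id, seqid=contig_name, start=start, end=end,
                          strand=strand)
        mid = f"{gene_id}.m1"
        model.mrnas[mid] = {"exons": coords, "cds": list(coords)}
        return model, contig_name, contig

    # families
    for fi, spec in enumerate(config.family_specs, 1):
        family_id = f"fam{fi:02d}"
        root = rng.choice(N_CODONS, size=spec.cds_codons, p=pi)
        separation = calibrate_separation(spec.target_ks, spec.kappa, spec.omega, pi)
        q = rate_matrix(spec.kappa, spec.omega, pi)
        decomp = decompose_rate_matrix(q, pi)
        if spec.topology == "star":
            tips = [_evolve_indices(root, separation / 2.0, decomp, rng)
                    for _ in range(spec.size)]
        else:
            tips = _birth_tips(root, separation / 2.0, spec.size, decomp, rng)
        members = []
        for mi, idx in enumerate(tips, 1):
            gene_id = f"{family_id}g{mi}"
            emit_gene(gene_id, focal, idx, spec.architecture, family_id, True)
            members.append(gene_id)
        manifest.families[family_id] = {
            "members": members,
            "target_ks": spec.target_ks,
            "omega": spec.omega,
            "kappa": spec.kappa,
            "architecture": spec.architecture,
            "species": focal,
            "topology": spec.topology,
            "tip_branch_length": separation / 2.0,
        }

    # singletons, alternating species so the tree carries both labels
    arch_cycle = ["XNL", "CN", "TN", "XN", "CNL", "TNL"]
    for si in range(1, config.singleton_count + 1):
        gene_id = f"sing{si:02d}"
        species = config.species_names[(si - 1) % len(config.species_names)]
        idx = rng.choice(N_CODONS, size=config.singleton_cds_codons, p=pi)
        emit_gene(gene_id, species, idx, arch_cycle[(si - 1) % len(arch_cycle)],
                  None, True)

    # filler (non-NBS) genes
    for gi in range(1, config.filler_gene_count + 1):
        gene_id = f"fill{gi:02d}"
        idx = rng.choice(N_CODONS, size=60, p=pi)
        emit_gene(gene_id, focal, idx, None, None, False)

    write_fasta(outdir / "proteins.faa", proteins)
    write_fasta(outdir / "cds.fna", cds)
    write_fasta(outdir / "promoters.fna", promoter_seqs)
    write_fasta(outdir / "genome.fna", genome)
    write_gff3(outdir / "genes.gff3", gene_models)
    write_domain_tsv(outdir / "domains.tsv", domain_rows)
    write_species_map(outdir / "species.tsv", species_map)
    write_manifest(outdir / "manifest.json", manifest.as_dict())
    return manifest


def _split_exons(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` bases into ``parts`` contiguous nonzero pieces."""
    if parts == 1:
        return [total]
    cuts = sorted(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    edges = [0, *cuts, total]
    return [edges[i + 1] - edges[i] for i in range(parts)]
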