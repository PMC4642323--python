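"""End-to-end orchestration of the analysis stages over one input dataset.

Stages: classify -> families (three thresholds) -> Ka/Ks + Ks profile ->
NBS-domain NJ tree with bootstrap + species-specific clades + RPW8
monophyly -> M7/M8 positive-selection tests -> promoter cis-element census
-> Markdown report.  Every stage writes plain TSVs so the report numbers
are recomputable from the stage outputs alone; all randomness flows from
one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import align, domains, families, io, kaks, phylo, promoters, selection
from .report import format_mean, format_percentage
from .simulate import default_motifs

DEFAULT_THRESHOLDS = (0.70, 0.80, 0.90)


@dataclass
class PipelineConfig:
    """Validated stage configuration, serialized alongside outputs."""

    proteins: Path
    cds: Path
    gff: Path
    genome: Path
    domain_table: Path
    species_map: Path
    outdir: Path
    motif_file: Path | None = None
    genome_gene_total: int = 400
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    family_threshold: float = 0.70        # threshold used for Ka/Ks + selection
    promoter_length: int = 1000
    bootstrap_replicates: int = 1000
    support_threshold: float = 50.0
    distance_model: str = "poisson"
    focal_species: str | None = None
    seed: int = 0
    selection_restarts: int = 2
    max_selection_families: int | None = None
    run_selection: bool = True

    def validate(self) -> None:
        for name in ("proteins", "cds", "gff", "genome", "domain_table", "species_map"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} input missing: {p}")
        if self.genome_gene_total <= 0:
            raise ValueError("genome_gene_total must be positive")


@dataclass
class PipelineResult:
    census: domains.ClassCensus
    family_sets: dict[float, families.GeneFamilySet]
    family_censuses: dict[float, families.FamilyCensus]
    family_kaks: list[kaks.FamilyKaKs]
    profile: kaks.KsProfile | None
    tree: phylo.PhyloTree | None
    clade_report: phylo.SpeciesCladeReport | None
    rnl_monophyly: tuple[bool, float | None] | None
    selection_rows: list[dict]
    motif_census: promoters.MotifCensus
    outdir: Path
    genes: dict[str, domains.GeneRecord] = field(default_factory=dict)


def load_genes(config: PipelineConfig) -> tuple[dict[str, domains.GeneRecord], dict]:
    """Read and cross-validate the inputs; returns (gene records, gene models)."""
    proteins = io.read_fasta(config.proteins)
    cds = io.read_fasta(config.cds)
    gff = io.read_gff3(config.gff)
    domain_hits = io.read_domain_tsv(config.domain_table)
    species = io.read_species_map(config.species_map)
    orphans = {
        "protein without CDS": sorted(set(proteins) - set(cds)),
        "CDS without protein": sorted(set(cds) - set(proteins)),
        "protein without gene model": sorted(set(proteins) - set(gff)),
        "protein without species": sorted(set(proteins) - set(species)),
        "domain row without protein": sorted(set(domain_hits) - set(proteins)),
    }
    problems = {k: v for k, v in orphans.items() if v}
    if problems:
        detail = "; ".join(f"{k}: {', '.join(v)}" for k, v in problems.items())
        raise ValueError(f"inconsistent inputs — {detail}")
    records = {}
    for gid, prot in proteins.items():
        if len(cds[gid]) != 3 * len(prot):
            raise ValueError(f"{gid}: CDS length {len(cds[gid])} != 3 x protein "
                             f"length {len(prot)}")
        records[gid] = domains.GeneRecord(
            gene_id=gid, species=species[gid], protein=prot, cds=cds[gid],
            exon_count=gff[gid].exon_count(),
            domain_hits=domain_hits.get(gid, []))
    return records, gff


def nbs_domain_sequence(record: domains.GeneRecord) -> str | None:
    """The NBS (NB-ARC) domain slice of the protein, used for the phylogeny."""
    for hit in record.domain_hits:
        if hit.domain == "NBS":
            return record.protein[hit.start - 1:hit.end]
    return None


def run_all(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, gff = load_genes(config)
    nbs_records = {g: r for g, r in records.items()
                   if "NBS" in r.domain_labels}

    # --- classification census
    cen = domains.census(list(nbs_records.values()), config.genome_gene_total)
    _write_class_census(outdir / "class_census.tsv", cen)

    # --- families at each threshold (one all-vs-all alignment, reused)
    nbs_proteins = {g: r.protein for g, r in nbs_records.items()}
    pairs = families.all_pairwise_metrics(nbs_proteins) if nbs_proteins else []
    tir = {g: domains.classify_gene(r.domain_labels).is_tir
           for g, r in nbs_records.items()}
    fsets, fcens = {}, {}
    for thr in config.thresholds:
        fs = families.build_families(nbs_proteins, thr, pairs=pairs)
        fsets[thr] = fs
        fcens[thr] = families.family_census(fs, tir)
        io.write_tsv(outdir / f"families_{int(round(thr * 100))}.tsv",
                     ["family_id", "gene_id"],
                     [(f"fam{i:03d}", g)
                      for i, fam in enumerate(fs.sorted_families(), 1)
                      for g in sorted(fam)])
    _write_family_census(outdir / "family_census.tsv", fcens)

    # --- Ka/Ks per family at the working threshold
    base = fsets[config.family_threshold]
    cds_map = {g: r.cds for g, r in nbs_records.items()}
    fam_estimates: list[kaks.FamilyKaKs] = []
    pair_rows = []
    for i, fam in enumerate(base.sorted_families(), 1):
        fam_id = f"fam{i:03d}"
        msa = align.progressive_msa({g: nbs_proteins[g] for g in sorted(fam)})
        codon_aln = kaks.backtranslate_alignment(msa, cds_map)
        est = kaks.family_kaks(fam_id, codon_aln)
        fam_estimates.append(est)
        for ga, gb, e in est.pair_estimates:
            pair_rows.append((ga, gb, f"{e.S:.2f}", f"{e.N:.2f}", f"{e.Sd:.2f}",
                              f"{e.Nd:.2f}", f"{e.Ks:.4f}", f"{e.Ka:.4f}",
                              f"{e.ratio:.4f}" if e.ratio is not None else "NA"))
    io.write_tsv(outdir / "kaks_pairs.tsv",
                 ["gene_a", "gene_b", "S", "N", "Sd", "Nd", "Ks", "Ka", "KaKs"],
                 pair_rows)
    io.write_tsv(outdir / "kaks_families.tsv",
                 ["family", "n_pairs", "Ka", "Ks", "KaKs", "n_saturated"],
                 [(e.family_id, e.n_pairs, f"{e.Ka:.4f}", f"{e.Ks:.4f}",
                   f"{e.ratio:.4f}" if e.ratio is not None else "NA", e.n_saturated)
                  for e in fam_estimates])
    all_pairs = [e for fe in fam_estimates for _, _, e in fe.pair_estimates]
    profile = kaks.ks_profile(all_pairs) if all_pairs else None
    if profile is not None:
        io.write_tsv(outdir / "ks_profile.tsv",
                     ["bin_lo", "bin_hi", "count", "frequency", "mean_KaKs"],
                     [(f"{profile.bin_edges[i]:.1f}", f"{profile.bin_edges[i+1]:.1f}",
                       int(profile.counts[i]), f"{profile.frequencies[i]:.4f}",
                       f"{profile.mean_ratio[i]:.4f}" if np.isfinite(profile.mean_ratio[i]) else "NA")
                      for i in range(len(profile.counts))])

    # --- phylogeny of NBS domains
    tree = clade_report = None
    rnl_mono = None
    nbs_domains = {g: s for g, r in nbs_records.items()
                   if (s := nbs_domain_sequence(r))}
    if len(nbs_domains) >= 4:
        msa = align.progressive_msa(nbs_domains)
        tree = phylo.bootstrap_supports(msa, replicates=config.bootstrap_replicates,
                                        seed=config.seed, model=config.distance_model)
        (outdir / "tree.nwk").write_text(tree.newick() + "\n")
        species = {g: nbs_records[g].species for g in nbs_domains}
        clade_report = phylo.species_specific_clades(
            tree, species, config.support_threshold, config.focal_species)
        io.write_tsv(outdir / "species_clades.tsv",
                     ["clade", "support", "n_genes", "genes"],
                     [(i, f"{c.support:.1f}", len(c.leaves), ",".join(sorted(c.leaves)))
                      for i, c in enumerate(clade_report.clades, 1)])
        rnl_members = [g for g in nbs_domains
                       if domains.classify_gene(nbs_records[g].domain_labels).rnl_flag]
        if len(rnl_members) >= 2:
            rnl_mono = phylo.clade_monophyly(tree, rnl_members)

    # --- positive selection on families with >= 3 members
    selection_rows: list[dict] = []
    if config.run_selection:
        eligible = [fam for fam in base.sorted_families() if len(fam) >= 3]
        if config.max_selection_families is not None:
            eligible = eligible[:config.max_selection_families]
        site_rows = []
        for i, fam in enumerate(eligible, 1):
            fam_id = f"fam{i:03d}"
            members = sorted(fam)
            msa = align.progressive_msa({g: nbs_proteins[g] for g in members})
            codon_aln = kaks.backtranslate_alignment(msa, cds_map)
            ftree = phylo.neighbor_joining(
                phylo.protein_distance({g: msa[g] for g in members},
                                       model=config.distance_model))
            aln = (codon_aln.ids, codon_aln.rows)
            fit0 = selection.fit_model(aln, ftree, "M0", seed=config.seed,
                                       restarts=config.selection_restarts)
            fit7 = selection.fit_model(aln, ftree, "M7", seed=config.seed,
                                       restarts=config.selection_restarts, m0_fit=fit0)
            fit8 = selection.fit_model(
                aln, ftree, "M8", seed=config.seed,
                restarts=config.selection_restarts, m0_fit=fit0,
                init={"p": fit7.params.p, "q": fit7.params.q,
                      "p0": 1.0, "omega_s": 1.0})
            lrt = selection.lrt_m7_m8(fit7, fit8)
            post = selection.positive_sites(fit8)
            selection_rows.append({
                "family": fam_id, "n": len(members),
                "lnL_M0": fit0.lnl, "omega_M0": fit0.params.omega,
                "lnL_M7": fit7.lnl, "lnL_M8": fit8.lnl,
                "two_delta_lnl": lrt.two_delta_lnl,
                "significance": lrt.significance,
                "n_sites_95": sum(1 for f in post.flags if f),
                "n_sites_99": sum(1 for f in post.flags if f == "**"),
            })
            for s, (p, flag) in enumerate(zip(post.prob_positive, post.flags), 1):
                if flag:
                    site_rows.append((fam_id, s, f"{p:.4f}", flag))
        io.write_tsv(outdir / "selection.tsv",
                     ["family", "n", "lnL_M0", "omega_M0", "lnL_M7", "lnL_M8",
                      "two_delta_lnl", "significance", "n_sites_95", "n_sites_99"],
                     [(r["family"], r["n"], f"{r['lnL_M0']:.4f}",
                       f"{r['omega_M0']:.4f}", f"{r['lnL_M7']:.4f}",
                       f"{r['lnL_M8']:.4f}", f"{r['two_delta_lnl']:.4f}",
                       r["significance"], r["n_sites_95"], r["n_sites_99"])
                      for r in selection_rows])
        io.write_tsv(outdir / "positive_sites.tsv",
                     ["family", "site", "prob_positive", "flag"], site_rows)

    # --- promoters
    genome = io.read_fasta(config.genome)
    models = [gff[g] for g in nbs_records]
    promoter_recs = promoters.extract_promoters(genome, models,
                                                length=config.promoter_length)
    io.write_fasta(outdir / "promoters_extracted.fna",
                   {r.gene_id: r.sequence for r in promoter_recs})
    motifs = (promoters.read_motif_file(config.motif_file)
              if config.motif_file else default_motifs())
    hits = promoters.scan(promoter_recs, motifs)
    io.write_tsv(outdir / "motif_hits.tsv", ["gene_id", "motif", "strand", "start"],
                 [(h.gene_id, h.motif, h.strand, h.start) for h in hits])
    mcensus = promoters.motif_census(hits, list(nbs_records), motifs)
    io.write_tsv(outdir / "motif_census.tsv",
                 ["motif", "occurrences", "genes_with_hit"],
                 [(n, mcensus.occurrences[n], mcensus.genes_with_hit[n])
                  for n in mcensus.sorted_names()])

    result = PipelineResult(
        census=cen, family_sets=fsets, family_censuses=fcens,
        family_kaks=fam_estimates, profile=profile, tree=tree,
        clade_report=clade_report, rnl_monophyly=rnl_mono,
        selection_rows=selection_rows, motif_census=mcensus,
        outdir=outdir, genes=records)
    (outdir / "report.md").write_text(render_report(result, config))
    return result


def _write_class_census(path, cen: domains.ClassCensus) -> None:
    rows = [("code:" + c, n) for c, n in cen.counts.items()]
    rows += [("NBS-encoding", cen.total_nbs), ("NBS-LRR", cen.nbs_lrr),
             ("NBS-only", cen.nbs_only), ("TIR", cen.tir), ("non-TIR", cen.non_tir),
             ("RPW8-flagged", cen.rnl_count),
             ("genome_gene_total", cen.genome_gene_total)]
    rows += [(f"proportion:{k}", f"{cen.proportions_pct[k]:.4f}")
             for k in cen.proportions_pct]
    rows += [(f"mean_exons:{k}", f"{cen.mean_exons[k]:.4f}") for k in cen.mean_exons]
    io.write_tsv(path, ["statistic", "value"], rows)


def _write_family_census(path, censuses: dict[float, families.FamilyCensus]) -> None:
    thresholds = sorted(censuses)
    header = ["statistic"] + [f"{int(round(t * 100))}%" for t in thresholds]
    fields = [
        ("Multi-gene", "multi"), ("Single gene", "single"),
        ("Proportion of multiple genes", "proportion_multi_pct"),
        ("Gene Family No.", "n_families"),
        ("Average number of members/family", "mean_members"),
        ("Maximal members of a family", "max_members"),
        ("TIR multiple genes", "tir_multi"),
        ("TIR multi-gene family No.", "tir_families"),
        ("Proportion of TIR multiple genes", "proportion_tir_multi_pct"),
        ("non-TIR multiple genes", "non_tir_multi"),
        ("non-TIR multi-gene family No.", "non_tir_families"),
        ("Proportion of non-TIR multiple genes", "proportion_non_tir_multi_pct"),
    ]
    rows = []
    for label, attr in fields:
        row = [label]
        for t in thresholds:
            v = getattr(censuses[t], attr)
            row.append(f"{v:.2f}%" if attr.endswith("_pct") else
                       f"{v:.2f}" if isinstance(v, float) else v)
        rows.append(row)
    io.write_tsv(path, header, rows)


def render_report(result: PipelineResult, config: PipelineConfig) -> str:
    """Markdown summary mirroring the census-table layouts."""
    cen = result.census
    lines = ["# NBS-encoding gene analysis report", ""]
    lines += ["## Architecture census", "",
              "| class | count |", "|---|---|"]
    for code, n in cen.counts.items():
        lines.append(f"| {code} | {n} |")
    lines += [f"| NBS-encoding total | {cen.total_nbs} |",
              f"| NBS-LRR | {cen.nbs_lrr} |",
              f"| RPW8-flagged | {cen.rnl_count} |",
              f"| Proportion of NBS-encoding genes | "
              f"{format_percentage(cen.total_nbs, cen.genome_gene_total)} |", ""]
    lines += ["## Gene families", "",
              "| statistic | " + " | ".join(f"{int(round(t*100))}%"
                                            for t in sorted(result.family_censuses)) + " |",
              "|---|" + "---|" * len(result.family_censuses)]
    for label, attr in [("Multi-gene", "multi"), ("Single gene", "single"),
                        ("Proportion of multiple genes", "proportion_multi_pct"),
                        ("Gene Family No.", "n_families"),
                        ("Average members/family", "mean_members"),
                        ("Maximal members", "max_members")]:
        cells = []
        for t in sorted(result.family_censuses):
            v = getattr(result.family_censuses[t], attr)
            cells.append(f"{v:.2f}%" if attr.endswith("_pct")
                         else f"{v:.2f}" if isinstance(v, float) else str(v))
        lines.append(f"| {label} | " + " | ".join(cells) + " |")
    lines.append("")
    if result.profile is not None:
        lines += ["## Ks duplication-age profile", "",
                  "| Ks bin | pairs | frequency | mean Ka/Ks |", "|---|---|---|---|"]
        p = result.profile
        for i in range(len(p.counts)):
            mr = f"{p.mean_ratio[i]:.3f}" if np.isfinite(p.mean_ratio[i]) else "-"
            lines.append(f"| [{p.bin_edges[i]:.1f}, {p.bin_edges[i+1]:.1f}) | "
                         f"{int(p.counts[i])} | {p.frequencies[i]:.3f} | {mr} |")
        lines.append(f"\nPairs with Ks >= 1: {p.n_over_one}\n")
    if result.clade_report is not None:
        r = result.clade_report
        lines += ["## Species-specific duplication clades", "",
                  f"- focal species: {r.focal_species}",
                  f"- clades (support > {config.support_threshold:g}%): {r.n_clades}",
                  f"- genes in clades: {r.n_genes}",
                  f"- mean paralogs/clade: {format_mean(r.n_genes, r.n_clades)}",
                  f"- proportion of focal-species genes: "
                  f"{r.proportion_pct:.2f}%", ""]
    if result.rnl_monophyly is not None:
        mono, sup = result.rnl_monophyly
        sup_txt = f"{sup:.1f}%" if sup is not None else "n/a"
        lines += ["## RPW8-flagged gene monophyly", "",
                  f"- monophyletic: {'yes' if mono else 'no'} (support {sup_txt})", ""]
    if result.selection_rows:
        lines += ["## Positive selection (M7 vs M8)", "",
                  "| family | n | omega(M0) | 2dlnL | significance | sites 95%/99% |",
                  "|---|---|---|---|---|---|"]
        for r in result.selection_rows:
            lines.append(f"| {r['family']} | {r['n']} | {r['omega_M0']:.3f} | "
                         f"{r['two_delta_lnl']:.3f} | {r['significance']} | "
                         f"{r['n_sites_95']}/{r['n_sites_99']} |")
        lines.append("")
    lines += ["## Promoter cis-elements", "",
              "| motif | occurrences | genes with hit |", "|---|---|---|"]
    mc = result.motif_census
    for name in mc.sorted_names():
        if mc.occurrences[name] or mc.genes_with_hit[name]:
            lines.append(f"| {name} | {mc.occurrences[name]} | {mc.genes_with_hit[name]} |")
    lines.append("")
    return "\n".join(lines)
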