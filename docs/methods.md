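# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
numerical details a maintainer would need.

## Architecture classification

A gene is NBS-encoding iff its domain table contains an NBS (NB-ARC) hit;
genes without one are signalled, never classified. The six-way code is a
pure function of domain presence: TIR ⇒ TNL/TN (by LRR), else CC ⇒ CNL/CN,
else XNL/XN. Multiple hits of one domain collapse to presence/absence —
coordinates are kept only for reporting (the NBS slice also feeds the
phylogeny stage). RPW8 is an orthogonal boolean rather than a seventh code
because RPW8 co-occurs with both TIR and CC architectures in real surveys;
treating it as a class would break the partition property (every
NBS-encoding gene gets exactly one code).

Exon counts come from GFF3: the number of `exon` features of the gene's
canonical mRNA, defined as the isoform with the longest summed CDS (ties on
mRNA id). Census percentages are displayed at 2 decimals with half-up
rounding; the genome-wide denominator is an explicit argument because
surveys differ in whether they count annotated or expressed genes.

## Gene families

Pairwise metrics come from global Needleman–Wunsch alignment under BLOSUM62
with affine gaps (open −10, extend −0.5; Biopython's C implementation, with
an independent Gotoh DP oracle in the tests). Aligned length counts columns
with residues in both sequences; identity counts identical residue pairs
('X' never identical); coverage divides aligned length by the **longer**
gene's length, which makes the criterion symmetric and conservative — the
weaker convention (shorter gene) would let a short fragment join a family it
barely covers. An edge requires coverage ≥ t AND identity ≥ t; families are
connected components with ≥ 2 members (single linkage), which is the weakest
linkage consistent with "genes grouped by pairwise criteria" and therefore
an upper bound on family size. Both choices are recorded in the output
metadata. Raising t can only delete edges, so families are nested across
70/80/90% — a property the tests check.

## Ka/Ks (Nei–Gojobori 1986 with Jukes–Cantor correction)

Codon alignments are back-translations of protein alignments (residue →
its source codon, gap → `---`), so alignment happens in protein space and
the reading frame is preserved by construction. Columns with a gap in
either row are dropped pairwise.

Site counting: each codon position contributes one site, apportioned by the
fraction of its single-nucleotide changes that are synonymous; changes that
create a stop codon are removed from the possible-change count (so TTA's
middle position, whose only non-stop change is nonsynonymous, contributes
zero synonymous sites). S is averaged over the two sequences; N = 3·codons −
S. Differences: for codons differing at k ≤ 3 positions, synonymous and
nonsynonymous steps are averaged over all k! orderings of the minimal
mutational pathways, excluding pathways through stop codons (if every
ordering passes through a stop — possible only for a handful of codon pairs
— all orderings are used, stop steps counted nonsynonymous). Both
proportions receive the Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p);
p ≥ 3/4 raises a saturation error and the pair is skipped with a log entry
at the family level.

Family Ka/Ks is mean(Ka)/mean(Ks) over within-family pairs rather than the
mean of pairwise ratios: the ratio of means is defined even when individual
pairs have Ks = 0 and is less noisy for small families. The Ks profile bins
pairs at 0.1 over [0, 1); frequencies are fractions of all pairs, so the
bins sum to the fraction with Ks < 1, and pairs beyond 1 are reported
separately.

## Phylogeny

Protein distances use pairwise deletion; the default model is the Poisson
correction d = −ln(1 − p) (the common default for protein NJ), with plain
p-distance selectable. A fully divergent pair (p = 1) is an error in direct
use; inside bootstrap resampling it is capped at the largest observable
proportion (1 − 1/(2·compared)) because fully divergent resamples of
unrelated sequences are routine and discarding those replicates would
deflate every support uniformly. Supports are normalized by the number of
valid replicates.

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion. Ties are broken on the lexicographically smallest pair of
minimum leaf labels, so trees are bit-for-bit reproducible. Negative branch
lengths are clamped to zero with the deficit moved to the sibling branch.
Bootstrap supports are percentages of replicate trees containing the same
leaf bipartition (canonicalized away from the smallest leaf).

Clade counting roots the tree at the midpoint of the longest leaf-to-leaf
path and reports **maximal** clades with ≥ 2 leaves, all of the focal
species, and support strictly > 50%; maximality (never counting a clade
nested in a counted clade) prevents double counting of genes. The focal
species is explicit because the analysis asks about duplications in one
genome against a reference outgroup. Monophyly of a gene set (used for the
RPW8-flagged genes) is evaluated on the unrooted tree: the set must equal
one side of some edge bipartition, whose support is reported.

The multiple alignment behind distances and back-translation is a built-in
progressive aligner: a UPGMA guide tree on pairwise identity distances,
then profile–profile Needleman–Wunsch with expected BLOSUM62 scores and an
occupancy-weighted linear gap penalty (−6 per column). It is adequate at
the package's scale (tens of sequences); it makes no claim to match
heuristic aligners' accuracy on hard cases.

## Codon site models

The substitution process is GY94-style over the 61 sense codons: rate
q_ij = π_j · κ^[transition] · ω^[nonsynonymous] for single-nucleotide
changes, zero otherwise, normalized to one expected substitution per codon
site at stationarity (branch lengths are substitutions per codon site).
P(t) is computed by symmetric eigendecomposition of the reversible
generator. Codon frequencies default to F3x4 from the alignment (with a
1e-6 floor so observed codons never have zero probability); equal
frequencies are selectable.

Likelihoods use Felsenstein pruning with per-node rescaling and log-space
accumulation. Site-class models average the per-site likelihood over K = 10
equal-probability beta categories at the category medians (M7), plus one
ω ≥ 1 class with weight 1 − p0 (M8).

Fitting: branch lengths and κ are estimated jointly with ω under M0
(bounded Powell search from the input tree's lengths) and held fixed for M7
and M8 — a standard runtime approximation to joint optimization whose cost
would be prohibitive per family at this scale. M7 (p, q) and M8 (p, q, p0,
ω_s) are maximized by bounded Powell search with seeded random restarts
(lnL tolerance 1e-6); the pipeline always seeds one M8 start at the fitted
M7 embedded in M8 (p0 → 1, ω_s = 1), which guarantees the nesting property
lnL(M8) ≥ lnL(M7) up to optimizer tolerance. Families of identical
sequences are flagged unidentifiable. The LRT is 2(lnL_M8 − lnL_M7) against
χ²(df = 2): 5.991 (p < 0.05, `*`) and 9.210 (p < 0.01, `**`); tiny negative
values within 1e-4 are clamped to zero.

Site identification is **NEB** — posteriors at the MLEs, P(class k | site)
∝ weight_k · L(site | ω_k) — not full Bayes-empirical-Bayes integration
over parameter uncertainty; output headers state this. Flags: `*` at
P(ω>1) ≥ 0.95, `**` at ≥ 0.99.

## Promoters

Promoters are the `length` (default 1,000) bases immediately upstream of
the annotated gene feature — not the transcription start site, which the
input annotations do not carry — emitted 5'→3' relative to the gene:
for minus-strand genes the reverse complement of the downstream flank.
Contig edges truncate the promoter and set a flag.

Motifs are IUPAC consensus patterns compiled to character classes; an 'N'
in the promoter matches only motif positions that are themselves 'N'.
Scanning reports all overlapping occurrences on both strands, so a
palindromic site yields one hit per strand — the behaviour of classic
signal-scanning tools, and flagged in output metadata. Because published
per-element counts are ambiguous between occurrences and genes, the census
reports both, ordered by genes-with-hit. A ~20-motif subset of named
plant cis-element patterns ships as a fixture; real scans should supply a
motif TSV from a full collection.

## Synthetic-data generator

Each family evolves from a root drawn from the stationary codon
distribution (uniform over the 61 sense codons by default) under the same
GY94 process the likelihood engine uses. The pairwise separation t is
calibrated by root-finding so the **expected Nei–Gojobori plug-in estimate**
at separation t equals the requested target_ks — this, rather than a naive
rate-based conversion, is what makes the generating parameters a valid
oracle for the estimator. Default genealogy is a star (every pair at
exactly the target separation); a random ultrametric birth tree is
available, where the target applies to the deepest pairs and nested pairs
are younger.

Defaults (two species; five families of sizes 5/4/4/3/3 with targets
Ks 0.45/0.45/0.15/0.10/0.15 and ω 0.2/0.2/0.3/1.5/0.2; six singletons;
300-codon CDSs; 1,000 bp promoters; 400-gene census denominator) sketch the
shape such surveys report: an ancient duplication mode near Ks 0.4–0.5, a
recent mode, mostly purifying families with a positively selected minority,
and one RPW8-flagged family. The ω values keep within-family protein
identity above 70% — required for the members to *be* a family under the
clustering criterion. κ defaults to 1 because Nei–Gojobori site counting
assumes no transition bias; with κ > 1 (configurable) the estimator is
systematically biased, which is a property of the method, not the
generator.

Domain architectures are emitted as annotation rows (the pipeline consumes
domain tables, as real surveys consume Pfam/SMART output), not as sequence
motifs. Exon structures are planted by splitting the CDS across exons with
20 bp introns; one contig per gene, half on the minus strand. Promoter
backgrounds are drawn from the largest nucleotide alphabet on which no
planted motif can occur on either strand, and every built promoter is
verified by scanning (with retries), so manifest motif counts are exactly
recoverable. Singletons and filler (non-NBS) genes are independent random
sequences.

What the generator does **not** emulate: indels and alignment uncertainty,
recombination and gene conversion, rate variation across sites and
lineages, base composition bias, domain-sequence signal (domains are
annotations), realistic intergenic sequence, and genome-scale gene counts.
Tests passing on this data therefore validate the machinery and estimator
calibration, not performance on noisy real genomes.

## Problem sizes and determinism

The default dataset is desk-scale (29 genes, 300-codon CDSs); the test
suite and the acceptance script use 50–200 bootstrap replicates, selection
fits with one restart plus the M7-seeded M8 start, recovery checks at
500–2,000 codons with 5–10 seeds — sizes chosen so the full suite runs in
a couple of minutes while keeping Monte-Carlo error well inside the asserted
tolerances. The library defaults remain 1,000 replicates and 3 restarts.
Every random step (simulation, bootstrap, restarts) flows from one seed;
identical configurations reproduce files byte for byte.

## Known limitations

- NEB rather than full BEB for site posteriors (flagged above).
- Branch lengths fixed after M0; no joint branch/model optimization.
- The progressive aligner has no iterative refinement.
- Pairwise-deletion distances can be non-additive on very gappy alignments.
- The coverage denominator and linkage conventions are one defensible
  reading of the clustering criterion; alternatives (shorter-gene coverage,
  complete linkage) would shrink families.
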