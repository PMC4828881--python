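# Methods

`itvus` implements a unified information-theory (IT) framework for
flagging and prioritizing variants of uncertain significance in
hereditary breast/ovarian cancer (HBOC) gene panels. Every class of
protein–nucleic-acid recognition — splice sites, splicing regulatory
factors (SRFs), transcription factors (TFs), RNA-binding proteins
(RBPs) — is scored on a single scale, individual information, so that
one set of thermodynamically motivated thresholds governs the whole
analysis. Two non-IT components complete the framework: a
structure-disruption rank statistic for UTR variants, and a cohort
screen for candidate hemizygous deletions.

## Individual information

A binding-site model is an information weight matrix (IWM) with one bit
value per (position, base),

    riw(b, l) = 2 + log2 f(b, l) − e(n),

where `f(b, l)` are the base frequencies of the aligned training sites
and `e(n) ≈ 3/(2·ln2·n)` is the standard first-order small-sample
correction for a four-letter alphabet (switchable off; zero for
published PWMs, whose `n` is unknown). The individual information of a
candidate site is the sum of the cells its bases select,

    Ri = Σ_l riw(base_l, l)   [bits],

and a variant's effect on a site is `ΔRi = Ri(alt) − Ri(ref)`. Because
`Ri` is proportional to the free energy of binding, a change of ΔRi
bits bounds the change in binding affinity by `2^ΔRi` — a 1-bit loss is
at least a 2-fold reduction, 4 bits at least 16-fold.

`Rsequence`, the model's mean information content, is computed as the
mean `Ri` over the training sites (with its S.D.). This is the
definition used throughout the flagging rules; it coincides with the
column-entropy form `Σ_l (2 − H(l) − e(n))` in the zero-pseudocount
limit, which is how it is computed for PWM-derived models that have no
training sites (their S.D. is reported as 0 and marked undefined).

Numerical choices: Laplace pseudocounts (+1 count per cell) when
building from sites; 1e-6 probability mass, then renormalization, when
converting PWMs — both keep every `riw` finite. Non-ACGT bases in a
scored window contribute the column minimum and raise a warning, never
silently. Minus-strand scoring reverse-complements and re-reads 5'→3',
so strand symmetry holds by construction. Indels are re-scored on the
edited sequence at the same boundary coordinate; the best-scoring
anchor within ±(indel length) is reported as a secondary result.
Report rounding: bits to 1 decimal; folds to 2 significant figures
above 10, 1 decimal below.

## Flagging and prioritization rules

All thresholds are configuration defaults, exposed per module.

**Filters.** Variants outside the capture regions or with call quality
below 50 are removed first. Common variants — population allele
frequency ≥ 1% (inclusive) or more than 5 cohort carriers (exclusive at
5) — are set aside; missing frequency counts as rare, since novel
variants are the point of the screen. Indels inside or adjacent to
homopolymer runs of ≥ 6 nt get a manual-review flag instead of a
computable verdict.

**Natural splice sites.** Flag when weakened by ≥ 1.0 bit. If the final
strength falls below `Ri,minimum` (default 1.6 bits) the site is
considered non-functional (abolished → exon skipping predicted);
otherwise splicing is predicted to be leaky.

**Cryptic splice sites.** Flag a strengthened site within 300 nt of the
nearest exon whose final strength is equal or greater than the nearest
natural site of the same polarity. "Same phase" is interpreted as same
polarity (acceptor vs donor); reading frame is reported as metadata.

**Exon definition.** Exon strength is
`Ri,total = Ri(acceptor) + Ri(donor) − gap surprisal`, with the gap
surprisal `−log2 P(L)/P(L_modal)` taken from an exon-length
distribution (shipped default: log-normal, median 120 nt, log-s.d. 0.7;
an empirical table may be supplied). Candidate isoforms around an
affected exon are enumerated from natural plus cryptic (Ri > 0) sites
within a 300-nt flank, ranked by `Ri,total`, with relative abundance
∝ `2^Ri,total` normalized over the reported isoforms. Ties break
shorter-exon-first, then 5'-most. Because the exon-length distribution
used by the original analysis server is unpublished, absolute
`Ri,total` values are illustrative; the ranking machinery, not the
shipped distribution, is the tested surface.

**Pseudoexons.** A deep-intronic variant is called pseudoexon-forming
only if all five conditions hold: (1) ΔRi > 1.0 bit at an intronic
cryptic site; (2) final strength ≥ Rsequence − 1 S.D. (inclusive);
(3) a pre-existing opposite-polarity site with Ri strictly above
Rsequence − 1 S.D. in the correct orientation forming a 10–250 nt exon;
(4) both intronic remnants ≥ 100 nt; (5) an hnRNPA1 proofreading site
(Ri ≥ its Rsequence) within 10 nt of the pseudoexon acceptor (5 nt
available by config). Multiple qualifying partners are resolved to the
highest-`Ri,total` exon; others are listed as alternates. Frameshift is
length mod 3.

**SRFBSs.** Exonic variants and those within 500 nt of an exon are
flagged when (a) ΔRi ≤ −4.0 with initial strength ≥ Rsequence, or (b)
ΔRi ≥ +4.0 ending at ≥ 0 bits. Context then refines the flag: exon-
strength decreases under 3.0 bits (8-fold) are deprioritized as likely
benign; an abolished site replaced by an equivalent site (|ΔRi| ≤ 0.5
bits, a documented operationalization) within 2 nt is neutral; TIA1
effects count only intronically; hnRNPA1 gains near the 3'SS are
proofreading, elsewhere repression; PTB changes trigger re-evaluation
of overlapped factors rather than a direct effect. The factor's
contribution is folded into `Ri,total` additively (enhancers add,
repressors subtract) — an explicit assumption, as the original
server's algebra is unpublished.

**TFBSs.** Promoter regions run from 10 kb upstream of the TSS through
the end of intron 1. Flag weakened sites (initial ≥ Rsequence, ΔRi ≤
−4.0) and created sites (final ≥ Rsequence and the strongest predicted
site of that factor within ±50 nt, a configurable window the source
leaves unspecified). A function-aware filter then drops
direction-consistent changes: strengthened activators and weakened
repressors.

**RBBSs.** UTR variants are flagged when |ΔRi| ≥ 4.0 or when a site is
created/strengthened across the Rsequence line — unless the site
overlaps or lies within 10 nt (footprint-edge distance) of a stronger
pre-existing site (Ri > 0) of a different RBP on the variant sequence.

**UTR structure.** The structure-change score for a substitution is
1 − Pearson correlation between per-position unpaired-probability
profiles of the wild-type and mutant UTR (full base-pair-matrix
correlation available by config). The substitution is ranked among all
3L possible substitutions, most disruptive first (ties: position, then
alt allele), and `p = rank/total`; p < 0.1 prioritizes. The pipeline
additionally treats p ≤ 0.15 as flagged, mirroring the reporting of
near-threshold candidates. The folding engine is pluggable: ViennaRNA's
partition function when its bindings are available, otherwise a
deterministic Boltzmann-weighted Nussinov/McCaskill engine written for
this package (pair weights GC:AU:GU = 8:3:1, minimum hairpin 3 nt,
exact inside–outside sums; O(n⁴), validated against exhaustive
structure enumeration for n ≤ 12). UTRs longer than a configurable
window (default 100 nt) are folded in a local window centered on the
variant; shorter UTRs are folded whole (the long-range mode).

**Coding.** Variants overlapping the CDS are translated; frameshifts
scan for the first downstream stop in the new frame (running into the
3' UTR when needed). For a premature stop at residue `s` of an
`L`-residue protein, residues lost = `L − s + 1` (counting the
stop-gained position). Prioritization: all frameshift indels; nonsense
with the stop more than 50 residues from the C-terminus. Missense
variants are routed to external predictors through report hook columns
and never auto-prioritized. Boundary-spanning variants defer to the
splicing analysis.

**Hemizygosity.** Per sample, maximal genotype-silent stretches (no
heterozygous calls) of at least `min_length` (default 1 kb; the
simulation study below uses 5 kb, matching its ≥ 5 kb planted
deletions) with repeat content < 10% are candidate intervals. An
interval is a candidate deletion when strictly more than 80% of the
≥ 10 controls are heterozygous at ≥ 2 well-distributed loci inside it
(pairwise spread ≥ interval_length/10 — an operationalization the
source leaves qualitative) and the interval is not fully inside a
supplied LD haploblock. Case-non-polymorphic loci are weighted by
expected heterozygosity `2·AF·(1−AF)` into an aggregate
informativeness score. The verdict is deterministic given genotypes.

**Aggregation.** A variant may hold several categories; its status is
the strongest of them (prioritized ⊃ flagged ⊃ dropped), and an
optional override table (variant → pathogenic/benign) supersedes the
computed status, emulating literature or pedigree evidence. Reports:
per-variant TSV, gene × category count matrix, per-sample funnel
(total → post-filter → prioritized), and an annotated VCF with
`ITV_*` INFO tags. Identical inputs and seed give byte-identical
reports.

## Synthetic data

The generator builds a desk-scale study so every module is testable
without downloads: a ~14 kb plus-strand gene (4 exons, introns of
0.5/1.2/0.4 kb, 60 nt 5' UTR, 130 nt 3' UTR, 10.6 kb upstream flank
covering the promoter scan) with a clean ORF, consensus-stamped splice
sites at every boundary, and one engineered variant per prioritization
category (indel, nonsense, missense, natural/cryptic splicing,
pseudoexon, SRF, TF, UTR structure, UTR binding). Every plant is
verified against the package's own rules at generation time — e.g. the
natural-site plant is weakened until the single-base hit demonstrably
abolishes it, and the structure plant is the rank-1 disruptor of the
5' UTR under the configured engine — so end-to-end recall is a test of
the pipeline wiring and rule implementations, not of luck. Cohorts of
12 samples carry each plant heterozygously in one sample, plus common
background (removed by the frequency filter), low-quality calls
(removed by the technical filter), and rare deep-intronic background
verified quiet at generation. All randomness flows from one seed;
fixed seed gives byte-identical FASTA/VCF/tables.

The built-in binding-site models are synthetic: generated from
hand-written consensus/conservation profiles (splice and SRF models via
200 deterministically sampled training sites, so Rsequence and its
S.D. are meaningful; TF/RBP models via the PWM path, mirroring how
published matrices enter the analysis). They emulate the *shapes* of
real motif classes, not the published human models, so bit values are
internally consistent but not comparable to literature values.

The hemizygosity simulation is a separate genotype-matrix generator:
40 kb regions with informative common markers (AF 0.35–0.5) every
~300 nt, Hardy–Weinberg genotypes for 20 samples, and an optional 8 kb
planted deletion whose carrier can never be called heterozygous inside
it. These conditions were fixed from detection-power arithmetic: with
~15 informative markers per candidate window, >80% control support is
near-certain for true deletions while the null false-candidate rate
stays below 5% (≈ 600 sample×window trials × p_hom^15 ≈ 2%).

What passing these tests does **not** show: performance on real human
panels, where marker density and LD structure vary, motifs overlap in
more complex ways, repeat content is pervasive, and the exon-length
distribution matters quantitatively.

## Problem sizes

The shipped test-suite and acceptance studies run at desk scale by
design: one ~14 kb gene, 12-sample cohorts, 10 planted variants per
study, 200 + 200 simulated 20-sample cohorts for the deletion screen,
500 sampled sites for parameter recovery, and toy-engine folding kept
to sequences ≤ 40 nt (the exhaustive-enumeration oracle to ≤ 12 nt).
The ViennaRNA engine handles pipeline-scale UTRs.

## Known limitations

- The pipeline orchestrator analyzes plus-strand gene models (the
  module-level analyses are strand-capable via reverse-complement
  scoring; coding annotation handles both strands). TF scanning is
  single-strand.
- Structure ranking supports substitutions only, like the rank
  statistic it implements; indels in UTRs are not ranked.
- Exon-definition enumeration is per-exon (affected exon ± flank), not
  whole-transcript combinatorics; branch-point models are out of scope.
- Missense pathogenicity, database cross-referencing, junctional-read
  deletion detection, and miRNA target analysis are upstream/external
  by design; the reports expose hook columns instead. (For users
  running junctional-read detection upstream: the convention adopted
  from the source protocol is ≥ 4 supporting reads separated by
  > 700 nt.)
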