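"""Synthetic study fixtures: genes, cohorts, and planted ground truth.

Generates a complete desk-scale study — a reference contig carrying one
multi-exon gene with planted binding sites, a cohort VCF with one
engineered variant per prioritization category plus common/low-quality
background, the matching allele-frequency and factor tables — so every
analysis module can be exercised against known truth without downloads.

Planted variants are constructed, then *verified* against the package's
own rules at generation time (with small deterministic searches, e.g.
for a codon one substitution away from a stop); the manifest records the
ground truth each analysis is expected to recover. Hemizygosity
simulations use a separate light-weight genotype-matrix generator.

Everything is driven by a single seed; fixed seed gives byte-identical
output. Default scales are desk scale: genes under 50 kb, cohorts of at
most 30 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import models as builtin
from .coding import annotate_coding
from .gio import (CohortVariant, GeneModel, write_af_table, write_gene_models,
                  write_vcf)
from .hemizygosity import CohortGenotypes
from .iminfo import BASES, InformationWeightMatrix, delta_ri, score_site
from .pseudoexon import detect_pseudoexon
from .splicing import flag_natural_site_variant

__all__ = ["GeneSpec", "SimulatedGene", "PlantedVariant", "StudyFixture",
           "simulate_gene", "simulate_study", "simulate_cohort",
           "simulate_hemizygosity_cohort"]

CATEGORIES = ("indel", "nonsense", "missense", "natural_splicing",
              "cryptic_splicing", "pseudoexon", "srf", "tf",
              "utr_structure", "utr_binding")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneSpec:
    """Layout of the synthetic gene (plus strand)."""

    gene_id: str = "GENE1"
    chrom: str = "chrSim"
    exon_lengths: tuple[int, ...] = (200, 180, 160, 220)
    intron_lengths: tuple[int, ...] = (500, 1200, 400)
    utr5_length: int = 60
    utr3_length: int = 130
    upstream_flank: int = 10_600  # covers the 10 kb promoter scan
    downstream_flank: int = 500


@dataclass
class SimulatedGene:
    sequence: str
    gene: GeneModel
    manifest: dict = field(default_factory=dict)


@dataclass
class PlantedVariant:
    category: str
    chrom: str
    pos: int          # 0-based
    ref: str
    alt: str
    sample: str = ""
    note: str = ""

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class StudyFixture:
    gene: SimulatedGene
    planted: list[PlantedVariant]
    samples: list[str]
    paths: dict[str, Path] = field(default_factory=dict)


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in _STOPS:
            return codon


def _stamp(seq: list[str], start: int, text: str) -> None:
    for i, c in enumerate(text):
        seq[start + i] = c


def simulate_gene(seed: int, spec: GeneSpec | None = None,
                  models: dict[str, InformationWeightMatrix] | None = None
                  ) -> SimulatedGene:
    """Build the reference contig, gene model and planted-site manifest."""
    spec = spec or GeneSpec()
    models = models or builtin.builtin_models()
    rng = np.random.default_rng(seed)
    acc, don = models["acceptor"], models["donor"]

    if len(spec.intron_lengths) != len(spec.exon_lengths) - 1:
        raise ValueError("need exactly one intron between consecutive exons")
    total = (spec.upstream_flank + sum(spec.exon_lengths)
             + sum(spec.intron_lengths) + spec.downstream_flank)
    seq = list(rng.choice(list(BASES), size=total))

    # gene coordinates
    exons: list[tuple[int, int]] = []
    cursor = spec.upstream_flank
    for i, elen in enumerate(spec.exon_lengths):
        exons.append((cursor, cursor + elen))
        cursor += elen
        if i < len(spec.intron_lengths):
            cursor += spec.intron_lengths[i]
    tss = exons[0][0]
    cds_start = exons[0][0] + spec.utr5_length
    cds_end = exons[-1][1] - spec.utr3_length

    # natural splice sites: stamp the intronic part of each boundary motif
    for i, (s, e) in enumerate(exons):
        if i > 0:  # acceptor at the exon start
            cons = acc.consensus()
            _stamp(seq, s - acc.offset, cons[: acc.offset])
        if i < len(exons) - 1:  # donor at the exon end
            cons = don.consensus()
            _stamp(seq, e, cons[don.offset:])

    # coding sequence: clean ORF written over the exonic CDS positions
    cds_positions = [p for s, e in exons for p in range(s, e)
                     if cds_start <= p < cds_end]
    if len(cds_positions) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    n_codons = len(cds_positions) // 3
    codons = ["ATG"] + [_random_codon(rng) for _ in range(n_codons - 2)] + ["TAA"]
    for p, c in zip(cds_positions, "".join(codons)):
        seq[p] = c

    manifest: dict = {"natural_sites": [], "planted_sites": []}
    gene = GeneModel(
        gene_id=spec.gene_id, chrom=spec.chrom, strand="+", tss=tss,
        exons=list(exons), cds_start=cds_start, cds_end=cds_end,
        utr5=[(tss, cds_start)], utr3=[(cds_end, exons[-1][1])],
        protein_length=n_codons - 1,
    )
    sim = SimulatedGene(sequence="".join(seq), gene=gene, manifest=manifest)
    sim.manifest["seq_list"] = seq  # mutable, used by simulate_study
    for i, (s, e) in enumerate(exons):
        if i > 0:
            manifest["natural_sites"].append(
                ("acceptor", s, score_site(sim.sequence, acc, s).ri))
        if i < len(exons) - 1:
            manifest["natural_sites"].append(
                ("donor", e, score_site(sim.sequence, don, e).ri))
    return sim


def _one_snv_to(codon: str, targets: set[str]) -> tuple[int, str] | None:
    for i in range(3):
        for b in BASES:
            if b != codon[i] and codon[:i] + b + codon[i + 1:] in targets:
                return i, b
    return None


def _plant_all(sim: SimulatedGene, models: dict[str, InformationWeightMatrix],
               engine, rng: np.random.Generator) -> list[PlantedVariant]:
    """Engineer one variant per category into the reference, verifying each
    against the package's own rules."""
    spec_seq = sim.manifest["seq_list"]
    gene = sim.gene
    chrom = gene.chrom
    acc, don, hn = models["acceptor"], models["donor"], models["hnRNPA1"]
    exons = gene.exons
    introns = gene.introns()
    planted: list[PlantedVariant] = []

    def refresh() -> str:
        sim.sequence = "".join(spec_seq)
        return sim.sequence

    # --- natural splicing: abolish the exon-3 acceptor -------------------
    e3s = exons[2][0]
    # weaken the polypyrimidine tract until the single-base hit below will
    # push the site under Ri,minimum while keeping it a real site
    variant = (e3s - 2, "A", "C")
    _stamp(spec_seq, e3s - 2, "A")
    for weaken_pos in range(e3s - 13, e3s - 5):
        change = delta_ri(refresh(), variant, acc, e3s)
        flag = flag_natural_site_variant(change)
        if flag.classification == "abolished":
            break
        spec_seq[weaken_pos] = "A"  # worst base for the pyrimidine tract
    change = delta_ri(refresh(), variant, acc, e3s)
    assert flag_natural_site_variant(change).classification == "abolished"
    planted.append(PlantedVariant("natural_splicing", chrom, *variant,
                                  note="abolishes exon-3 acceptor"))

    # --- cryptic splicing: strengthen a cryptic acceptor near exon 2 -----
    i1s, i1e = introns[0]
    c_anchor = i1e - 60
    cons = acc.consensus()
    _stamp(spec_seq, c_anchor - acc.offset, cons)
    spec_seq[c_anchor - 2] = "C"  # pre-existing site one base off consensus
    planted.append(PlantedVariant(
        "cryptic_splicing", chrom, c_anchor - 2, "C", "A",
        note="restores consensus of a cryptic acceptor 60 nt upstream of exon 2"))

    # --- pseudoexon in intron 2 ------------------------------------------
    i2s, i2e = introns[1]
    pa = i2s + 300                       # pseudoexon acceptor boundary
    pd = pa + 150                        # pseudoexon donor boundary
    _stamp(spec_seq, pa - acc.offset, cons)          # strong partner acceptor
    _stamp(spec_seq, pa + 1, hn.consensus())          # proofreading site
    _stamp(spec_seq, pd - don.offset, don.consensus())
    spec_seq[pd] = "A"                   # kill the donor GT; variant restores
    px_variant = (pd, "A", "G")
    call = detect_pseudoexon(refresh(), px_variant, (i2s, i2e),
                             {"acceptor": acc, "donor": don, "hnrnpa1": hn})
    assert call is not None and call.lengths == (300, 150, 750)
    planted.append(PlantedVariant("pseudoexon", chrom, *px_variant,
                                  note=f"pseudoexon {call.lengths_str}"))

    # --- SRF: exonic variant creating an hnRNPA1 repressor site ----------
    e3e = exons[2][1]
    hn_cons = hn.consensus()  # TAGGGT; created TAG must be out of frame
    for start in range(e3s + 60, e3s + 90):
        frame = (start - _cds_index_origin(gene, start)) % 3
        if frame == 0:
            continue  # avoid an in-frame TAG stop
        _stamp(spec_seq, start, hn_cons)
        spec_seq[start + 2] = "C"  # TACGGT: one base from the consensus
        srf_variant = (start + 2, "C", "G")
        change = delta_ri(refresh(), srf_variant, hn, start + hn.offset)
        cons_check = _coding_consequence_of(sim, srf_variant)
        if (change.delta_ri >= 4.0 and change.ri_final >= 0
                and cons_check not in ("nonsense", None)):
            planted.append(PlantedVariant(
                "srf", chrom, *srf_variant,
                note="creates an exonic hnRNPA1 site"))
            break
    else:
        raise RuntimeError("could not place the SRF plant")

    # --- TF: promoter variant abolishing a strong GATA3 site -------------
    gata = models["GATA3"]
    t_anchor = gene.tss - 1500
    _stamp(spec_seq, t_anchor, gata.consensus())
    core = t_anchor + 2  # the invariant A of the GATA core
    tf_variant = (core, spec_seq[core], "C")
    change = delta_ri(refresh(), tf_variant, gata, t_anchor + gata.offset)
    assert change.ri_initial >= gata.r_sequence and change.delta_ri <= -4.0
    planted.append(PlantedVariant("tf", chrom, *tf_variant,
                                  note="abolishes a planted GATA3 site"))

    # --- RBBS: 3' UTR variant abolishing a strong RBFOX site -------------
    # verified against the full rule (including the suppression clause) at
    # the stamped anchor, sliding along the UTR past unlucky backgrounds
    from .pipeline import _rbp_neighbors
    from .rbbs import flag_rbbs_variant
    rbfox = models["RBFOX"]
    rbp = {name: models[name] for name in builtin.RBP_FACTORS}
    saved = list(spec_seq)
    for u_anchor in range(gene.cds_end + 40, exons[-1][1] - 20, 7):
        spec_seq[:] = saved
        _stamp(spec_seq, u_anchor, rbfox.consensus())
        rb_variant = (u_anchor + 2, spec_seq[u_anchor + 2], "A")
        seq_now = refresh()
        change = delta_ri(seq_now, rb_variant, rbfox,
                          u_anchor + rbfox.offset)
        alt_now = (seq_now[:rb_variant[0]] + rb_variant[2]
                   + seq_now[rb_variant[0] + 1:])
        neighbors = _rbp_neighbors(alt_now, rbp, "RBFOX",
                                   u_anchor + rbfox.offset, rbfox)
        if (abs(change.delta_ri) >= 4.0
                and flag_rbbs_variant(change, rbfox, neighbors).flagged):
            break
    else:
        raise RuntimeError("could not place the RBBS plant")
    planted.append(PlantedVariant("utr_binding", chrom, *rb_variant,
                                  note="abolishes a planted RBFOX site"))

    # --- UTR structure: hairpin in the 5' UTR, most disruptive SNV -------
    utr5_s, utr5_e = gene.utr5[0]
    stem = "GGCAGCCUGG".replace("U", "T")
    loop = "TTCGA"
    hp = stem + loop + _revcomp(stem)
    hp_start = utr5_s + 10
    _stamp(spec_seq, hp_start, hp)
    utr_seq = refresh()[utr5_s:utr5_e]
    from .utrstruct import _distance, all_substitutions
    wt_profile = engine.unpaired_profile(utr_seq)
    scored = []
    for (i, r, a) in all_substitutions(utr_seq):
        mut = utr_seq[:i] + a + utr_seq[i + 1:]
        d = _distance(wt_profile, engine.unpaired_profile(mut))
        scored.append((-d, i, a, r))
    scored.sort()
    _, upos, ualt, uref = scored[0]  # the rank-1 disruptor under this engine
    planted.append(PlantedVariant(
        "utr_structure", chrom, utr5_s + upos, uref, ualt,
        note="most structure-disruptive substitution of the 5' UTR"))

    # --- coding: nonsense, missense, frameshift indel ---------------------
    seq = refresh()
    cds_positions = [p for s, e in exons for p in range(s, e)
                     if gene.cds_start <= p < gene.cds_end]
    taken = {v.pos for v in planted}

    def codon_at(k: int) -> str:
        return "".join(seq[cds_positions[3 * k + i]] for i in range(3))

    nonsense = missense = None
    for k in range(10, gene.protein_length - 60):
        pos_set = {cds_positions[3 * k + i] for i in range(3)}
        if pos_set & taken or min(pos_set) < exons[1][0]:
            continue  # keep plants in exons 2+, clear of other plants
        codon = codon_at(k)
        if nonsense is None:
            hit = _one_snv_to(codon, _STOPS)
            if hit:
                i, b = hit
                nonsense = PlantedVariant(
                    "nonsense", chrom, cds_positions[3 * k + i],
                    codon[i], b, note=f"stop at codon {k + 1}")
                taken.add(nonsense.pos)
                continue
        if missense is None:
            from Bio.Seq import Seq
            aa = str(Seq(codon).translate())
            for i in range(3):
                done = False
                for b in BASES:
                    alt_codon = codon[:i] + b + codon[i + 1:]
                    if (b != codon[i] and alt_codon not in _STOPS
                            and str(Seq(alt_codon).translate()) != aa):
                        missense = PlantedVariant(
                            "missense", chrom, cds_positions[3 * k + i],
                            codon[i], b, note=f"codon {k + 1}")
                        taken.add(missense.pos)
                        done = True
                        break
                if done:
                    break
        if nonsense and missense:
            break
    assert nonsense is not None and missense is not None
    planted += [nonsense, missense]

    ipos = exons[1][0] + 50
    while ipos in taken:
        ipos += 3
    planted.append(PlantedVariant(
        "indel", chrom, ipos, seq[ipos], seq[ipos] + "AG",
        note="2-nt insertion, frameshift"))

    # verify the coding plants
    assert _coding_consequence_of(sim, (nonsense.pos, nonsense.ref,
                                        nonsense.alt)) == "nonsense"
    assert _coding_consequence_of(sim, (missense.pos, missense.ref,
                                        missense.alt)) == "missense"
    refresh()
    return planted


def _revcomp(s: str) -> str:
    from .iminfo import reverse_complement
    return reverse_complement(s)


def _cds_index_origin(gene: GeneModel, pos: int) -> int:
    """Genomic position congruent to the codon frame origin at ``pos``.

    Returns a reference point so that (pos - origin) % 3 is the in-codon
    offset, accounting for introns upstream of ``pos``.
    """
    offset = 0
    for s, e in gene.exons:
        lo = max(s, gene.cds_start)
        hi = min(e, gene.cds_end)
        if hi <= lo:
            continue
        if lo <= pos < hi:
            return pos - ((offset + (pos - lo)) % 3)
        offset += hi - lo
    return gene.cds_start


class _SeqRef:
    """Minimal in-memory stand-in for a ReferenceStore over one contig."""

    def __init__(self, chrom: str, sequence: str):
        self._chrom, self._seq = chrom, sequence.upper()

    def sequence(self, chrom: str) -> str:
        if chrom != self._chrom:
            raise KeyError(chrom)
        return self._seq

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        s = self.sequence(chrom)[start:end]
        return _revcomp(s) if strand == "-" else s


def _coding_consequence_of(sim: SimulatedGene,
                           variant: tuple[int, str, str]) -> str | None:
    pos, ref, alt = variant
    cv = CohortVariant(chrom=sim.gene.chrom, pos=pos, ref=ref, alt=alt,
                       qual=200.0)
    cons = annotate_coding(cv, sim.gene, _SeqRef(sim.gene.chrom, sim.sequence))
    return cons.consequence if cons else None


def simulate_cohort(
    seed: int,
    sim: SimulatedGene,
    n_samples: int,
    planted_variants: list[PlantedVariant],
    planted_deletion: tuple[str, tuple[int, int]] | None = None,
) -> tuple[list[CohortVariant], dict[tuple, float], list[str]]:
    """Cohort genotypes: planted variants in designated samples, common and
    low-quality background, and optionally a hemizygous deletion rendered
    as absence of heterozygosity in its carrier."""
    rng = np.random.default_rng(seed)
    gene = sim.gene
    chrom = gene.chrom
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    variants: list[CohortVariant] = []
    afs: dict[tuple, float] = {}
    taken = {v.pos for v in planted_variants}

    deletion_carrier, deletion_iv = (None, None)
    if planted_deletion is not None:
        deletion_carrier, deletion_iv = planted_deletion

    def genotypes_for(carriers: dict[str, int],
                      pos: int) -> dict[str, int | None]:
        gt = {s: carriers.get(s, 0) for s in samples}
        if (deletion_iv is not None and deletion_carrier is not None
                and deletion_iv[0] <= pos < deletion_iv[1]):
            # a hemizygous carrier cannot be called heterozygous
            if gt[deletion_carrier] == 1:
                gt[deletion_carrier] = 0
        return gt

    # planted variants: one heterozygous carrier each, round robin
    for i, pv in enumerate(planted_variants):
        pv.sample = samples[i % n_samples]
        variants.append(CohortVariant(
            chrom=chrom, pos=pv.pos, ref=pv.ref, alt=pv.alt, qual=200.0,
            genotypes=genotypes_for({pv.sample: 1}, pv.pos)))

    i1s, i1e = gene.introns()[0]
    # common background: filtered out by frequency rules
    for k in range(8):
        pos = i1s + 40 + 17 * k
        if pos in taken:
            continue
        ref = sim.sequence[pos]
        alt = rng.choice([b for b in BASES if b != ref])
        af = float(rng.uniform(0.02, 0.3))
        n_car = max(6, int(round(af * 2 * n_samples)) + 6)
        carriers = {s: 1 for s in rng.choice(samples, size=min(n_car, n_samples),
                                             replace=False)}
        variants.append(CohortVariant(chrom=chrom, pos=pos, ref=ref,
                                      alt=str(alt), qual=180.0,
                                      genotypes=genotypes_for(carriers, pos)))
        afs[(chrom, pos, ref, str(alt))] = af

    # rare deep-intronic background: analyzed, expected quiet
    i2s, i2e = gene.introns()[1]
    models = builtin.splice_models()
    models = {"acceptor": models["acceptor"], "donor": models["donor"],
              "hnrnpa1": models["hnrnpa1"]}
    for k in range(6):
        pos = i2s + 560 + 11 * k
        ref = sim.sequence[pos]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        if detect_pseudoexon(sim.sequence, (pos, ref, alt), (i2s, i2e),
                             models) is not None:
            continue  # keep the background quiet by construction
        carrier = samples[int(rng.integers(n_samples))]
        variants.append(CohortVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, qual=150.0,
            genotypes=genotypes_for({carrier: 1}, pos)))
        afs[(chrom, pos, ref, alt)] = 0.001

    # low-quality calls: removed by the technical filter
    i3s, i3e = gene.introns()[2]
    for k in range(3):
        pos = i3s + 50 + 29 * k
        ref = sim.sequence[pos]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        carrier = samples[int(rng.integers(n_samples))]
        variants.append(CohortVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, qual=30.0,
            genotypes=genotypes_for({carrier: 1}, pos)))
    return variants, afs, samples


def simulate_study(seed: int = 0, n_samples: int = 12,
                   out_dir: Path | str | None = None,
                   engine=None) -> StudyFixture:
    """Full fixture set: contig FASTA, gene table, capture BED, cohort VCF,
    AF table, factor table. Deterministic in ``seed`` (given one engine)."""
    from .utrstruct import get_engine
    engine = engine or get_engine("auto")
    rng = np.random.default_rng(seed)
    models = builtin.builtin_models()
    sim = simulate_gene(int(rng.integers(2**31)), models=models)
    planted = _plant_all(sim, models, engine, rng)
    variants, afs, samples = simulate_cohort(
        int(rng.integers(2**31)), sim, n_samples, planted)
    fixture = StudyFixture(gene=sim, planted=planted, samples=samples)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        chrom, n = sim.gene.chrom, len(sim.sequence)
        fasta = out / "reference.fa"
        with open(fasta, "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, n, 70):
                fh.write(sim.sequence[i:i + 70] + "\n")
        bed = out / "capture.bed"
        bed.write_text(f"{chrom}\t0\t{n}\n")
        vcf = out / "cohort.vcf"
        write_vcf(vcf, variants, {chrom: n}, samples=samples)
        af_path = out / "population_af.tsv"
        write_af_table(af_path, afs)
        genes_path = out / "genes.tsv"
        write_gene_models(genes_path, [sim.gene])
        factors = out / "factors.tsv"
        with open(factors, "w") as fh:
            for row in builtin.factor_table_rows():
                fh.write("\t".join(row) + "\n")
        fixture.paths = {"reference": fasta, "capture_bed": bed, "vcf": vcf,
                         "af_table": af_path, "genes": genes_path,
                         "factors": factors}
    fixture.gene.manifest["variants"] = variants
    fixture.gene.manifest["afs"] = afs
    return fixture


def simulate_hemizygosity_cohort(
    seed: int,
    n_samples: int = 20,
    region_length: int = 40_000,
    marker_spacing: int = 300,
    af_range: tuple[float, float] = (0.35, 0.5),
    deletion: tuple[int, int] | None = (16_000, 8_000),
    carrier: int = 0,
) -> tuple[CohortGenotypes, tuple[int, int] | None]:
    """Genotype-matrix cohort for the deletion screen.

    Informative common markers (AF drawn from ``af_range``) are placed
    every ``marker_spacing`` nt with jitter; Hardy-Weinberg genotypes are
    drawn per sample. A planted deletion makes its carrier hemizygous —
    read as homozygous, never heterozygous — across the interval.
    """
    rng = np.random.default_rng(seed)
    n_loci = region_length // marker_spacing
    jitter = rng.integers(0, marker_spacing // 2, size=n_loci)
    positions = np.arange(n_loci) * marker_spacing + jitter
    positions = np.unique(positions[positions < region_length])
    afs = rng.uniform(af_range[0], af_range[1], size=positions.size)
    # Hardy-Weinberg genotypes: Binomial(2, AF) per sample x locus
    gt = rng.binomial(2, afs[None, :], size=(n_samples, positions.size))
    interval = None
    if deletion is not None:
        start, length = deletion
        interval = (start, start + length)
        inside = (positions >= interval[0]) & (positions < interval[1])
        # the surviving haplotype is a single allele: het is impossible
        hap = rng.binomial(1, afs[inside])
        gt[carrier, inside] = 2 * hap
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    cohort = CohortGenotypes(samples=samples, positions=positions,
                             afs=afs, gt=gt, region=(0, region_length))
    return cohort, interval
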