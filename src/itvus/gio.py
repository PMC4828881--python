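"""Readers/writers for the genomic file formats the pipeline consumes.

Coordinate convention: everything internal is 0-based half-open; VCF and
HGVS-style 1-based coordinates exist only at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .iminfo import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "CohortVariant",
    "ReferenceStore",
    "VcfReadStats",
    "read_reference",
    "read_cohort_vcf",
    "read_bed",
    "read_af_table",
    "read_factor_table",
    "read_gene_models",
    "write_gene_models",
    "write_vcf",
]


@dataclass
class GeneModel:
    """Minimal transcript structure for one gene.

    Exons are genomic [start, end) intervals sorted 5'->3' in transcription
    order (i.e. descending genomic coordinate on the minus strand); the CDS
    and UTRs are genomic intervals within the exon union.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    protein_length: int = 0

    def __post_init__(self) -> None:
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        # store in transcription order
        self.exons = genomic if self.strand == "+" else genomic[::-1]
        if not (self.cds_start < self.cds_end):
            raise ValueError(f"{self.gene_id}: empty CDS")

    @property
    def span(self) -> tuple[int, int]:
        genomic = sorted(self.exons)
        return genomic[0][0], genomic[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic [start, end) intron intervals, transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out

    def region_of(self, pos: int) -> str:
        """Classify a 0-based position: cds/utr5/utr3/exon/intron/flank."""
        if any(s <= pos < e for s, e in self.utr5):
            return "utr5"
        if any(s <= pos < e for s, e in self.utr3):
            return "utr3"
        in_exon = any(s <= pos < e for s, e in self.exons)
        if in_exon:
            return "cds" if self.cds_start <= pos < self.cds_end else "exon"
        lo, hi = self.span
        return "intron" if lo <= pos < hi else "flank"


@dataclass
class CohortVariant:
    """One allele of one VCF record across the cohort.

    ``pos`` is the internal 0-based coordinate (VCF POS - 1); ``genotypes``
    maps sample -> alt-allele count in {0, 1, 2} (None for missing).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None
    genotypes: dict[str, int | None] = field(default_factory=dict)
    population_af: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def pos1(self) -> int:
        """1-based VCF coordinate."""
        return self.pos + 1

    @property
    def carrier_count(self) -> int:
        return sum(1 for g in self.genotypes.values() if g)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


class ReferenceStore:
    """Case-insensitive random access to a FASTA reference."""

    def __init__(self, path):
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on ``chrom``; '-' returns the reverse
        complement read 5'->3'."""
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} not in reference")
        if end < start:
            raise ValueError("end < start")
        seq = str(self._fasta[chrom][start:end]) if end > start else ""
        return reverse_complement(seq) if strand == "-" else seq

    def sequence(self, chrom: str) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} not in reference")
        return str(self._fasta[chrom][:])


def read_reference(path) -> ReferenceStore:
    return ReferenceStore(path)


def read_bed(path) -> dict[str, IntervalTree]:
    """BED3 -> per-chromosome interval trees (capture regions, LD blocks)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


@dataclass
class VcfReadStats:
    total: int = 0
    emitted: int = 0
    excluded_by_region: int = 0
    malformed: int = 0


def read_cohort_vcf(
    vcf_path,
    region_bed: dict[str, IntervalTree] | None = None,
    stats: VcfReadStats | None = None,
) -> list[CohortVariant]:
    """Read a VCF (v4.x) into per-allele CohortVariants.

    Multi-allelic records are split before any filtering; records outside
    ``region_bed`` are dropped and counted; malformed records are skipped
    and logged. ``stats`` counts records (conservation: emitted + excluded
    + malformed = total is over records whose every allele survives or not
    per-allele; counters are per emitted allele / per dropped record).
    """
    stats = stats if stats is not None else VcfReadStats()
    out: list[CohortVariant] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            stats.total += 1
            try:
                pos0 = rec.pos - 1
                if region_bed is not None:
                    tree = region_bed.get(rec.chrom)
                    if tree is None or not tree.overlaps(pos0, pos0 + len(rec.ref)):
                        stats.excluded_by_region += 1
                        continue
                alts = rec.alts or ()
                for ai, alt in enumerate(alts, start=1):
                    genotypes: dict[str, int | None] = {}
                    for s in samples:
                        gt = rec.samples[s].get("GT")
                        if gt is None or all(a is None for a in gt):
                            genotypes[s] = None
                        else:
                            genotypes[s] = sum(1 for a in gt if a == ai)
                    out.append(
                        CohortVariant(
                            chrom=rec.chrom,
                            pos=pos0,
                            ref=rec.ref,
                            alt=alt,
                            qual=rec.qual,
                            genotypes=genotypes,
                        )
                    )
                stats.emitted += 1
            except Exception as exc:  # malformed record: skip + log
                stats.malformed += 1
                logger.warning("skipping malformed VCF record: %s", exc)
    return out


def write_vcf(path, variants: list[CohortVariant], contigs: dict[str, int],
              samples: list[str] | None = None,
              info_tags: dict[tuple, dict[str, str]] | None = None) -> None:
    """Write CohortVariants as an uncompressed VCF v4.2 text file."""
    if samples is None:
        seen: list[str] = []
        for v in variants:
            for s in v.genotypes:
                if s not in seen:
                    seen.append(s)
        samples = seen
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    tag_names = sorted({k for tags in (info_tags or {}).values() for k in tags})
    for t in tag_names:
        lines.append(f'##INFO=<ID={t},Number=1,Type=String,Description="{t}">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header += ["FORMAT"] + samples
    lines.append("\t".join(header))
    gt_str = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info = "."
        if info_tags and v.key in info_tags and info_tags[v.key]:
            info = ";".join(f"{k}={val}" for k, val in sorted(info_tags[v.key].items()))
        qual = "." if v.qual is None else f"{v.qual:g}"
        row = [v.chrom, str(v.pos1), ".", v.ref, v.alt, qual, ".", info]
        if samples:
            row.append("GT")
            row += [gt_str[v.genotypes.get(s)] for s in samples]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_af_table(path) -> dict[tuple, float]:
    """Tab-delimited allele-frequency table: chrom, pos (1-based), ref, alt, AF."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "pos", "ref", "alt", "af"], dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos) - 1, r.ref, r.alt): float(r.af)
        for r in df.itertuples()
    }


def write_af_table(path, afs: dict[tuple, float]) -> None:
    with open(path, "w") as fh:
        for (chrom, pos, ref, alt), af in sorted(afs.items()):
            fh.write(f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t{af:.6f}\n")


def read_factor_table(path) -> pd.DataFrame:
    """Factor metadata: factor, class in {SRF,TF,RBP}, role."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["factor", "klass", "role"], dtype=str)
    return df


def annotate_population_af(variants: list[CohortVariant],
                           afs: dict[tuple, float]) -> None:
    for v in variants:
        v.population_af = afs.get(v.key)


_GENE_COLUMNS = [
    "gene_id", "chrom", "strand", "tss", "exons", "cds_start", "cds_end",
    "utr5", "utr3", "protein_length",
]


def _fmt_intervals(ivs: list[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in ivs) or "."


def _parse_intervals(text: str) -> list[tuple[int, int]]:
    if text in (".", "", None):
        return []
    return [tuple(int(x) for x in part.split("-")) for part in text.split(";")]


def write_gene_models(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join([
                    g.gene_id, g.chrom, g.strand, str(g.tss),
                    _fmt_intervals(sorted(g.exons)), str(g.cds_start),
                    str(g.cds_end), _fmt_intervals(g.utr5),
                    _fmt_intervals(g.utr3), str(g.protein_length),
                ]) + "\n"
            )


def read_gene_models(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(
                    gene_id=f[0], chrom=f[1], strand=f[2], tss=int(f[3]),
                    exons=_parse_intervals(f[4]), cds_start=int(f[5]),
                    cds_end=int(f[6]), utr5=_parse_intervals(f[7]),
                    utr3=_parse_intervals(f[8]), protein_length=int(f[9]),
                )
            )
    return genes
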