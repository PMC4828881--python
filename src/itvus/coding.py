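"""Coding-consequence annotation and truncation-based prioritization.

Exonic variants are classified as nonsense, frameshift or in-frame
indels, missense, or synonymous by translating the reference and variant
coding sequences. When a premature stop is introduced at residue
``stop_codon_position`` of a protein of length L, the residues lost are
counted as ``L - stop_codon_position + 1`` (the stop-gained position
itself is counted). Truncations are prioritized when the stop lies more
than 50 residues from the C-terminus; frameshift indels are always
prioritized; missense variants are routed to external evidence and never
auto-prioritized.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .gio import CohortVariant, GeneModel, ReferenceStore
from .iminfo import reverse_complement

__all__ = ["CodingConsequence", "annotate_coding", "prioritize_truncation",
           "residues_lost", "TruncationDecision"]

CTERM_DISTANCE_RULE = 50  # residues; "> 50 amino acids from the C-terminus"


@dataclass
class CodingConsequence:
    variant: CohortVariant
    consequence: str  # nonsense | frameshift_indel | inframe_indel |
    #                   missense | synonymous
    stop_codon_position: int | None = None  # 1-based residue index
    residues_lost: int | None = None
    distance_from_cterm: int | None = None
    protein_change: str = ""


def residues_lost(protein_length: int, stop_codon_position: int) -> int:
    """Residues lost for a premature stop at a 1-based residue position,
    counting the stop-gained position itself."""
    if not (1 <= stop_codon_position <= protein_length):
        raise ValueError("stop position outside the protein")
    return protein_length - stop_codon_position + 1


def _transcript_sequences(gene: GeneModel, ref: ReferenceStore
                          ) -> tuple[str, list[int]]:
    """Spliced transcript in transcription orientation plus, per transcript
    index, the genomic coordinate it came from."""
    chrom_seq = ref.sequence(gene.chrom)
    seq_parts: list[str] = []
    coords: list[int] = []
    for s, e in gene.exons:
        if gene.strand == "+":
            seq_parts.append(chrom_seq[s:e])
            coords.extend(range(s, e))
        else:
            seq_parts.append(reverse_complement(chrom_seq[s:e]))
            coords.extend(range(e - 1, s - 1, -1))
    return "".join(seq_parts), coords


def _cds_bounds(gene: GeneModel, coords: list[int]) -> tuple[int, int]:
    """[start, end) of the CDS within the spliced transcript."""
    idx = [i for i, g in enumerate(coords)
           if gene.cds_start <= g < gene.cds_end]
    if not idx:
        raise ValueError(f"{gene.gene_id}: CDS not covered by exons")
    return min(idx), max(idx) + 1


def annotate_coding(variant: CohortVariant, gene: GeneModel,
                    reference: ReferenceStore) -> CodingConsequence | None:
    """Classify a CDS-overlapping variant; returns None when the variant
    spans an intron/exon boundary (deferred to splicing analysis)."""
    var_span = range(variant.pos, variant.pos + max(len(variant.ref), 1))
    exonic = [any(s <= p < e for s, e in gene.exons) for p in var_span]
    if not all(exonic):
        return None  # boundary-spanning: no coding call
    transcript, coords = _transcript_sequences(gene, reference)
    cds_lo, cds_hi = _cds_bounds(gene, coords)
    pos_in_tx = {g: i for i, g in enumerate(coords)}

    # transcript-frame variant alleles
    if gene.strand == "+":
        t_pos = pos_in_tx[variant.pos]
        t_ref, t_alt = variant.ref, variant.alt
    else:
        t_pos = pos_in_tx[variant.pos + len(variant.ref) - 1]
        t_ref = reverse_complement(variant.ref)
        t_alt = reverse_complement(variant.alt)
    if transcript[t_pos:t_pos + len(t_ref)].upper() != t_ref.upper():
        raise ValueError(
            f"reference mismatch for {variant.chrom}:{variant.pos1}")
    if not (cds_lo <= t_pos and t_pos + len(t_ref) <= cds_hi):
        return None  # partially outside CDS

    cds_ref = transcript[cds_lo:cds_hi]
    mutant_tx = transcript[:t_pos] + t_alt + transcript[t_pos + len(t_ref):]
    cds_alt_plus_utr = mutant_tx[cds_lo:]  # run-on for frameshift stop scan
    protein_ref = str(Seq(cds_ref).translate())
    if protein_ref.endswith("*"):
        protein_ref = protein_ref[:-1]
    L = gene.protein_length or len(protein_ref)
    protein_alt = str(Seq(cds_alt_plus_utr[: 3 * (len(cds_alt_plus_utr) // 3)]
                          ).translate())
    stop_idx = protein_alt.find("*")
    stop_pos = stop_idx + 1 if stop_idx >= 0 else None

    indel_len = len(t_alt) - len(t_ref)
    if indel_len != 0:
        consequence = ("frameshift_indel" if indel_len % 3 != 0
                       else "inframe_indel")
    elif stop_pos is not None and stop_pos <= L:
        consequence = "nonsense"
    elif protein_alt[:L] == protein_ref:
        consequence = "synonymous"
    else:
        consequence = "missense"

    out = CodingConsequence(variant=variant, consequence=consequence)
    premature = stop_pos is not None and stop_pos <= L
    if consequence in ("nonsense", "frameshift_indel") and premature:
        out.stop_codon_position = stop_pos
        out.residues_lost = residues_lost(L, stop_pos)
        out.distance_from_cterm = L - stop_pos
    if consequence == "missense":
        codon = (t_pos - cds_lo) // 3 + 1
        out.protein_change = (f"p.{protein_ref[codon - 1]}{codon}"
                              f"{protein_alt[codon - 1]}")
    return out


@dataclass(frozen=True)
class TruncationDecision:
    prioritized: bool
    reason: str


def prioritize_truncation(consequence: CodingConsequence) -> TruncationDecision:
    """Truncation-based prioritization.

    Nonsense variants are prioritized when the stop is more than 50
    residues from the C-terminus; all frameshift indels are prioritized;
    missense variants are routed to external predictors, never
    auto-prioritized.
    """
    c = consequence
    if c.consequence == "frameshift_indel":
        return TruncationDecision(True, "frameshift indel")
    if c.consequence == "nonsense":
        if c.distance_from_cterm is not None \
                and c.distance_from_cterm > CTERM_DISTANCE_RULE:
            return TruncationDecision(
                True, f"stop {c.distance_from_cterm} residues from the "
                f"C-terminus (> {CTERM_DISTANCE_RULE})")
        return TruncationDecision(
            False, f"stop within {CTERM_DISTANCE_RULE} residues of the "
            "C-terminus")
    if c.consequence == "missense":
        return TruncationDecision(False,
                                  "missense routed to external evidence")
    return TruncationDecision(False, c.consequence)
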