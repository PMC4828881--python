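"""Transcription-factor binding-site rules for promoter variants.

The promoter region runs from 10 kb upstream of the transcription start
site through the end of intron 1. Only strong effects are flagged:
weakening of a strong site (Ri,initial >= Rsequence) by >= 4.0 bits, or
creation/strengthening of a site to Ri,final >= Rsequence that is also
the strongest predicted site of that factor in the surrounding interval.
A final function-aware filter drops changes whose direction is
consistent with normal regulation (activator strengthened, repressor
weakened).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .gio import GeneModel
from .iminfo import InformationWeightMatrix, SiteChange, SiteScore

__all__ = ["PromoterRegion", "TfFlag", "promoter_region",
           "flag_tfbs_variant", "function_filter"]

PROMOTER_UPSTREAM_NT = 10_000
FLAG_BITS = 4.0
LOCAL_WINDOW_NT = 50  # "corresponding genomic interval" half-width


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def promoter_region(gene: GeneModel) -> PromoterRegion:
    """10 kb upstream of the TSS through the end of intron 1."""
    introns = gene.introns()
    if gene.strand == "+":
        end_ivs1 = introns[0][1] if introns else gene.exons[0][1]
        start = gene.tss - PROMOTER_UPSTREAM_NT
        end = end_ivs1
    else:
        end_ivs1 = introns[0][0] if introns else gene.exons[0][0]
        start = end_ivs1
        end = gene.tss + PROMOTER_UPSTREAM_NT + 1
    if not (start <= gene.tss < end):
        raise ValueError("promoter region must contain the TSS")
    return PromoterRegion(gene.gene_id, gene.chrom, start, end, gene.strand)


@dataclass(frozen=True)
class TfFlag:
    factor: str
    flagged: bool
    kind: str  # "weakened" | "created" | ""
    reason: str


def flag_tfbs_variant(change: SiteChange,
                      tf_model: InformationWeightMatrix,
                      local_sites: list[SiteScore],
                      flag_bits: float = FLAG_BITS) -> TfFlag:
    """Flag a promoter variant against one TF model.

    ``local_sites`` are that factor's sites in the surrounding interval
    (variant +- 50 nt by convention), unaltered by the variant; the
    "created" clause requires the new site to be the strongest among them.
    """
    factor = tf_model.model_id
    rseq = tf_model.r_sequence
    if change.ri_initial >= rseq and change.delta_ri <= -flag_bits:
        return TfFlag(factor, True, "weakened",
                      f"strong site ({change.ri_initial:.1f} bits >= "
                      f"Rsequence {rseq:.1f}) weakened "
                      f"{-change.delta_ri:.1f} bits")
    if change.ri_final >= rseq:
        strongest = max((s.ri for s in local_sites), default=float("-inf"))
        if change.ri_final > strongest:
            return TfFlag(factor, True, "created",
                          f"novel/strengthened site {change.ri_final:.1f} "
                          f"bits >= Rsequence {rseq:.1f}, strongest in "
                          "interval")
        return TfFlag(factor, False, "",
                      f"site {change.ri_final:.1f} bits not the strongest "
                      f"in interval (max {strongest:.1f})")
    return TfFlag(factor, False, "", "below TFBS flagging rules")


def function_filter(flag: TfFlag, change: SiteChange, tf_role: str | None
                    ) -> tuple[bool, str]:
    """Keep/drop a flagged TFBS change given the factor's known role.

    Drops (activator, strengthened) and (repressor, weakened); unknown
    roles are kept with a warning.
    """
    if not flag.flagged:
        raise ValueError("function filter applies to flagged variants")
    strengthened = change.delta_ri > 0
    if tf_role is None:
        warnings.warn(f"unknown transcriptional role for {flag.factor}; "
                      "keeping flagged variant", stacklevel=2)
        return True, "unknown role: kept"
    if tf_role == "activator" and strengthened:
        return False, "activator with stronger predicted binding"
    if tf_role == "repressor" and not strengthened:
        return False, "repressor with weaker predicted binding"
    return True, f"{tf_role} with {'stronger' if strengthened else 'weaker'} binding"
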