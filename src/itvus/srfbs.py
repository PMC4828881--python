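"""Splicing-regulatory-factor binding-site (SRFBS) rules.

SRF motifs (SRSF1/2/5/6, hnRNPH, hnRNPA1, ELAVL1, TIA1, PTB) occur
frequently in unspliced transcripts, so only large information changes
are flagged: (a) a >= 4.0-bit decrease at a site that started strong
(Ri,initial >= Rsequence), or (b) a >= 4.0-bit increase ending at
Ri,final >= 0. Flagged variants are then interpreted in the context of
the factor's documented splicing role and of the exon-definition change
(delta Ri,total with the factor's contribution folded in): small exon-
strength decreases (< 3 bits, i.e. < 8-fold) are deprioritized as likely
benign, redundant site swaps (equivalent site within 2 nt) are neutral,
and PTB changes trigger re-evaluation of overlapped factors rather than
a direct effect.
"""

from __future__ import annotations

from dataclasses import dataclass

from .iminfo import InformationWeightMatrix, SiteChange
from .splicing import ExonDefinition

__all__ = ["SrfContextRule", "SrfFlag", "SrfDecision", "flag_srf_variant",
           "contextual_interpretation", "exon_ri_total_with_factor"]

SRF_MAX_EXON_DISTANCE = 500   # nt; variants further from an exon are not analyzed
FLAG_BITS = 4.0
BENIGN_DELTA_RI_TOTAL = 3.0   # bits (8-fold)
REDUNDANT_DISTANCE_NT = 2
EQUIVALENT_STRENGTH_BITS = 0.5  # |Ri difference| for "equivalent strength"


@dataclass(frozen=True)
class SrfContextRule:
    factor: str
    allowed_region: str  # exonic | intronic | either
    role: str            # enhancer | repressor | acceptor-proofreader | blocker


@dataclass(frozen=True)
class SrfFlag:
    factor: str
    flagged: bool
    clause: str  # "a" (weakened strong site) | "b" (created/strengthened) | ""
    reason: str


@dataclass(frozen=True)
class SrfDecision:
    decision: str  # prioritized | deprioritized | neutral
    reason: str
    rescan_factors: tuple[str, ...] = ()


def flag_srf_variant(change: SiteChange,
                     factor_model: InformationWeightMatrix,
                     distance_to_exon: int = 0,
                     max_exon_distance: int = SRF_MAX_EXON_DISTANCE,
                     flag_bits: float = FLAG_BITS,
                     min_final_bits: float = 0.0) -> SrfFlag:
    """Apply the two-clause SRFBS flagging rule.

    ``distance_to_exon`` is 0 for exonic variants; variants beyond
    ``max_exon_distance`` nt of an exon are never flagged. The bit
    thresholds are configurable (defaults are the reporting rules).
    """
    factor = factor_model.model_id
    if distance_to_exon > max_exon_distance:
        return SrfFlag(factor, False, "",
                       f"more than {max_exon_distance} nt from an exon")
    if (change.delta_ri <= -flag_bits
            and change.ri_initial >= factor_model.r_sequence):
        return SrfFlag(factor, True, "a",
                       f"strong site weakened {-change.delta_ri:.1f} bits "
                       f"(initial {change.ri_initial:.1f} >= Rsequence "
                       f"{factor_model.r_sequence:.1f})")
    if change.delta_ri >= flag_bits and change.ri_final >= min_final_bits:
        return SrfFlag(factor, True, "b",
                       f"site strengthened {change.delta_ri:.1f} bits to "
                       f"{change.ri_final:.1f} bits")
    return SrfFlag(factor, False, "", "below the 4.0-bit SRFBS rules")


def exon_ri_total_with_factor(exon: ExonDefinition, factor_ri: float,
                              role: str) -> float:
    """Exon strength with one SRF's contribution folded in.

    Enhancer-type factors add their site strength to ri_total;
    repressor-type factors subtract it. (The additive convention is this
    package's documented design choice.)
    """
    if role in ("enhancer", "enhancer-intronic", "acceptor-proofreader"):
        return exon.ri_total + max(factor_ri, 0.0)
    if role in ("repressor", "blocker"):
        return exon.ri_total - max(factor_ri, 0.0)
    return exon.ri_total


def contextual_interpretation(
    flag: SrfFlag,
    change: SiteChange,
    rule: SrfContextRule,
    delta_ri_total: float | None = None,
    variant_region: str = "exonic",
    redundant_sites: list[SiteChange] | None = None,
    near_acceptor: bool = False,
) -> SrfDecision:
    """Context-aware prioritize/deprioritize decision for a flagged SRFBS.

    ``delta_ri_total`` is the factor-aware exon-strength change;
    ``redundant_sites`` lists other site changes of the same factor near
    the variant (for the <= 2 nt equivalent-site redundancy rule);
    ``near_acceptor`` marks an hnRNPA1 footprint within 10 nt of the 3'SS.
    """
    if not flag.flagged:
        raise ValueError("contextual interpretation needs a flagged variant")
    # TIA1 acts as an intronic enhancer of exon definition only
    if rule.allowed_region == "intronic" and variant_region != "intronic":
        return SrfDecision("deprioritized",
                           f"{rule.factor} changes considered intronic only")
    if rule.allowed_region == "exonic" and variant_region != "exonic":
        return SrfDecision("deprioritized",
                           f"{rule.factor} changes considered exonic only")
    # redundant site swap: abolished site replaced by an equivalent site
    # within 2 nt -> neutral for splicing
    if redundant_sites and change.delta_ri < 0:
        for other in redundant_sites:
            dist = abs(other.alt_score.position - change.ref_score.position)
            if (dist <= REDUNDANT_DISTANCE_NT
                    and other.delta_ri > 0
                    and abs(other.ri_final - change.ri_initial)
                    <= EQUIVALENT_STRENGTH_BITS):
                return SrfDecision(
                    "neutral",
                    f"equivalent {rule.factor} site activated within "
                    f"{REDUNDANT_DISTANCE_NT} nt of the abolished site")
    # PTB does not enhance or inhibit directly; it blocks overlapping sites
    if rule.role == "blocker":
        return SrfDecision(
            "prioritized",
            f"{rule.factor} blocking site changed; overlapped factors "
            "re-evaluated",
            rescan_factors=("*",))
    if (delta_ri_total is not None and delta_ri_total < 0
            and -delta_ri_total < BENIGN_DELTA_RI_TOTAL):
        return SrfDecision(
            "deprioritized",
            f"exon-strength decrease {-delta_ri_total:.1f} bits < "
            f"{BENIGN_DELTA_RI_TOTAL:g} bits (8-fold); potentially benign")
    if rule.role == "acceptor-proofreader":
        where = ("acceptor proofreading affected"
                 if near_acceptor else
                 "repression outside the acceptor context")
        return SrfDecision("prioritized", f"hnRNPA1 {where}")
    return SrfDecision("prioritized",
                       f"{rule.factor} ({rule.role}) site change exceeds "
                       "contextual thresholds")
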