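"""RNA-binding-protein binding-site rules for UTR variants.

A UTR variant is flagged against an RBP model when (a) |delta Ri| >= 4.0
bits, or (b) it creates/strengthens a site across the Rsequence line
(Ri,final >= Rsequence with Ri,initial < Rsequence) — unless (c) the site
overlaps, or lies within 10 nt of, a stronger pre-existing site of a
different RBP (footprint-edge to footprint-edge, compared on the variant
sequence), in which case the stronger occupant wins and the flag is
suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .iminfo import InformationWeightMatrix, SiteChange, SiteScore

__all__ = ["RbpNeighborSite", "RbbsFlag", "flag_rbbs_variant"]

FLAG_BITS = 4.0
SUPPRESSION_DISTANCE_NT = 10


@dataclass(frozen=True)
class RbpNeighborSite:
    """A pre-existing site of another RBP near the candidate site."""

    factor: str
    score: SiteScore
    footprint: tuple[int, int]  # [start, end) on the variant sequence


@dataclass(frozen=True)
class RbbsFlag:
    factor: str
    flagged: bool
    clause: str  # "a" | "b" | ""
    suppressed_by: str | None
    reason: str


def _edge_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Footprint-edge to footprint-edge distance; 0 when overlapping."""
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def flag_rbbs_variant(change: SiteChange,
                      rbp_model: InformationWeightMatrix,
                      neighborhood_sites: list[RbpNeighborSite] = (),
                      in_utr: bool = True,
                      flag_bits: float = FLAG_BITS) -> RbbsFlag:
    """Apply the three-clause RBBS rule to one site change."""
    if not in_utr:
        raise ValueError("RBBS analysis applies to UTR variants only")
    factor = rbp_model.model_id
    rseq = rbp_model.r_sequence
    clause = ""
    if abs(change.delta_ri) >= flag_bits:
        clause = "a"
        reason = f"|delta Ri| = {abs(change.delta_ri):.1f} bits >= {flag_bits:g}"
    elif change.ri_final >= rseq and change.ri_initial < rseq:
        clause = "b"
        reason = (f"site created/strengthened across Rsequence "
                  f"({change.ri_initial:.1f} -> {change.ri_final:.1f} bits, "
                  f"Rsequence {rseq:.1f})")
    else:
        return RbbsFlag(factor, False, "", None, "below RBBS rules")
    # clause (c): suppression by a stronger pre-existing site of another RBP
    start = change.alt_score.position - rbp_model.offset
    footprint = (start, start + rbp_model.length)
    for other in neighborhood_sites:
        if other.factor == factor:
            continue
        # a pre-existing site must actually be a site (Ri > 0)
        if (other.score.ri > 0
                and _edge_distance(footprint, other.footprint)
                <= SUPPRESSION_DISTANCE_NT
                and other.score.ri > change.ri_final):
            return RbbsFlag(factor, False, clause, other.factor,
                            f"suppressed: stronger pre-existing "
                            f"{other.factor} site ({other.score.ri:.1f} bits) "
                            f"within {SUPPRESSION_DISTANCE_NT} nt")
    return RbbsFlag(factor, True, clause, None, reason)
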