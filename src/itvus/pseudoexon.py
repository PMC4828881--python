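"""Pseudoexon activation by deep-intronic variants.

A pseudoexon call requires all five conditions to hold:

1. the variant strengthens an intronic cryptic splice site by more than
   1.0 bit;
2. the activated site's final strength is at least Rsequence - 1 S.D. for
   its model (inclusive);
3. a pre-existing cryptic site of opposite polarity, with Ri strictly
   above Rsequence - 1 S.D., lies in the proper orientation to form an
   exon of 10-250 nt;
4. both intronic remnants flanking the pseudoexon are >= 100 nt;
5. a strong hnRNPA1 proofreading site (Ri >= its Rsequence) sits within
   10 nt of the pseudoexon acceptor.

Coordinates are in transcription orientation; the intron runs
[intron_start, intron_end) with the upstream exon ending at intron_start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .iminfo import (InformationWeightMatrix, SiteChange, SiteScore,
                     apply_variant, delta_ri, score_site)
from .splicing import ExonLengthDistribution, exon_definition

__all__ = ["PseudoexonConfig", "PseudoexonCall", "detect_pseudoexon"]


@dataclass
class PseudoexonConfig:
    min_delta_ri: float = 1.0          # strict >
    min_exon_length: int = 10
    max_exon_length: int = 250
    min_intronic_distance: int = 100
    hnrnpa1_max_distance: int = 10     # Methods value; 5 available by config


@dataclass
class PseudoexonCall:
    variant: tuple[int, str, str]
    activated_site: SiteChange
    activated_polarity: str
    partner_site: SiteScore
    pseudoexon_interval: tuple[int, int]
    lengths: tuple[int, int, int]      # new intron A / pseudoexon / new exon B
    hnrnpa1_site: SiteScore
    frameshift: bool
    ri_total: float
    alternates: list[tuple[SiteScore, float]] = field(default_factory=list)

    @property
    def lengths_str(self) -> str:
        a, p, b = self.lengths
        return f"{a}/{p}/{b}"


def _anchor_range(matrix: InformationWeightMatrix, vpos: int,
                  vlen: int) -> range:
    """Anchors whose footprint overlaps the edited bases."""
    lo = vpos - (matrix.length - matrix.offset) + 1
    hi = vpos + vlen + matrix.offset
    return range(lo, hi)


def _footprint(matrix: InformationWeightMatrix, anchor: int) -> tuple[int, int]:
    start = anchor - matrix.offset
    return start, start + matrix.length


def _strong_hnrnpa1_near(sequence: str, hn_model: InformationWeightMatrix,
                         acceptor_anchor: int, max_distance: int
                         ) -> SiteScore | None:
    """Strongest hnRNPA1 site (Ri >= its Rsequence) whose footprint edge is
    within ``max_distance`` nt of the acceptor boundary position."""
    best = None
    lo = acceptor_anchor - max_distance - hn_model.length + 1
    hi = acceptor_anchor + max_distance
    for anchor in range(lo + hn_model.offset, hi + hn_model.offset + 1):
        fs, fe = _footprint(hn_model, anchor)
        dist = max(fs - acceptor_anchor, acceptor_anchor - (fe - 1), 0)
        if dist > max_distance:
            continue
        try:
            s = score_site(sequence, hn_model, anchor)
        except ValueError:
            continue
        if s.ri >= hn_model.r_sequence and (best is None or s.ri > best.ri):
            best = s
    return best


def detect_pseudoexon(sequence: str, variant: tuple[int, str, str],
                      intron: tuple[int, int],
                      models: dict[str, InformationWeightMatrix],
                      length_dist: ExonLengthDistribution | None = None,
                      config: PseudoexonConfig | None = None
                      ) -> PseudoexonCall | None:
    """Return a PseudoexonCall if the five-part rule holds, else None.

    ``models`` must supply 'acceptor', 'donor' and 'hnrnpa1' IWMs. For
    PWM-derived splice models the S.D. defaults to 0 (threshold becomes
    Rsequence itself).
    """
    config = config or PseudoexonConfig()
    length_dist = length_dist or ExonLengthDistribution()
    vpos, ref, alt = variant
    intron_start, intron_end = intron
    if not (intron_start <= vpos and vpos + len(ref) <= intron_end):
        raise ValueError(
            f"variant at {vpos} is not inside intron [{intron_start}, "
            f"{intron_end})")
    alt_seq = apply_variant(sequence, vpos, ref, alt)
    shift = len(alt) - len(ref)

    acc, don, hn = models["acceptor"], models["donor"], models["hnrnpa1"]
    calls: list[PseudoexonCall] = []
    for polarity, model, partner_model in (("donor", don, acc),
                                           ("acceptor", acc, don)):
        threshold = model.r_sequence - model.r_sequence_sd
        p_threshold = partner_model.r_sequence - partner_model.r_sequence_sd
        for anchor in _anchor_range(model, vpos, len(ref)):
            fs, fe = _footprint(model, anchor)
            if fs < intron_start or fe > intron_end:
                continue
            try:
                change = delta_ri(sequence, variant, model, anchor)
            except ValueError:
                continue
            # (1) strict > 1 bit increase; (2) final >= Rseq - 1 SD
            if not (change.delta_ri > config.min_delta_ri):
                continue
            if not (change.ri_final >= threshold):
                continue
            site_anchor_alt = anchor if anchor <= vpos else anchor + shift
            # (3) pre-existing opposite-polarity partner forming a 10-250 nt
            # exon in the correct orientation (acceptor upstream of donor)
            candidates = []
            for plen in range(config.min_exon_length,
                              config.max_exon_length + 1):
                if polarity == "donor":
                    acc_anchor = site_anchor_alt - plen
                    don_anchor = site_anchor_alt
                    partner_anchor_alt = acc_anchor
                else:
                    acc_anchor = site_anchor_alt
                    don_anchor = site_anchor_alt + plen
                    partner_anchor_alt = don_anchor
                # partner must be pre-existing: score on the reference
                partner_anchor_ref = (partner_anchor_alt
                                      if partner_anchor_alt <= vpos
                                      else partner_anchor_alt - shift)
                pfs, pfe = _footprint(partner_model, partner_anchor_alt)
                intron_end_alt = intron_end + shift
                if pfs < intron_start or pfe > intron_end_alt:
                    continue
                try:
                    partner_ref = score_site(sequence, partner_model,
                                             partner_anchor_ref)
                    partner_alt = score_site(alt_seq, partner_model,
                                             partner_anchor_alt)
                except ValueError:
                    continue
                if not (partner_ref.ri > p_threshold):
                    continue
                # (4) intronic remnants >= 100 nt on both sides
                rem_a = acc_anchor - intron_start
                rem_b = intron_end_alt - don_anchor
                if (rem_a < config.min_intronic_distance
                        or rem_b < config.min_intronic_distance):
                    continue
                # (5) strong hnRNPA1 proofreading site near the acceptor
                hn_site = _strong_hnrnpa1_near(alt_seq, hn, acc_anchor,
                                               config.hnrnpa1_max_distance)
                if hn_site is None:
                    continue
                acc_score = (change.alt_score if polarity == "acceptor"
                             else partner_alt)
                don_score = (change.alt_score if polarity == "donor"
                             else partner_alt)
                acc_site = SiteScore(acc_anchor, "+", acc_score.ri,
                                     acc.model_id)
                don_site = SiteScore(don_anchor, "+", don_score.ri,
                                     don.model_id)
                exo = exon_definition(acc_site, don_site, length_dist)
                candidates.append((exo, partner_alt, hn_site,
                                   (rem_a, plen, rem_b)))
            if not candidates:
                continue
            candidates.sort(key=lambda c: -c[0].ri_total)
            exo, partner, hn_site, lengths = candidates[0]
            calls.append(PseudoexonCall(
                variant=variant,
                activated_site=change,
                activated_polarity=polarity,
                partner_site=partner,
                pseudoexon_interval=(exo.acceptor.position,
                                     exo.donor.position),
                lengths=lengths,
                hnrnpa1_site=hn_site,
                frameshift=(lengths[1] % 3 != 0),
                ri_total=exo.ri_total,
                alternates=[(c[1], c[0].ri_total) for c in candidates[1:]],
            ))
    if not calls:
        return None
    calls.sort(key=lambda c: -c.ri_total)
    return calls[0]
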