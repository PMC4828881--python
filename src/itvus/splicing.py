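"""Natural and cryptic splice-site analysis with exon-definition ranking.

An exon is "defined" by an acceptor/donor pair; its strength is
``ri_total = Ri(acceptor) + Ri(donor) - gap surprisal``, where the gap
surprisal penalizes exon lengths that are improbable under an exon-length
distribution (0 bits at the modal length). Candidate isoforms around an
affected exon are ranked by ri_total, with predicted relative abundance
proportional to 2**ri_total; a natural site whose strength falls below
Ri,minimum (1.6 bits by default) is considered non-functional, which
predicts exon skipping, while a weakened-but-functional site predicts
leaky splicing.

This module works in transcription orientation: sequences read 5'->3' on
the coding strand, the acceptor anchor on the first exon base and the
donor anchor on the first intron base after the exon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .iminfo import (InformationWeightMatrix, SiteChange, SiteScore,
                     apply_variant, scan_sequence, score_site)

__all__ = [
    "ExonLengthDistribution",
    "ExonDefinition",
    "IsoformPrediction",
    "SpliceFlag",
    "SpliceSiteInventory",
    "flag_natural_site_variant",
    "flag_cryptic_site_variant",
    "exon_definition",
    "rank_isoforms",
    "build_splice_inventory",
]

RI_MINIMUM_DEFAULT = 1.6  # bits; below this a site is non-functional
CRYPTIC_MAX_DISTANCE = 300  # nt from the nearest exon


class ExonLengthDistribution:
    """Exon-length probability model supplying the gap surprisal.

    The shipped default is a log-normal over internal exon lengths
    (median 120 nt, log-sd 0.7); an empirical table may be supplied
    instead. gap_surprisal(L) = -log2 P(L)/P(modal length) >= 0.
    """

    def __init__(self, mu: float = math.log(120.0), sigma: float = 0.7):
        self._mu = mu
        self._sigma = sigma
        self._table: dict[int, float] | None = None
        self._modal_p = self._pdf(self.modal_length)

    @classmethod
    def from_table(cls, probabilities: dict[int, float]) -> "ExonLengthDistribution":
        self = cls.__new__(cls)
        total = sum(probabilities.values())
        self._table = {int(k): v / total for k, v in probabilities.items()}
        self._mu = self._sigma = float("nan")
        self._modal_p = max(self._table.values())
        return self

    @property
    def modal_length(self) -> int:
        if self._table is not None:
            return max(self._table, key=self._table.get)
        return int(round(math.exp(self._mu - self._sigma**2)))

    def _pdf(self, length: float) -> float:
        return _stats.lognorm.pdf(length, s=self._sigma, scale=math.exp(self._mu))

    def probability(self, length: int) -> float:
        if length <= 0:
            raise ValueError("exon length must be positive")
        if self._table is not None:
            if length not in self._table:
                warnings.warn(
                    f"exon length {length} outside distribution support; "
                    "using tail value", stacklevel=3)
                return min(self._table.values())
            return self._table[length]
        return self._pdf(length)

    def gap_surprisal(self, length: int) -> float:
        return -math.log2(self.probability(length) / self._modal_p)


@dataclass(frozen=True)
class ExonDefinition:
    """An acceptor/donor pair and the exon strength it implies."""

    acceptor: SiteScore
    donor: SiteScore
    exon_length: int
    gap_surprisal: float
    ri_total: float

    def recompute(self) -> float:
        return self.acceptor.ri + self.donor.ri - self.gap_surprisal


def exon_definition(acceptor: SiteScore, donor: SiteScore,
                    length_dist: ExonLengthDistribution) -> ExonDefinition:
    """Exon strength of one acceptor/donor pair (transcription order)."""
    length = donor.position - acceptor.position
    if length <= 0:
        raise ValueError("acceptor must lie upstream of donor in "
                         "transcription order")
    gap = length_dist.gap_surprisal(length)
    return ExonDefinition(
        acceptor=acceptor, donor=donor, exon_length=length,
        gap_surprisal=gap, ri_total=acceptor.ri + donor.ri - gap,
    )


@dataclass(frozen=True)
class SpliceFlag:
    flagged: bool
    classification: str  # abolished | leaky | strengthened | minor-change |
    #                      cryptic-activated | not-flagged
    reason: str


def flag_natural_site_variant(change: SiteChange,
                              ri_minimum: float = RI_MINIMUM_DEFAULT) -> SpliceFlag:
    """Flag a variant at a natural splice site.

    Flagged when the site is weakened by >= 1.0 bits; classified abolished
    when the final strength falls below Ri,minimum (exon skipping
    expected), otherwise leaky.
    """
    if change.delta_ri <= -1.0:
        if change.ri_final < ri_minimum:
            return SpliceFlag(True, "abolished",
                              f"weakened {-change.delta_ri:.1f} bits; final "
                              f"{change.ri_final:.1f} < Ri,min {ri_minimum:g}")
        return SpliceFlag(True, "leaky",
                          f"weakened {-change.delta_ri:.1f} bits; final "
                          f"{change.ri_final:.1f} >= Ri,min {ri_minimum:g}")
    if change.delta_ri > 0:
        return SpliceFlag(False, "strengthened", "natural site strengthened")
    return SpliceFlag(False, "minor-change",
                      "weakening below the 1.0-bit reporting rule")


def flag_cryptic_site_variant(change: SiteChange,
                              natural_same_polarity: SiteScore,
                              distance_nt: int,
                              max_distance: int = CRYPTIC_MAX_DISTANCE
                              ) -> SpliceFlag:
    """Flag a strengthened cryptic site.

    Flagged iff the site is strengthened, lies within ``max_distance`` nt
    of the nearest exon, and its final strength is equivalent or greater
    than the nearest natural site of the same polarity.
    """
    if change.delta_ri <= 0:
        return SpliceFlag(False, "not-flagged", "cryptic site not strengthened")
    if distance_nt > max_distance:
        return SpliceFlag(False, "not-flagged",
                          f"distance {distance_nt} nt > {max_distance} nt")
    if change.ri_final < natural_same_polarity.ri:
        return SpliceFlag(False, "not-flagged",
                          f"final {change.ri_final:.1f} bits below natural "
                          f"site {natural_same_polarity.ri:.1f} bits")
    return SpliceFlag(True, "cryptic-activated",
                      f"strengthened to {change.ri_final:.1f} bits >= natural "
                      f"{natural_same_polarity.ri:.1f} bits at {distance_nt} nt")


@dataclass
class SpliceSiteInventory:
    """Natural and cryptic splice sites for one gene region."""

    natural_acceptors: list[SiteScore] = field(default_factory=list)
    natural_donors: list[SiteScore] = field(default_factory=list)
    cryptic_acceptors: list[SiteScore] = field(default_factory=list)
    cryptic_donors: list[SiteScore] = field(default_factory=list)

    def nearest_natural(self, polarity: str, position: int) -> SiteScore | None:
        sites = (self.natural_acceptors if polarity == "acceptor"
                 else self.natural_donors)
        if not sites:
            return None
        return min(sites, key=lambda s: abs(s.position - position))


def build_splice_inventory(sequence: str, exons: list[tuple[int, int]],
                           acceptor_model: InformationWeightMatrix,
                           donor_model: InformationWeightMatrix,
                           cryptic_flank: int = CRYPTIC_MAX_DISTANCE,
                           min_cryptic_ri: float = 0.0) -> SpliceSiteInventory:
    """Score natural sites at annotated exon boundaries and cryptic sites
    (Ri > ``min_cryptic_ri``) within ``cryptic_flank`` nt of any exon."""
    inv = SpliceSiteInventory()
    natural_anchors = set()
    for start, end in exons:
        try:
            inv.natural_acceptors.append(score_site(sequence, acceptor_model, start))
            natural_anchors.add(("acceptor", start))
        except ValueError:
            pass
        try:
            inv.natural_donors.append(score_site(sequence, donor_model, end))
            natural_anchors.add(("donor", end))
        except ValueError:
            pass
    for start, end in exons:
        lo, hi = start - cryptic_flank, end + cryptic_flank
        for model, polarity, out in (
            (acceptor_model, "acceptor", inv.cryptic_acceptors),
            (donor_model, "donor", inv.cryptic_donors),
        ):
            for s in scan_sequence(sequence, model, lo, hi, min_ri=min_cryptic_ri):
                if (polarity, s.position) not in natural_anchors:
                    out.append(s)
    return inv


@dataclass
class Isoform:
    exon: ExonDefinition
    rank: int
    relative_abundance: float
    uses_cryptic: bool


@dataclass
class IsoformPrediction:
    isoforms: list[Isoform]
    flags: set[str]
    wild_type_rank: int | None
    natural_change: dict[str, SiteChange] = field(default_factory=dict)

    @property
    def top(self) -> Isoform | None:
        return self.isoforms[0] if self.isoforms else None


def rank_isoforms(sequence: str, exon: tuple[int, int],
                  acceptor_model: InformationWeightMatrix,
                  donor_model: InformationWeightMatrix,
                  length_dist: ExonLengthDistribution | None = None,
                  variant: tuple[int, str, str] | None = None,
                  flank: int = CRYPTIC_MAX_DISTANCE,
                  ri_minimum: float = RI_MINIMUM_DEFAULT,
                  min_cryptic_ri: float = 0.0,
                  max_isoforms: int = 8) -> IsoformPrediction:
    """Enumerate and rank candidate exon definitions around one exon.

    Candidate acceptors/donors are the natural boundary sites plus all
    cryptic sites (Ri > ``min_cryptic_ri``) within ``flank`` nt of the
    exon, scored on the variant-bearing sequence when a variant is given.
    Isoforms are ranked by ri_total (ties: shorter exon first, then
    5'-most acceptor) and relative abundance is 2**ri_total normalized
    over the reported isoforms.
    """
    length_dist = length_dist or ExonLengthDistribution()
    start, end = exon
    alt_seq = sequence
    shift = 0
    if variant is not None:
        pos, ref, alt = variant
        alt_seq = apply_variant(sequence, pos, ref, alt)
        shift = len(alt) - len(ref)

    def shifted(anchor: int) -> int:
        if variant is not None and anchor > variant[0]:
            return anchor + shift
        return anchor

    flags: set[str] = set()
    natural_change: dict[str, SiteChange] = {}
    # natural boundary sites on ref and alt
    nat_scores = {}
    for polarity, model, anchor in (("acceptor", acceptor_model, start),
                                    ("donor", donor_model, end)):
        ref_s = score_site(sequence, model, anchor)
        alt_s = score_site(alt_seq, model, shifted(anchor))
        nat_scores[polarity] = (ref_s, alt_s)
        natural_change[polarity] = SiteChange(
            ref_score=ref_s, alt_score=alt_s, delta_ri=alt_s.ri - ref_s.ri)
        if alt_s.ri < ri_minimum:
            flags.add("exon_skipping")
        elif alt_s.ri - ref_s.ri <= -1.0:
            flags.add("leaky")

    lo, hi = start - flank, end + flank
    acceptors = {s.position: s for s in scan_sequence(
        alt_seq, acceptor_model, shifted(lo), shifted(hi), min_ri=min_cryptic_ri)}
    donors = {s.position: s for s in scan_sequence(
        alt_seq, donor_model, shifted(lo), shifted(hi), min_ri=min_cryptic_ri)}
    acceptors[shifted(start)] = nat_scores["acceptor"][1]
    donors[shifted(end)] = nat_scores["donor"][1]

    defs: list[ExonDefinition] = []
    for a in acceptors.values():
        for d in donors.values():
            if d.position > a.position:
                defs.append(exon_definition(a, d, length_dist))
    if not defs:
        flags.add("exon_skipping")
        return IsoformPrediction([], flags, None, natural_change)

    defs.sort(key=lambda e: (-e.ri_total, e.exon_length, e.acceptor.position))
    defs = defs[:max_isoforms]
    weights = np.array([e.ri_total for e in defs])
    w = np.exp2(weights - weights.max())
    w /= w.sum()
    wt_pair = (shifted(start), shifted(end))
    wt_rank = None
    isoforms = []
    for i, (e, ab) in enumerate(zip(defs, w), start=1):
        is_nat = (e.acceptor.position, e.donor.position) == wt_pair
        if is_nat:
            wt_rank = i
        isoforms.append(Isoform(exon=e, rank=i, relative_abundance=float(ab),
                                uses_cryptic=not is_nat))
    if isoforms and isoforms[0].uses_cryptic:
        flags.add("cryptic_use")
    return IsoformPrediction(isoforms, flags, wt_rank, natural_change)
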