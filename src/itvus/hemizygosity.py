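"""Cohort-based detection of candidate hemizygous (deleted) intervals.

A hemizygous deletion carrier shows an extended run with no heterozygous
calls where the rest of the cohort is polymorphic. The screen has two
stages: (1) per sample, find maximal genotype-silent stretches of at
least ``min_length`` nt with low repetitive content (<10%); (2) assess
each stretch against the rest of the cohort as controls — a candidate
requires strictly more than 80% of controls to be heterozygous at two or
more well-distributed loci inside the interval (pairwise separation at
least interval_length/10), and the interval must not lie inside a
supplied LD haploblock, where low heterozygosity is expected anyway.
Case-non-polymorphic loci are weighted by their expected heterozygosity
2*AF*(1-AF) into an aggregate informativeness score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

__all__ = ["CohortGenotypes", "HemizygosityCall",
           "find_nonpolymorphic_stretches", "assess_hemizygosity",
           "screen_cohort"]

MIN_STRETCH_LENGTH = 1000        # nt; deletions of interest are "usually >> 1 kb"
MAX_REPEAT_FRACTION = 0.10
CONTROL_SUPPORT_FRACTION = 0.8   # strict >
MIN_SUPPORT_LOCI = 2
MIN_CONTROLS = 10


@dataclass
class CohortGenotypes:
    """Genotypes of one cohort over the informative loci of a region.

    ``gt`` is (n_samples, n_loci) of alt-allele counts in {0, 1, 2};
    ``positions`` are 0-based locus coordinates, ``afs`` their population
    allele frequencies, ``region`` the captured [start, end) interval.
    """

    samples: list[str]
    positions: np.ndarray
    afs: np.ndarray
    gt: np.ndarray
    region: tuple[int, int]

    def het_positions(self, sample_idx: int) -> np.ndarray:
        return self.positions[self.gt[sample_idx] == 1]


@dataclass
class HemizygosityCall:
    sample: str
    interval: tuple[int, int]
    het_loci_in_controls: dict[str, int] = field(default_factory=dict)
    control_support_fraction: float = 0.0
    informativeness_weight: float = 0.0
    excluded_by_ld: bool = False
    verdict: str = "rejected"  # candidate | rejected | insufficient-controls

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def _repeat_fraction(interval: tuple[int, int],
                     repeat_mask: IntervalTree | None) -> float:
    if repeat_mask is None:
        return 0.0
    start, end = interval
    covered = 0
    for iv in repeat_mask.overlap(start, end):
        covered += min(iv.end, end) - max(iv.begin, start)
    return covered / (end - start)


def find_nonpolymorphic_stretches(
    het_positions: np.ndarray,
    region: tuple[int, int],
    min_length: int = MIN_STRETCH_LENGTH,
    repeat_mask: IntervalTree | None = None,
    max_repeat_fraction: float = MAX_REPEAT_FRACTION,
) -> list[tuple[int, int]]:
    """Maximal intervals of ``region`` with zero heterozygous calls,
    at least ``min_length`` nt long and with repeat content below the
    threshold."""
    start, end = region
    het = np.sort(np.asarray(het_positions, dtype=int))
    het = het[(het >= start) & (het < end)]
    edges = [start - 1] + [int(p) for p in het] + [end]
    out = []
    for a, b in zip(edges, edges[1:]):
        lo = a + 1
        if b - lo >= min_length \
                and _repeat_fraction((lo, b), repeat_mask) < max_repeat_fraction:
            out.append((lo, b))
    return out


def _well_distributed(het_pos: np.ndarray, min_separation: float) -> bool:
    """At least MIN_SUPPORT_LOCI het loci with adequate spread."""
    if het_pos.size < MIN_SUPPORT_LOCI:
        return False
    return (het_pos.max() - het_pos.min()) >= min_separation


def assess_hemizygosity(
    interval: tuple[int, int],
    sample: str,
    cohort: CohortGenotypes,
    ld_blocks: IntervalTree | None = None,
    min_controls: int = MIN_CONTROLS,
    support_threshold: float = CONTROL_SUPPORT_FRACTION,
) -> HemizygosityCall:
    """Assess one genotype-silent interval of one sample against controls."""
    case_idx = cohort.samples.index(sample)
    controls = [i for i in range(len(cohort.samples)) if i != case_idx]
    call = HemizygosityCall(sample=sample, interval=interval)
    if len(controls) < min_controls:
        call.verdict = "insufficient-controls"
        return call
    start, end = interval
    in_iv = (cohort.positions >= start) & (cohort.positions < end)
    min_sep = (end - start) / 10.0
    supporting = 0
    for ci in controls:
        het_pos = cohort.positions[in_iv & (cohort.gt[ci] == 1)]
        call.het_loci_in_controls[cohort.samples[ci]] = int(het_pos.size)
        if _well_distributed(het_pos, min_sep):
            supporting += 1
    call.control_support_fraction = supporting / len(controls)
    if ld_blocks is not None:
        call.excluded_by_ld = any(
            iv.begin <= start and end <= iv.end
            for iv in ld_blocks.overlap(start, end))
    case_nonpoly = in_iv & (cohort.gt[case_idx] != 1)
    call.informativeness_weight = float(
        (2.0 * cohort.afs * (1.0 - cohort.afs))[case_nonpoly].sum())
    if (call.control_support_fraction > support_threshold
            and not call.excluded_by_ld):
        call.verdict = "candidate"
    return call


def screen_cohort(
    cohort: CohortGenotypes,
    min_length: int = MIN_STRETCH_LENGTH,
    repeat_mask: IntervalTree | None = None,
    ld_blocks: IntervalTree | None = None,
    support_threshold: float = CONTROL_SUPPORT_FRACTION,
) -> list[HemizygosityCall]:
    """Run both stages for every sample; deterministic given genotypes."""
    calls = []
    for i, sample in enumerate(cohort.samples):
        stretches = find_nonpolymorphic_stretches(
            cohort.het_positions(i), cohort.region,
            min_length=min_length, repeat_mask=repeat_mask)
        for interval in stretches:
            calls.append(assess_hemizygosity(
                interval, sample, cohort, ld_blocks=ld_blocks,
                support_threshold=support_threshold))
    return calls
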