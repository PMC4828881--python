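"""Technical- and frequency-based pre-filters applied before any
information-theory analysis.

Variants with call quality below 50 are removed; common variants —
population allele frequency >= 1% or carried by more than 5 cohort
members — are set aside and not prioritized. Missing allele frequency is
treated as rare (novel variants are the point of the screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gio import CohortVariant

__all__ = ["FilterConfig", "technical_filter", "frequency_filter",
           "homopolymer_review_flag", "filter_report"]


@dataclass
class FilterConfig:
    min_qual: float = 50.0
    #: documentation only: upstream caller's per-base quality setting
    min_base_phred: int = 30
    max_population_af: float = 0.01
    max_cohort_carriers: int = 5

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_base_phred, self.max_population_af,
               self.max_cohort_carriers) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterOutcome:
    kept: list[CohortVariant] = field(default_factory=list)
    removed: list[tuple[CohortVariant, str]] = field(default_factory=list)


def technical_filter(variants: list[CohortVariant],
                     config: FilterConfig | None = None) -> FilterOutcome:
    """Remove variants with QUAL below the threshold (inclusive keep at
    the boundary); missing QUAL fails and is recorded."""
    config = config or FilterConfig()
    out = FilterOutcome()
    for v in variants:
        if v.qual is None:
            out.removed.append((v, "missing-qual"))
        elif v.qual < config.min_qual:
            out.removed.append((v, f"qual<{config.min_qual:g}"))
        else:
            out.kept.append(v)
    return out


def frequency_filter(variants: list[CohortVariant],
                     config: FilterConfig | None = None
                     ) -> tuple[list[CohortVariant], list[CohortVariant]]:
    """Partition into (rare, common).

    Common iff population AF >= 1% (inclusive) OR cohort carriers > 5
    (exclusive at 5). Missing AF counts as rare.
    """
    config = config or FilterConfig()
    rare, common = [], []
    for v in variants:
        af_common = (v.population_af is not None
                     and v.population_af >= config.max_population_af)
        carrier_common = v.carrier_count > config.max_cohort_carriers
        (common if af_common or carrier_common else rare).append(v)
    return rare, common


def homopolymer_review_flag(variant: CohortVariant, sequence: str,
                            min_run: int = 6) -> bool:
    """Manual-review recommendation: indel adjacent to a homopolymer run.

    No computable rule removes dephasing false positives; indel calls in or
    next to runs of >= ``min_run`` identical bases are flagged for IGV-style
    inspection instead.
    """
    if not variant.is_indel:
        return False
    pos = variant.pos
    lo = max(0, pos - min_run)
    hi = min(len(sequence), pos + len(variant.ref) + min_run)
    window = sequence[lo:hi].upper()
    run, prev = 1, ""
    for c in window:
        if c == prev:
            run += 1
            if run >= min_run:
                return True
        else:
            run, prev = 1, c
    return False


def filter_report(outcome: FilterOutcome,
                  common: list[CohortVariant]) -> pd.DataFrame:
    """TSV-shaped report: variant, stage, reason."""
    rows = []
    for v, reason in outcome.removed:
        rows.append((f"{v.chrom}:{v.pos1}{v.ref}>{v.alt}", "technical", reason))
    for v in common:
        rows.append((f"{v.chrom}:{v.pos1}{v.ref}>{v.alt}", "frequency", "common"))
    return pd.DataFrame(rows, columns=["variant", "stage", "reason"])
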