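"""End-to-end orchestration: filter funnel, per-category analyses,
aggregation and reports.

The workflow mirrors the study design: read cohort calls restricted to
the capture regions, remove low-quality and common variants, then push
every rare variant through the analyses its genomic context selects
(coding consequence, natural/cryptic splicing, pseudoexon, SRFBS, TFBS,
RBBS, UTR structure). Each analysis contributes category evidence
(flagged / prioritized with a machine-readable reason); a variant's
status is the strongest of its categories, optionally superseded by a
user-supplied override table emulating literature/pedigree evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import models as builtin
from .coding import annotate_coding, prioritize_truncation
from .gio import (CohortVariant, GeneModel, VcfReadStats,
                  annotate_population_af, read_af_table, read_bed,
                  read_cohort_vcf, read_factor_table, read_gene_models,
                  read_reference, write_vcf)
from .iminfo import InformationWeightMatrix, delta_ri, scan_sequence, score_site
from .pseudoexon import detect_pseudoexon
from .rbbs import RbpNeighborSite, flag_rbbs_variant
from .splicing import (ExonLengthDistribution, RI_MINIMUM_DEFAULT,
                       flag_cryptic_site_variant, flag_natural_site_variant,
                       rank_isoforms)
from .srfbs import SRF_MAX_EXON_DISTANCE, contextual_interpretation, flag_srf_variant
from .tfbs import flag_tfbs_variant, function_filter, promoter_region
from .utrstruct import get_engine, structure_disruption_rank
from .variant_filter import FilterConfig, frequency_filter, technical_filter

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PrioritizationRecord", "CategoryEvidence",
           "PipelineResult", "run_pipeline", "classify"]

CATEGORY_ORDER = ("indel", "nonsense", "missense", "natural_splicing",
                  "cryptic_splicing", "pseudoexon", "srf", "tf",
                  "utr_structure", "utr_binding")


@dataclass
class PipelineConfig:
    reference: str
    vcf: str
    genes: str
    capture_bed: str
    af_table: str | None = None
    factor_table: str | None = None
    out_dir: str | None = None
    engine: str = "auto"
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    ri_minimum: float = RI_MINIMUM_DEFAULT
    max_fold_length: int = 100     # local-range folding window for long UTRs
    utr_flag_p: float = 0.15       # flagged; prioritized needs p < 0.1
    overrides: dict[str, str] = field(default_factory=dict)
    skip_categories: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filt = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=filt, **raw)


@dataclass
class CategoryEvidence:
    flagged: bool
    prioritized: bool
    reason: str
    details: dict = field(default_factory=dict)


@dataclass
class PrioritizationRecord:
    variant: CohortVariant
    gene_id: str
    categories: dict[str, CategoryEvidence] = field(default_factory=dict)
    status: str = "dropped"
    reason_chain: list[str] = field(default_factory=list)

    @property
    def flagged_categories(self) -> list[str]:
        return [c for c in CATEGORY_ORDER
                if c in self.categories and self.categories[c].flagged]

    @property
    def prioritized_categories(self) -> list[str]:
        return [c for c in CATEGORY_ORDER
                if c in self.categories and self.categories[c].prioritized]


@dataclass
class PipelineResult:
    records: list[PrioritizationRecord]
    funnel: dict[str, int]
    per_sample: pd.DataFrame
    count_matrix: pd.DataFrame
    variant_table: pd.DataFrame
    common: list[CohortVariant] = field(default_factory=list)


def _variant_id(v: CohortVariant) -> str:
    return f"{v.chrom}:{v.pos1}{v.ref}>{v.alt}"


def dual_method_background_rate(n_prioritized_both: int,
                                n_total: int) -> float:
    """Background rate, in percent, of variants prioritized by both UTR
    methods (structure ranking and RBP information models) in a screen of
    ``n_total`` candidate substitutions."""
    if n_total <= 0:
        raise ValueError("screen size must be positive")
    return 100.0 * n_prioritized_both / n_total


def classify(record: PrioritizationRecord,
             overrides: dict[str, str] | None = None) -> str:
    """Aggregate category evidence into flagged/prioritized/dropped; a
    user override (pathogenic/benign) supersedes the computed status."""
    override = (overrides or {}).get(_variant_id(record.variant))
    if override == "benign":
        record.status = "dropped"
        record.reason_chain.append("override: benign")
    elif override == "pathogenic":
        record.status = "prioritized"
        record.reason_chain.append("override: pathogenic")
    elif record.prioritized_categories:
        record.status = "prioritized"
    elif record.flagged_categories:
        record.status = "flagged"
    else:
        record.status = "dropped"
    return record.status


# ---------------------------------------------------------------------------
# per-category analyses (all in transcription frame, plus strand)
# ---------------------------------------------------------------------------

def _anchors_covering(model: InformationWeightMatrix, pos: int,
                      ref_len: int) -> range:
    lo = pos - (model.length - model.offset) + 1
    hi = pos + ref_len + model.offset
    return range(lo, hi)


def _all_changes(seq: str, variant, model: InformationWeightMatrix,
                 allowed=None) -> list[tuple[int, object]]:
    """Site changes at every anchor whose footprint covers the variant.

    Each anchor is a distinct potential site of the factor; the flagging
    rules are applied per site, not only at the largest-|delta| anchor.
    """
    out = []
    for anchor in _anchors_covering(model, variant[0], len(variant[1])):
        if allowed is not None and not allowed(anchor):
            continue
        try:
            out.append((anchor, delta_ri(seq, variant, model, anchor)))
        except ValueError:
            continue
    return out


def _exon_distance(gene: GeneModel, pos: int) -> int:
    d = []
    for s, e in gene.exons:
        if s <= pos < e:
            return 0
        d.append(min(abs(pos - s), abs(pos - (e - 1))))
    return min(d)


def _nearest_exon(gene: GeneModel, pos: int) -> tuple[int, int]:
    return min(gene.exons, key=lambda ex: 0 if ex[0] <= pos < ex[1]
               else min(abs(pos - ex[0]), abs(pos - ex[1])))


def _rbp_neighbors(alt_seq: str, rbp_models: dict, name: str, anchor: int,
                   model: InformationWeightMatrix) -> list[RbpNeighborSite]:
    """Pre-existing sites of other RBPs near one candidate site, scored on
    the variant sequence (for the RBBS suppression clause)."""
    neighbors = []
    for other, om in rbp_models.items():
        if other == name:
            continue
        lo = anchor - model.offset - 10 - om.length
        hi = anchor - model.offset + model.length + 10 + om.length
        for s in scan_sequence(alt_seq, om, lo + om.offset, hi + om.offset,
                               min_ri=0.0):
            fs = s.position - om.offset
            neighbors.append(RbpNeighborSite(
                factor=other, score=s, footprint=(fs, fs + om.length)))
    return neighbors


class _Analyzer:
    """All per-variant analyses for one gene on one chromosome."""

    def __init__(self, gene: GeneModel, chrom_seq: str, models: dict,
                 factor_roles: dict[str, str], config: PipelineConfig):
        if gene.strand != "+":
            raise NotImplementedError(
                "pipeline analyses run in transcription frame; minus-strand "
                "gene models are not supported by this orchestrator")
        self.gene = gene
        self.seq = chrom_seq
        self.models = models
        self.roles = factor_roles
        self.config = config
        self.length_dist = ExonLengthDistribution()
        self._engine = None
        self.acc = models["splice"]["acceptor"]
        self.don = models["splice"]["donor"]
        self._natural = {"acceptor": [s for s, _ in gene.exons[1:]],
                         "donor": [e for _, e in gene.exons[:-1]]}

    @property
    def engine(self):
        if self._engine is None:
            self._engine = get_engine(self.config.engine)
        return self._engine

    def analyze(self, v: CohortVariant) -> dict[str, CategoryEvidence]:
        variant = (v.pos, v.ref, v.alt)
        region = self.gene.region_of(v.pos)
        out: dict[str, CategoryEvidence] = {}
        skip = set(self.config.skip_categories)

        def run(name, fn, *args):
            if name in skip:
                return
            try:
                ev = fn(*args)
            except Exception as exc:
                logger.warning("%s analysis failed for %s: %s", name,
                               _variant_id(v), exc)
                return
            if ev is not None:
                if isinstance(ev, dict):
                    out.update(ev)
                else:
                    out[name] = ev

        if region == "cds":
            run("coding", self._coding, v)
        run("natural_splicing", self._natural_splice, variant)
        run("cryptic_splicing", self._cryptic_splice, variant)
        if region == "intron":
            run("pseudoexon", self._pseudoexon, variant)
        if _exon_distance(self.gene, v.pos) <= SRF_MAX_EXON_DISTANCE:
            run("srf", self._srf, variant, region)
        promoter = promoter_region(self.gene)
        if promoter.contains(v.pos):
            run("tf", self._tf, variant)
        if region in ("utr5", "utr3"):
            run("utr_binding", self._rbbs, variant)
            run("utr_structure", self._utr_structure, v, region)
        return out

    # -- coding ------------------------------------------------------------
    def _coding(self, v: CohortVariant) -> dict[str, CategoryEvidence] | None:
        class _Ref:
            def __init__(self, chrom, seq):
                self._c, self._s = chrom, seq

            def sequence(self, chrom):
                if chrom != self._c:
                    raise KeyError(chrom)
                return self._s

        cons = annotate_coding(v, self.gene, _Ref(v.chrom, self.seq))
        if cons is None:
            return None
        decision = prioritize_truncation(cons)
        category = {"nonsense": "nonsense",
                    "frameshift_indel": "indel",
                    "inframe_indel": "indel",
                    "missense": "missense"}.get(cons.consequence)
        if category is None:  # synonymous: routed onward to SRF analysis
            return None
        details = {"consequence": cons.consequence,
                   "stop_codon_position": cons.stop_codon_position,
                   "residues_lost": cons.residues_lost}
        return {category: CategoryEvidence(
            flagged=True, prioritized=decision.prioritized,
            reason=decision.reason, details=details)}

    # -- splicing ----------------------------------------------------------
    def _natural_splice(self, variant) -> CategoryEvidence | None:
        best = None
        for polarity, model in (("acceptor", self.acc), ("donor", self.don)):
            for anchor in self._natural[polarity]:
                if anchor not in _anchors_covering(model, variant[0],
                                                   len(variant[1])):
                    continue
                change = delta_ri(self.seq, variant, model, anchor)
                flag = flag_natural_site_variant(change,
                                                 self.config.ri_minimum)
                if best is None or flag.flagged:
                    best = (flag, change, polarity, anchor)
        if best is None:
            return None
        flag, change, polarity, anchor = best
        return CategoryEvidence(
            flagged=flag.flagged, prioritized=flag.flagged,
            reason=f"{polarity} {flag.classification}: {flag.reason}",
            details={"ri_initial": change.ri_initial,
                     "ri_final": change.ri_final,
                     "delta_ri": change.delta_ri,
                     "classification": flag.classification})

    def _cryptic_splice(self, variant) -> CategoryEvidence | None:
        distance = _exon_distance(self.gene, variant[0])
        best = None
        for polarity, model in (("acceptor", self.acc), ("donor", self.don)):
            naturals = self._natural[polarity]
            for anchor, change in _all_changes(self.seq, variant, model,
                                               allowed=lambda a: a not in naturals):
                nearest = min(naturals, key=lambda a: abs(a - anchor))
                natural_score = score_site(self.seq, model, nearest)
                flag = flag_cryptic_site_variant(change, natural_score,
                                                 distance)
                if (best is None
                        or (flag.flagged, abs(change.delta_ri))
                        > (best[0].flagged, abs(best[1].delta_ri))):
                    best = (flag, change, polarity)
        if best is None:
            return None
        flag, change, polarity = best
        prioritized = False
        if flag.flagged:
            exon = _nearest_exon(self.gene, variant[0])
            pred = rank_isoforms(self.seq, exon, self.acc, self.don,
                                 self.length_dist, variant=variant)
            prioritized = pred.top is not None and pred.top.uses_cryptic
        return CategoryEvidence(
            flagged=flag.flagged, prioritized=prioritized,
            reason=f"{polarity}: {flag.reason}",
            details={"delta_ri": change.delta_ri,
                     "ri_final": change.ri_final})

    def _pseudoexon(self, variant) -> CategoryEvidence | None:
        intron = next((iv for iv in self.gene.introns()
                       if iv[0] <= variant[0] < iv[1]), None)
        if intron is None:
            return None
        models = {"acceptor": self.acc, "donor": self.don,
                  "hnrnpa1": self.models["srf"]["hnRNPA1"]}
        call = detect_pseudoexon(self.seq, variant, intron, models,
                                 self.length_dist)
        if call is None:
            return None
        return CategoryEvidence(
            flagged=True, prioritized=True,
            reason=f"pseudoexon {call.lengths_str}"
                   f"{' (frameshift)' if call.frameshift else ''}",
            details={"lengths": call.lengths, "frameshift": call.frameshift,
                     "ri_total": call.ri_total})

    # -- regulatory sites ---------------------------------------------------
    def _srf(self, variant, region) -> CategoryEvidence | None:
        distance = _exon_distance(self.gene, variant[0])
        variant_region = "exonic" if distance == 0 else "intronic"
        best = None
        for name in builtin.SRF_FACTORS:
            model = self.models["srf"][name]
            flagged_hits = []
            for anchor, change in _all_changes(self.seq, variant, model):
                f = flag_srf_variant(change, model, distance)
                if f.flagged:
                    flagged_hits.append((abs(change.delta_ri), anchor,
                                         change, f))
            if not flagged_hits:
                continue
            _, anchor, change, flag = max(flagged_hits, key=lambda h: h[0])
            rule = builtin.SRF_CONTEXT_RULES[name]
            exon = _nearest_exon(self.gene, variant[0])
            from .splicing import exon_definition
            from .iminfo import SiteScore
            nat_delta = 0.0
            for pol, mdl, a in (("acceptor", self.acc, exon[0]),
                                ("donor", self.don, exon[1])):
                try:
                    ch = delta_ri(self.seq, variant, mdl, a)
                    nat_delta += ch.delta_ri
                except ValueError:
                    pass
            factor_term = (change.delta_ri
                           if rule.role in ("enhancer", "enhancer-intronic",
                                            "acceptor-proofreader")
                           else -change.delta_ri)
            delta_ri_total = nat_delta + factor_term
            near_acc = any(abs(variant[0] - a) <= 10
                           for a in self._natural["acceptor"])
            # other same-factor site changes near the variant, for the
            # redundant-site rule
            redundant = []
            for a2 in _anchors_covering(model, variant[0], len(variant[1])):
                if a2 == anchor:
                    continue
                try:
                    redundant.append(delta_ri(self.seq, variant, model, a2))
                except ValueError:
                    pass
            decision = contextual_interpretation(
                flag, change, rule, delta_ri_total=delta_ri_total,
                variant_region=variant_region, redundant_sites=redundant,
                near_acceptor=near_acc)
            cand = (decision.decision == "prioritized", name, flag, change,
                    decision, delta_ri_total)
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            return None
        _, name, flag, change, decision, drt = best
        return CategoryEvidence(
            flagged=True, prioritized=decision.decision == "prioritized",
            reason=f"{name}: {flag.reason}; {decision.reason}",
            details={"factor": name, "delta_ri": change.delta_ri,
                     "delta_ri_total": drt, "decision": decision.decision})

    def _tf(self, variant) -> CategoryEvidence | None:
        best = None
        for name in builtin.TF_FACTORS:
            model = self.models["tf"][name]
            lo = variant[0] - 50
            hi = variant[0] + len(variant[1]) + 50
            covering = set(_anchors_covering(model, variant[0],
                                             len(variant[1])))
            local = [s for s in scan_sequence(self.seq, model, lo, hi)
                     if s.position not in covering]
            flagged_hits = []
            for anchor, change in _all_changes(self.seq, variant, model):
                f = flag_tfbs_variant(change, model, local)
                if f.flagged:
                    flagged_hits.append((abs(change.delta_ri), anchor,
                                         change, f))
            if not flagged_hits:
                continue
            _, anchor, change, flag = max(flagged_hits, key=lambda h: h[0])
            role = self.roles.get(name)
            keep, why = function_filter(flag, change, role)
            cand = (keep, name, flag, change, why)
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            return None
        keep, name, flag, change, why = best
        return CategoryEvidence(
            flagged=True, prioritized=keep,
            reason=f"{name} {flag.kind}: {flag.reason}; {why}",
            details={"factor": name, "delta_ri": change.delta_ri,
                     "kind": flag.kind})

    def _rbbs(self, variant) -> CategoryEvidence | None:
        alt_seq = (self.seq[:variant[0]] + variant[2]
                   + self.seq[variant[0] + len(variant[1]):])
        best = None
        for name in builtin.RBP_FACTORS:
            model = self.models["rbp"][name]
            for anchor, change in _all_changes(self.seq, variant, model):
                neighbors = _rbp_neighbors(alt_seq, self.models["rbp"], name,
                                           anchor, model)
                flag = flag_rbbs_variant(change, model, neighbors)
                cand = (flag.flagged, abs(change.delta_ri), name, flag,
                        change)
                if best is None or cand[:2] > best[:2]:
                    best = cand
        if best is None:
            return None
        flagged, _, name, flag, change = best
        return CategoryEvidence(
            flagged=flagged, prioritized=flagged,
            reason=f"{name}: {flag.reason}",
            details={"factor": name, "delta_ri": change.delta_ri,
                     "clause": flag.clause,
                     "suppressed_by": flag.suppressed_by})

    def _utr_structure(self, v: CohortVariant, region) -> CategoryEvidence | None:
        if v.is_indel:
            return None  # substitutions only, as in the rank statistic
        intervals = self.gene.utr5 if region == "utr5" else self.gene.utr3
        iv = next((x for x in intervals if x[0] <= v.pos < x[1]), None)
        if iv is None:
            return None
        lo, hi = iv
        mode = "long-range"
        if hi - lo > self.config.max_fold_length:
            mode = "local"
            half = self.config.max_fold_length // 2
            lo = max(iv[0], v.pos - half)
            hi = min(iv[1], lo + self.config.max_fold_length)
            lo = max(iv[0], hi - self.config.max_fold_length)
        utr_seq = self.seq[lo:hi]
        rank = structure_disruption_rank(utr_seq, (v.pos - lo, v.ref, v.alt),
                                         self.engine)
        flagged = rank.p_value <= self.config.utr_flag_p
        return CategoryEvidence(
            flagged=flagged, prioritized=rank.prioritized,
            reason=f"structure rank {rank.rank}/{rank.total} "
                   f"(p={rank.p_value:.3f}, {mode})",
            details={"rank": rank.rank, "total": rank.total,
                     "p_value": rank.p_value, "mode": mode})


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _load_models() -> dict:
    return {"splice": builtin.splice_models(), "srf": builtin.srf_models(),
            "tf": builtin.tf_models(), "rbp": builtin.rbp_models()}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full funnel and emit reports (TSVs and an annotated VCF
    under ``config.out_dir`` when given)."""
    ref = read_reference(config.reference)
    regions = read_bed(config.capture_bed)
    stats = VcfReadStats()
    variants = read_cohort_vcf(config.vcf, regions, stats)
    if config.af_table:
        annotate_population_af(variants, read_af_table(config.af_table))
    genes = read_gene_models(config.genes)
    roles: dict[str, str] = dict(builtin.TF_ROLES)
    if config.factor_table:
        df = read_factor_table(config.factor_table)
        roles.update({r.factor: r.role for r in df.itertuples()
                      if r.klass == "TF"})
    models = _load_models()

    tech = technical_filter(variants, config.filter)
    rare, common = frequency_filter(tech.kept, config.filter)

    analyzers: dict[str, _Analyzer] = {}
    records: list[PrioritizationRecord] = []
    for v in sorted(rare, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        gene = next((g for g in genes if g.chrom == v.chrom
                     and g.span[0] - 11_000 <= v.pos < g.span[1] + 1_000), None)
        rec = PrioritizationRecord(variant=v,
                                   gene_id=gene.gene_id if gene else "")
        if gene is not None:
            if gene.gene_id not in analyzers:
                analyzers[gene.gene_id] = _Analyzer(
                    gene, ref.sequence(gene.chrom), models, roles, config)
            rec.categories = analyzers[gene.gene_id].analyze(v)
        classify(rec, config.overrides)
        records.append(rec)

    funnel = {
        "input_records": stats.total,
        "in_region": stats.total - stats.excluded_by_region - stats.malformed,
        "post_technical": len(tech.kept),
        "rare": len(rare),
        "flagged": sum(1 for r in records
                       if r.status in ("flagged", "prioritized")),
        "prioritized": sum(1 for r in records if r.status == "prioritized"),
    }

    samples = sorted({s for v in variants for s in v.genotypes})
    rare_keys = {r.variant.key for r in records}
    prio_keys = {r.variant.key for r in records if r.status == "prioritized"}
    per_sample = pd.DataFrame([
        {"sample": s,
         "total": sum(1 for v in variants if v.genotypes.get(s)),
         "post_filter": sum(1 for v in rare
                            if v.key in rare_keys and v.genotypes.get(s)),
         "prioritized": sum(1 for v in rare
                            if v.key in prio_keys and v.genotypes.get(s))}
        for s in samples])

    gene_ids = sorted({g.gene_id for g in genes})
    matrix = pd.DataFrame(0, index=gene_ids,
                          columns=list(CATEGORY_ORDER) + ["total"])
    for r in records:
        if not r.gene_id or r.status == "dropped":
            continue
        for c in r.flagged_categories:
            matrix.loc[r.gene_id, c] += 1
        if r.flagged_categories:
            matrix.loc[r.gene_id, "total"] += 1

    rows = []
    for r in records:
        rows.append({
            "variant": _variant_id(r.variant),
            "gene": r.gene_id,
            "qual": r.variant.qual,
            "carriers": r.variant.carrier_count,
            "population_af": r.variant.population_af,
            "status": r.status,
            "categories": ",".join(r.flagged_categories),
            "prioritized_categories": ",".join(r.prioritized_categories),
            "reasons": " | ".join(
                f"{c}:{r.categories[c].reason}"
                for c in CATEGORY_ORDER if c in r.categories
                and r.categories[c].flagged) or ".",
        })
    variant_table = pd.DataFrame(rows)

    result = PipelineResult(records=records, funnel=funnel,
                            per_sample=per_sample, count_matrix=matrix,
                            variant_table=variant_table, common=common)
    if config.out_dir:
        _write_reports(result, variants, ref, config)
    return result


def _write_reports(result: PipelineResult, variants, ref,
                   config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.variant_table.to_csv(out / "variants.tsv", sep="\t", index=False,
                                float_format="%.4g")
    result.count_matrix.to_csv(out / "count_matrix.tsv", sep="\t")
    result.per_sample.to_csv(out / "per_sample.tsv", sep="\t", index=False)
    pd.Series(result.funnel).to_csv(out / "funnel.tsv", sep="\t",
                                    header=False)
    info = {}
    for r in result.records:
        tags = {"ITV_STATUS": r.status}
        if r.flagged_categories:
            tags["ITV_CATEGORIES"] = ",".join(r.flagged_categories)
        info[r.variant.key] = tags
    contigs = {c: len(ref.sequence(c)) for c in ref.contigs()}
    write_vcf(out / "annotated.vcf", variants, contigs, info_tags=info)
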