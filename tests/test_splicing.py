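"""Splice-site flagging and exon-definition isoform ranking."""

import math

import numpy as np
import pytest

from itvus.iminfo import SiteChange, SiteScore, delta_ri, fold_change, score_site
from itvus.splicing import (ExonLengthDistribution, exon_definition,
                            flag_cryptic_site_variant,
                            flag_natural_site_variant, rank_isoforms)


def change(ri_initial, ri_final, position=1000):
    return SiteChange(
        ref_score=SiteScore(position, "+", ri_initial),
        alt_score=SiteScore(position, "+", ri_final),
        delta_ri=ri_final - ri_initial)


class TestNaturalSiteRule:
    def test_abolished_acceptor(self):
        # an 11.0 -> 0.1 bit collapse is flagged and classified abolished
        flag = flag_natural_site_variant(change(11.0, 0.1))
        assert flag.flagged and flag.classification == "abolished"

    def test_leaky_acceptor(self):
        # 6.8 -> 4.1 bits: weakened but still above Ri,minimum
        flag = flag_natural_site_variant(change(6.8, 4.1))
        assert flag.flagged and flag.classification == "leaky"

    def test_sub_one_bit_weakening_not_flagged(self):
        assert not flag_natural_site_variant(change(8.0, 7.5)).flagged

    def test_exact_one_bit_weakening_flagged(self):
        assert flag_natural_site_variant(change(8.0, 7.0)).flagged

    def test_ri_minimum_configurable(self):
        flag = flag_natural_site_variant(change(6.8, 4.1), ri_minimum=5.0)
        assert flag.classification == "abolished"


class TestCrypticSiteRule:
    def test_strengthened_beyond_natural_flagged(self):
        # cryptic 3.9 -> 9.4 bits vs a 6.9-bit natural site at 245 nt
        natural = SiteScore(0, "+", 6.9)
        flag = flag_cryptic_site_variant(change(3.9, 9.4), natural, 245)
        assert flag.flagged

    def test_distance_rule(self):
        natural = SiteScore(0, "+", 6.9)
        assert not flag_cryptic_site_variant(change(3.9, 9.4), natural,
                                             400).flagged

    def test_weaker_than_natural_not_flagged(self):
        natural = SiteScore(0, "+", 11.0)
        assert not flag_cryptic_site_variant(change(3.9, 9.4), natural,
                                             100).flagged

    def test_weakened_cryptic_not_flagged(self):
        natural = SiteScore(0, "+", 2.0)
        assert not flag_cryptic_site_variant(change(9.4, 3.9), natural,
                                             100).flagged


class TestExonDefinition:
    def test_modal_length_has_zero_gap_surprisal(self):
        dist = ExonLengthDistribution()
        modal = dist.modal_length
        acc = SiteScore(1000, "+", 8.0)
        don = SiteScore(1000 + modal, "+", 6.0)
        exo = exon_definition(acc, don, dist)
        assert exo.gap_surprisal == pytest.approx(0.0, abs=1e-9)
        assert exo.ri_total == pytest.approx(14.0)

    def test_ri_total_recomputable(self):
        dist = ExonLengthDistribution()
        exo = exon_definition(SiteScore(0, "+", 8.0),
                              SiteScore(57, "+", 6.0), dist)
        assert exo.ri_total == pytest.approx(exo.recompute(), abs=1e-9)

    def test_exon_strength_drop_implies_fold_change(self):
        # a 14.5 -> 3.6 bit exon-strength drop is a ~1910-fold decrease
        fold = fold_change(3.6 - 14.5)
        assert fold.direction == "reduction"
        assert float(f"{fold.fold:.3g}") == 1910

    def test_gap_surprisal_table_oracle(self):
        table = {50: 0.2, 100: 0.5, 150: 0.3}
        dist = ExonLengthDistribution.from_table(table)
        for length, p in table.items():
            assert dist.gap_surprisal(length) == pytest.approx(
                -math.log2(p / 0.5))
        with pytest.warns(UserWarning, match="outside"):
            tail = dist.gap_surprisal(400)
        assert tail == pytest.approx(-math.log2(0.2 / 0.5))

    def test_wrong_order_rejected(self):
        with pytest.raises(ValueError):
            exon_definition(SiteScore(100, "+", 1.0), SiteScore(50, "+", 1.0),
                            ExonLengthDistribution())


@pytest.fixture()
def mini_gene(models, rng):
    """One internal exon with planted acceptor/donor in random background."""
    acc, don = models["acceptor"], models["donor"]
    exon = (400, 520)
    seq = list(rng.choice(list("ACGT"), size=1000))
    for i, c in enumerate(acc.consensus()):
        seq[exon[0] - acc.offset + i] = c
    for i, c in enumerate(don.consensus()):
        seq[exon[1] - don.offset + i] = c
    return "".join(seq), exon


class TestIsoformRanking:
    def test_wild_type_ranks_first_without_variant(self, models, mini_gene):
        seq, exon = mini_gene
        pred = rank_isoforms(seq, exon, models["acceptor"], models["donor"])
        assert pred.wild_type_rank == 1
        assert not pred.top.uses_cryptic

    def test_abundances_normalize_and_follow_ri_total(self, models,
                                                      mini_gene):
        seq, exon = mini_gene
        pred = rank_isoforms(seq, exon, models["acceptor"], models["donor"])
        ab = [i.relative_abundance for i in pred.isoforms]
        assert sum(ab) == pytest.approx(1.0, abs=1e-6)
        ris = [i.exon.ri_total for i in pred.isoforms]
        assert ris == sorted(ris, reverse=True)

    def test_abolishing_acceptor_flags_skipping(self, models, study):
        """The planted natural-site variant abolishes its acceptor and
        predicts skipping of the affected exon."""
        gene = study.gene.gene
        planted = next(p for p in study.planted
                       if p.category == "natural_splicing")
        exon = next(ex for ex in gene.exons
                    if abs(ex[0] - planted.pos) <= 13)
        pred = rank_isoforms(study.gene.sequence, exon, models["acceptor"],
                             models["donor"],
                             variant=(planted.pos, planted.ref, planted.alt))
        assert "exon_skipping" in pred.flags

    def test_reverting_variant_restores_wild_type(self, models, mini_gene):
        seq, exon = mini_gene
        variant = (exon[0] - 2, seq[exon[0] - 2], "C")
        before = rank_isoforms(seq, exon, models["acceptor"], models["donor"])
        edited = seq[:variant[0]] + "C" + seq[variant[0] + 1:]
        restored = rank_isoforms(edited, exon, models["acceptor"],
                                 models["donor"],
                                 variant=(variant[0], "C", variant[1]))
        assert restored.top.exon.acceptor.position \
            == before.top.exon.acceptor.position
        assert restored.top.exon.ri_total \
            == pytest.approx(before.top.exon.ri_total, abs=1e-9)

    def test_equal_ri_total_ties_split_abundance_equally(self, models, rng):
        """Two identical acceptors at equally probable lengths tie; the
        shorter exon is ranked first by convention."""
        acc, don = models["acceptor"], models["donor"]
        dist = ExonLengthDistribution.from_table({100: 0.5, 140: 0.5})
        seq = list("A" * 900)
        donor_pos = 600
        for i, c in enumerate(don.consensus()):
            seq[donor_pos - don.offset + i] = c
        for start in (donor_pos - 140, donor_pos - 100):
            for i, c in enumerate(acc.consensus()):
                seq[start - acc.offset + i] = c
        pred = rank_isoforms("".join(seq), (donor_pos - 140, donor_pos),
                             acc, don, length_dist=dist, max_isoforms=2)
        top, second = pred.isoforms[0], pred.isoforms[1]
        assert top.exon.ri_total == pytest.approx(second.exon.ri_total)
        assert top.relative_abundance == pytest.approx(0.5, abs=1e-6)
        assert top.exon.exon_length < second.exon.exon_length

    def test_sub_one_bit_perturbations_never_flagged(self, models,
                                                     mini_gene):
        seq, exon = mini_gene
        acc = models["acceptor"]
        # a change at the weakly conserved exonic position of the motif
        col = acc.offset  # first exon base, conservation ~0.5
        ris = np.sort(acc.riw[col])[::-1]
        pos = exon[0]
        base_now = seq[pos]
        for alt in "ACGT":
            if alt == base_now:
                continue
            ch = delta_ri(seq, (pos, base_now, alt), acc, exon[0])
            if abs(ch.delta_ri) < 1.0:
                assert not flag_natural_site_variant(ch).flagged
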