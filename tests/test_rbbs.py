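"""RNA-binding-protein binding-site rules in UTRs."""

import numpy as np
import pytest

from itvus.iminfo import (InformationWeightMatrix, SiteChange, SiteScore,
                          reverse_complement, scan_sequence, score_site)
from itvus.rbbs import RbpNeighborSite, flag_rbbs_variant


def fake_model(rsequence, factor="RBFOX", length=6):
    return InformationWeightMatrix(riw=np.zeros((length, 4)),
                                   r_sequence=rsequence, model_id=factor)


def change(ri_initial, ri_final, position=100):
    return SiteChange(SiteScore(position, "+", ri_initial),
                      SiteScore(position, "+", ri_final),
                      ri_final - ri_initial)


class TestFlagClauses:
    def test_large_decrease_flagged_clause_a(self):
        # an RBFOX site collapsing 9.8 -> -19.9 bits
        flag = flag_rbbs_variant(change(9.8, -19.9), fake_model(8.8))
        assert flag.flagged and flag.clause == "a"

    def test_site_created_across_rsequence_clause_b(self):
        # SF3B4 3.3 -> 11.4 bits crossing its Rsequence
        flag = flag_rbbs_variant(change(3.3, 11.4, position=100),
                                 fake_model(10.0, "SF3B4"))
        assert flag.flagged  # also satisfies |delta| >= 4 (clause a)
        small = flag_rbbs_variant(change(8.0, 10.5), fake_model(10.0))
        assert small.flagged and small.clause == "b"

    def test_below_both_clauses_not_flagged(self):
        flag = flag_rbbs_variant(change(5.0, 7.0), fake_model(10.0))
        assert not flag.flagged

    def test_suppressed_by_stronger_neighbor(self):
        # qualifying change 8 nt from a stronger pre-existing site of a
        # different RBP is suppressed under clause (c)
        model = fake_model(8.8)
        other = RbpNeighborSite("CELF4", SiteScore(114, "+", 12.0),
                                (114, 120))
        flag = flag_rbbs_variant(change(9.8, 2.0, position=100), model,
                                 [other])
        assert not flag.flagged and flag.suppressed_by == "CELF4"

    def test_weaker_neighbor_does_not_suppress(self):
        model = fake_model(8.8)
        other = RbpNeighborSite("CELF4", SiteScore(114, "+", 1.0),
                                (114, 120))
        assert flag_rbbs_variant(change(9.8, 2.0, position=100), model,
                                 [other]).flagged

    def test_distant_neighbor_does_not_suppress(self):
        model = fake_model(8.8)
        other = RbpNeighborSite("CELF4", SiteScore(130, "+", 12.0),
                                (130, 136))
        assert flag_rbbs_variant(change(9.8, 2.0, position=100), model,
                                 [other]).flagged

    def test_same_factor_never_suppresses(self):
        model = fake_model(8.8)
        other = RbpNeighborSite("RBFOX", SiteScore(104, "+", 12.0),
                                (104, 110))
        assert flag_rbbs_variant(change(9.8, 2.0, position=100), model,
                                 [other]).flagged

    def test_non_utr_variant_rejected(self):
        with pytest.raises(ValueError):
            flag_rbbs_variant(change(9.8, 2.0), fake_model(8.8),
                              in_utr=False)


def naive_rbbs_flags(seq, variant, rbp_models):
    """Independent oracle: direct loops over every model and anchor,
    applying the written three-clause rule."""
    vpos, ref, alt = variant
    alt_seq = seq[:vpos] + alt + seq[vpos + 1:]
    flags = set()
    for name, model in rbp_models.items():
        rseq = model.r_sequence
        L = model.length
        for start in range(max(0, vpos - L + 1), min(len(seq) - L, vpos) + 1):
            ri_ref = sum(model.riw[l]["ACGT".index(seq[start + l])]
                         for l in range(L))
            ri_alt = sum(model.riw[l]["ACGT".index(alt_seq[start + l])]
                         for l in range(L))
            hit = (abs(ri_alt - ri_ref) >= 4.0
                   or (ri_alt >= rseq and ri_ref < rseq))
            if not hit:
                continue
            suppressed = False
            for oname, om in rbp_models.items():
                if oname == name:
                    continue
                for os in range(max(0, start - 10 - om.length),
                                min(len(seq) - om.length,
                                    start + L + 10) + 1):
                    gap = max(os - (start + L), start - (os + om.length), 0)
                    if gap > 10:
                        continue
                    o_ri = sum(om.riw[l]["ACGT".index(alt_seq[os + l])]
                               for l in range(om.length))
                    # only windows that are sites (Ri > 0) can suppress
                    if o_ri > 0 and o_ri > ri_alt:
                        suppressed = True
            if not suppressed:
                flags.add((name, start))
    return flags


def module_rbbs_flags(seq, variant, rbp_models):
    from itvus.iminfo import delta_ri
    from itvus.pipeline import _rbp_neighbors
    vpos, ref, alt = variant
    alt_seq = seq[:vpos] + alt + seq[vpos + 1:]
    flags = set()
    for name, model in rbp_models.items():
        for anchor in range(vpos - model.length + 1, vpos + 1):
            try:
                ch = delta_ri(seq, variant, model, anchor + model.offset)
            except ValueError:
                continue
            neighbors = _rbp_neighbors(alt_seq, rbp_models, name,
                                       anchor + model.offset, model)
            neighbors = [n for n in neighbors if n.score.ri > -1e18]
            if flag_rbbs_variant(ch, model, neighbors).flagged:
                flags.add((name, anchor))
    return flags


class TestBruteForceOracle:
    def test_exhaustive_scan_matches_module(self, models, rng):
        """Flag sets over a 300-nt synthetic UTR agree exactly with a
        naive reimplementation for all five RBP models."""
        from itvus import models as builtin
        rbp = {k: models[k] for k in builtin.RBP_FACTORS}
        seq = list(rng.choice(list("ACGT"), size=300))
        # salt the sequence with consensus and near-consensus sites
        for name, pos in (("RBFOX", 40), ("SF3B4", 80), ("CELF4", 120),
                          ("KHDRBS1", 160), ("NCL", 200), ("RBFOX", 240)):
            for i, c in enumerate(rbp[name].consensus()):
                seq[pos + i] = c
        seq = "".join(seq)
        checked = 0
        for vpos in range(38, 250, 7):
            ref = seq[vpos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                variant = (vpos, ref, alt)
                assert naive_rbbs_flags(seq, variant, rbp) == \
                    module_rbbs_flags(seq, variant, rbp)
                checked += 1
        assert checked > 80

    def test_strand_flip_gives_same_verdicts(self, models, rng):
        """Clause (c) suppression is symmetric in coordinates: analyzing
        the reverse complement with mirrored coordinates gives the same
        flag multiset."""
        from itvus import models as builtin
        rbp = {k: models[k] for k in builtin.RBP_FACTORS}
        seq = list(rng.choice(list("ACGT"), size=120))
        for i, c in enumerate(rbp["RBFOX"].consensus()):
            seq[50 + i] = c
        seq = "".join(seq)
        vpos, ref, alt = 52, seq[52], "A" if seq[52] != "A" else "C"
        fwd = naive_rbbs_flags(seq, (vpos, ref, alt), rbp)
        # mirrored fixture: reverse complement everything, including the
        # models, so the same physical sites are re-analyzed
        rc = reverse_complement(seq)
        rc_models = {}
        for name, m in rbp.items():
            riw_rc = m.riw[::-1, ::-1].copy()
            rc_models[name] = InformationWeightMatrix(
                riw=riw_rc, r_sequence=m.r_sequence,
                r_sequence_sd=m.r_sequence_sd, model_id=name)
        vpos_rc = len(seq) - 1 - vpos
        ref_rc = reverse_complement(ref)
        alt_rc = reverse_complement(alt)
        rev = naive_rbbs_flags(rc, (vpos_rc, ref_rc, alt_rc), rc_models)
        assert {name for name, _ in fwd} == {name for name, _ in rev}
        assert {len(seq) - s - rbp[n].length for n, s in fwd} == \
            {s for n, s in rev}
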