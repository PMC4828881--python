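"""Pseudoexon detection: the five-part rule and its brute-force oracle."""

import numpy as np
import pytest

from itvus.iminfo import score_site
from itvus.pseudoexon import (PseudoexonCall, PseudoexonConfig, SiteChange,
                              detect_pseudoexon)
from itvus.iminfo import SiteScore


@pytest.fixture()
def intron_fixture(models, rng):
    """A 1.6 kb intron with a planted passing pseudoexon configuration.

    A strong acceptor sits 400 nt into the intron with an hnRNPA1
    proofreading site just inside the pseudoexon; a donor 150 nt further
    is one substitution away from consensus and the variant restores it.
    """
    acc, don, hn = models["acceptor"], models["donor"], models["hnRNPA1"]
    intron = (200, 1800)
    seq = list(rng.choice(list("ACGT"), size=2000))
    pa = intron[0] + 400
    pd = pa + 150
    for i, c in enumerate(acc.consensus()):
        seq[pa - acc.offset + i] = c
    for i, c in enumerate(hn.consensus()):
        seq[pa + 1 + i] = c
    for i, c in enumerate(don.consensus()):
        seq[pd - don.offset + i] = c
    seq[pd] = "A"  # break the GT; the variant restores it
    return "".join(seq), intron, (pd, "A", "G"), pa, pd


MODEL_KEYS = {"acceptor": "acceptor", "donor": "donor", "hnrnpa1": "hnRNPA1"}


def model_dict(models):
    return {k: models[v] for k, v in MODEL_KEYS.items()}


class TestDetection:
    def test_planted_configuration_is_called(self, models, intron_fixture):
        seq, intron, variant, pa, pd = intron_fixture
        call = detect_pseudoexon(seq, variant, intron, model_dict(models))
        assert call is not None
        assert call.pseudoexon_interval == (pa, pd)
        a, p, b = call.lengths
        assert (a, p, b) == (400, 150, 1050)
        assert a + p + b == intron[1] - intron[0]
        assert not call.frameshift  # 150 nt is divisible by 3: in frame

    def test_variant_outside_intron_rejected(self, models, intron_fixture):
        seq, intron, variant, *_ = intron_fixture
        with pytest.raises(ValueError, match="not inside intron"):
            detect_pseudoexon(seq, (50, seq[50], "A" if seq[50] != "A"
                                    else "C"), intron, model_dict(models))

    def test_lengths_render_like_report(self):
        call = PseudoexonCall(
            variant=(0, "G", "A"),
            activated_site=SiteChange(SiteScore(0, "+", -9.3),
                                      SiteScore(0, "+", 5.4), 14.7),
            activated_polarity="acceptor",
            partner_site=SiteScore(10, "+", 5.6),
            pseudoexon_interval=(6065, 6276), lengths=(6065, 211, 592),
            hnrnpa1_site=SiteScore(6066, "+", 8.0), frameshift=True,
            ri_total=9.0)
        assert call.lengths_str == "6065/211/592"
        assert call.frameshift  # 211 % 3 != 0


def naive_pseudoexon_scan(seq, variant, intron, models,
                          config=None):
    """Independent brute-force oracle: loop over every (site, partner)
    pair and apply the five written conditions directly."""
    config = config or PseudoexonConfig()
    vpos, ref, alt = variant
    alt_seq = seq[:vpos] + alt + seq[vpos + len(ref):]
    results = []
    for polarity in ("acceptor", "donor"):
        model = models["acceptor" if polarity == "acceptor" else "donor"]
        partner = models["donor" if polarity == "acceptor" else "acceptor"]
        hn = models["hnrnpa1"]
        thr = model.r_sequence - model.r_sequence_sd
        pthr = partner.r_sequence - partner.r_sequence_sd
        for anchor in range(intron[0] + model.offset,
                            intron[1] - (model.length - model.offset) + 1):
            fs = anchor - model.offset
            if not (fs <= vpos < fs + model.length):
                continue
            ri_ref = score_site(seq, model, anchor).ri
            ri_alt = score_site(alt_seq, model, anchor).ri
            if not (ri_alt - ri_ref > config.min_delta_ri
                    and ri_alt >= thr):
                continue
            for plen in range(config.min_exon_length,
                              config.max_exon_length + 1):
                pa = anchor - plen if polarity == "donor" else anchor
                pd = anchor if polarity == "donor" else anchor + plen
                p_anchor = pa if polarity == "donor" else pd
                pfs = p_anchor - partner.offset
                if pfs < intron[0] or pfs + partner.length > intron[1]:
                    continue
                if not score_site(seq, partner, p_anchor).ri > pthr:
                    continue
                if pa - intron[0] < config.min_intronic_distance:
                    continue
                if intron[1] - pd < config.min_intronic_distance:
                    continue
                found_hn = False
                for h in range(pa - config.hnrnpa1_max_distance
                               - hn.length + 1,
                               pa + config.hnrnpa1_max_distance + 1):
                    if h < 0 or h + hn.length > len(alt_seq):
                        continue
                    dist = max(h - pa, pa - (h + hn.length - 1), 0)
                    if dist > config.hnrnpa1_max_distance:
                        continue
                    if score_site(alt_seq, hn, h + hn.offset).ri \
                            >= hn.r_sequence:
                        found_hn = True
                        break
                if found_hn:
                    results.append((polarity, anchor, pa, pd))
    return results


class TestOracleEquivalence:
    def test_brute_force_agrees_on_short_introns(self, models,
                                                 intron_fixture):
        seq, intron, variant, pa, pd = intron_fixture
        md = model_dict(models)
        oracle = naive_pseudoexon_scan(seq, variant, intron, md)
        call = detect_pseudoexon(seq, variant, intron, md)
        assert (len(oracle) > 0) == (call is not None)
        assert (call.activated_polarity, call.pseudoexon_interval) in \
            [(pol, (a, d)) for pol, _, a, d in oracle]

    def test_brute_force_agrees_on_negative_cases(self, models, rng):
        md = model_dict(models)
        intron = (100, 1300)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=1500))
            vpos = int(rng.integers(intron[0] + 20, intron[1] - 20))
            ref = seq[vpos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            oracle = naive_pseudoexon_scan(seq, (vpos, ref, alt), intron, md)
            call = detect_pseudoexon(seq, (vpos, ref, str(alt)), intron, md)
            assert (len(oracle) > 0) == (call is not None)
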