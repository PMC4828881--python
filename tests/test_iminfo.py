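"""Information weight matrices, Ri scoring and fold-change arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itvus.iminfo import (FrequencyMatrix, InformationWeightMatrix, SiteScore,
                          build_iwm_from_pwm, build_iwm_from_sites, delta_ri,
                          fold_change, reverse_complement, sampling_correction,
                          scan_sequence, score_site)

BASES = "ACGT"


def naive_ri(window: str, riw: np.ndarray) -> float:
    """Independent per-position summation oracle."""
    total = 0.0
    for l, c in enumerate(window):
        total += riw[l][BASES.index(c)]
    return total


class TestBuildFromSites:
    def test_perfectly_conserved_site(self):
        iwm = build_iwm_from_sites(["ACGT"] * 10, apply_correction=False)
        # Laplace smoothing: observed base frequency 11/14
        expected = 2 + math.log2(11 / 14)
        assert iwm.riw[0, 0] == pytest.approx(expected)
        assert iwm.r_sequence == pytest.approx(4 * expected)
        assert iwm.r_sequence_sd == 0.0

    def test_uniform_columns_carry_no_information(self):
        sites = ["AAAA", "CCCC", "GGGG", "TTTT"] * 3
        iwm = build_iwm_from_sites(sites, apply_correction=False,
                                   pseudocount=0)
        assert np.allclose(iwm.riw, 0.0)
        assert iwm.r_sequence == pytest.approx(0.0)

    def test_column_entropy_oracle(self):
        # every base observed in every column, so pseudocount-free
        # frequencies are exact and Rsequence equals sum_l (2 - H(l))
        sites = ["ACGTAC", "CATGCA", "GTACGT", "TGCATG",
                 "ACGTCA", "CACGAC", "GTGCGT", "TGTATG"]
        iwm = build_iwm_from_sites(sites, apply_correction=False,
                                   pseudocount=0)
        expected = 0.0
        for l in range(6):
            counts = [sum(1 for s in sites if s[l] == b) for b in BASES]
            f = [c / len(sites) for c in counts if c > 0]
            entropy = -sum(p * math.log2(p) for p in f)
            expected += 2.0 - entropy
        assert iwm.r_sequence == pytest.approx(expected, abs=1e-9)

    def test_mean_training_ri_equals_rsequence(self, rng):
        sites = ["".join(rng.choice(list(BASES), size=8)) for _ in range(30)]
        iwm = build_iwm_from_sites(sites, apply_correction=True)
        ris = [naive_ri(s, iwm.riw) for s in sites]
        assert np.mean(ris) == pytest.approx(iwm.r_sequence, abs=1e-6)
        assert np.std(ris) == pytest.approx(iwm.r_sequence_sd, abs=1e-6)

    def test_sampling_correction_subtracted(self):
        with_e = build_iwm_from_sites(["ACGT"] * 10, apply_correction=True)
        without = build_iwm_from_sites(["ACGT"] * 10, apply_correction=False)
        e = sampling_correction(10)
        assert np.allclose(without.riw - with_e.riw, e)
        assert e == pytest.approx(3 / (2 * math.log(2) * 10))

    def test_riw_respects_alphabet_bound(self, rng):
        sites = ["".join(rng.choice(list(BASES), size=5)) for _ in range(20)]
        iwm = build_iwm_from_sites(sites, apply_correction=True)
        assert np.all(iwm.riw <= 2.0 - iwm.sampling_correction + 1e-12)

    def test_n_contributes_nothing(self):
        iwm_n = build_iwm_from_sites(["ANGT", "ACGT", "ACGT"],
                                     apply_correction=False)
        # position 1 frequencies come from the two informative sites only
        assert iwm_n.riw[1, 1] == pytest.approx(2 + math.log2(3 / 6))

    @pytest.mark.parametrize("bad", [[], ["ACGT", "ACG"]])
    def test_rejects_empty_and_ragged(self, bad):
        with pytest.raises(ValueError):
            build_iwm_from_sites(bad)

    def test_parameter_recovery_from_sampled_sites(self, rng):
        """Sites drawn from a model's implied distribution reproduce it."""
        from itvus.models import profile_frequencies, sample_sites
        freq = profile_frequencies("TGACGT", [0.55] * 6)
        truth = build_iwm_from_pwm(FrequencyMatrix(freq=freq.copy()))
        sites = sample_sites(freq, 500, rng)
        # no zero cells at n=500 with f >= 0.15, so the unbiased
        # pseudocount-free refit is well defined
        refit = build_iwm_from_sites(sites, apply_correction=False,
                                     pseudocount=0)
        err = np.abs(refit.riw - truth.riw)
        assert err.mean() < 0.15
        assert abs(refit.r_sequence - truth.r_sequence) < 0.1


class TestBuildFromPwm:
    def test_degenerate_column_log_values(self):
        pwm = FrequencyMatrix(freq=np.array([[1.0, 0, 0, 0]]),
                              pseudocount=1e-6)
        iwm = build_iwm_from_pwm(pwm)
        assert iwm.riw[0, 0] == pytest.approx(2.0, abs=1e-4)
        assert iwm.riw[0, 1] == pytest.approx(2 + math.log2(1e-6), abs=0.01)
        assert iwm.sd_undefined_from_pwm

    def test_uniform_pwm_is_zero_information(self):
        pwm = FrequencyMatrix(freq=np.full((3, 4), 0.25))
        iwm = build_iwm_from_pwm(pwm)
        assert np.allclose(iwm.riw, 0.0)
        assert iwm.r_sequence == pytest.approx(0.0)

    def test_half_half_columns_give_one_bit_each(self):
        pwm = FrequencyMatrix(freq=np.tile([0.5, 0.5, 0.0, 0.0], (4, 1)),
                              pseudocount=1e-12)
        iwm = build_iwm_from_pwm(pwm)
        assert iwm.r_sequence == pytest.approx(4.0, abs=1e-6)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            FrequencyMatrix(freq=np.array([[0.0, 0.0, 0.0, 0.0]]))


class TestScoring:
    def test_consensus_scores_maximal_ri(self, models):
        m = models["donor"]
        seq = "A" * 10 + m.consensus() + "A" * 10
        s = score_site(seq, m, 10 + m.offset)
        assert s.ri == pytest.approx(m.max_ri)

    def test_strand_symmetry(self, models, rng):
        m = models["RBFOX"]
        seq = "".join(rng.choice(list(BASES), size=40))
        plus = score_site(seq, m, 12, "+")
        minus = score_site(reverse_complement(seq), m, len(seq) - 1 - 12, "-")
        # scoring the reverse complement on '-' at the mirrored anchor
        # re-reads the original plus-strand site
        assert minus.ri == pytest.approx(plus.ri)

    def test_all_windows_match_naive_sum(self, models, rng):
        m = models["acceptor"]
        seq = "".join(rng.choice(list(BASES), size=200))
        for s in scan_sequence(seq, m):
            start = s.position - m.offset
            assert s.ri == pytest.approx(
                naive_ri(seq[start:start + m.length], m.riw), abs=1e-9)
            assert s.ri <= m.max_ri + 1e-9

    def test_out_of_bounds_rejected(self, models):
        with pytest.raises(ValueError):
            score_site("ACGT", models["donor"], 2)

    def test_non_acgt_contributes_minimum_with_warning(self, models):
        m = models["RBFOX"]
        seq = "AAAA" + m.consensus() + "AAAA"
        clean = score_site(seq, m, 4)
        dirty_seq = seq[:5] + "N" + seq[6:]
        with pytest.warns(UserWarning, match="non-ACGT"):
            dirty = score_site(dirty_seq, m, 4)
        expected = clean.ri - m.riw[1].max() + m.riw[1].min()
        assert dirty.ri == pytest.approx(expected)


class TestDeltaRi:
    def test_variant_outside_footprint_is_neutral(self, models):
        m = models["RBFOX"]
        seq = "A" * 30
        change = delta_ri(seq, (20, "A", "C"), m, 5)
        assert change.delta_ri == 0.0

    def test_consensus_to_worst_equals_column_difference(self, models):
        m = models["RBFOX"]
        seq = "AAAA" + m.consensus() + "AAAA"
        col = 2
        worst = BASES[int(np.argmin(m.riw[col]))]
        change = delta_ri(seq, (4 + col, m.consensus()[col], worst), m, 4)
        assert change.delta_ri == pytest.approx(
            m.riw[col].min() - m.riw[col].max())

    def test_antisymmetry(self, models, rng):
        m = models["donor"]
        seq = "".join(rng.choice(list(BASES), size=30))
        alt = "G" if seq[12] != "G" else "A"
        fwd = delta_ri(seq, (12, seq[12], alt), m, 10)
        edited = seq[:12] + alt + seq[13:]
        rev = delta_ri(edited, (12, alt, seq[12]), m, 10)
        assert fwd.delta_ri + rev.delta_ri == pytest.approx(0.0, abs=1e-9)

    def test_reference_mismatch_names_coordinate(self, models):
        with pytest.raises(ValueError, match="position 3"):
            delta_ri("ACGTACGTACGT", (3, "A", "C"), models["RBFOX"], 2)

    def test_indel_rescores_at_same_anchor(self, models):
        m = models["RBFOX"]
        seq = "ACGTAC" + m.consensus() + "GGATCC"
        # deletion upstream of the site shifts the anchor back
        change = delta_ri(seq, (1, "CG", "C"), m, 6)
        assert change.alt_score.ri == pytest.approx(m.max_ri)
        assert change.best_alt_score is not None


class TestFoldChange:
    @pytest.mark.parametrize("bits,expected", [
        (-4.0, 16.0), (0.0, 1.0), (1.0, 2.0), (-3.0, 8.0)])
    def test_exact_folds(self, bits, expected):
        assert fold_change(bits).fold == pytest.approx(expected)

    def test_direction_reported_separately(self):
        assert fold_change(-4.0).direction == "reduction"
        assert fold_change(2.0).direction == "increase"
        assert fold_change(0.0).direction == "none"

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=-20, max_value=20),
           st.floats(min_value=0.01, max_value=5))
    def test_strictly_monotone_in_magnitude(self, bits, extra):
        assert fold_change(bits + extra if bits >= 0 else bits - extra).fold \
            > fold_change(bits).fold


def test_matrix_file_round_trip(models, tmp_path):
    from itvus.iminfo import read_matrix, write_matrix
    m = models["donor"]
    path = tmp_path / "donor.iwm"
    write_matrix(path, m)
    back = read_matrix(path)
    assert isinstance(back, InformationWeightMatrix)
    assert back.polarity == "donor" and back.offset == m.offset
    assert np.allclose(back.riw, m.riw, atol=1e-6)
    assert back.r_sequence == pytest.approx(m.r_sequence, abs=1e-6)
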