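"""Frequency/weight matrices, information content, consensus patterns and
primary-specificity calls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cleavspec.model import (
    ConsensusPattern,
    PatternGrammarError,
    build_pfm,
    classify_specificity_from_pwm,
    derive_consensus,
    information_content,
    match_pattern,
    modal_window,
    pfm_to_pwm,
    uniform_background,
)
from cleavspec.nomenclature import ALPHABET, AA_INDEX

W7 = ["P4", "P3", "P2", "P1", "P1'", "P2'", "P3'"]
windows7 = st.lists(
    st.text(alphabet=ALPHABET, min_size=7, max_size=7), min_size=1, max_size=15
)


def _pfm(freqs):
    from cleavspec.model import PositionFrequencyMatrix

    return PositionFrequencyMatrix(positions=list(W7), frequencies=freqs)


class TestBuildPfm:
    def test_pseudocount_formula(self):
        pfm = build_pfm((["RRRAAGS"] * 4, W7), pseudocount=0.5)
        # P4 column: 4 observed R out of 4 windows, smoothed
        assert pfm.frequencies[0, AA_INDEX["R"]] == pytest.approx((4 + 0.5) / (4 + 10))
        assert pfm.n_sequences == 4

    def test_zero_pseudocount_single_window_is_indicator(self):
        pfm = build_pfm((["RRRAAGS"], W7), pseudocount=0.0)
        assert set(np.max(pfm.frequencies, axis=1)) == {1.0}
        assert modal_window(pfm) == "RRRAAGS"

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_pfm((["RRRAAGS"], W7), pseudocount=-0.1)

    @given(windows7)
    def test_columns_normalized_and_counts_conserved(self, windows):
        pfm = build_pfm((windows, W7), pseudocount=0.5)
        np.testing.assert_allclose(pfm.frequencies.sum(axis=1), 1.0, atol=1e-9)
        assert pfm.raw_counts.sum() == 7 * len(windows)
        np.testing.assert_allclose(
            pfm.frequencies,
            (pfm.raw_counts + 0.5) / (len(windows) + 10),
            atol=1e-12,
        )


class TestPwm:
    def test_uniform_matrix_gives_zero_weights(self):
        pwm = pfm_to_pwm(_pfm(np.full((7, 20), 1 / 20)))
        np.testing.assert_allclose(pwm.weights, 0.0, atol=1e-12)

    def test_log_odds_arithmetic(self):
        freqs = np.full((7, 20), 1 / 20)
        freqs[3] = (1 - 0.5) / 19
        freqs[3, AA_INDEX["R"]] = 0.5
        pwm = pfm_to_pwm(_pfm(freqs))
        assert pwm.weights[3, AA_INDEX["R"]] == pytest.approx(np.log2(10))

    @given(windows7)
    def test_frequencies_recovered_from_weights(self, windows):
        pfm = build_pfm((windows, W7), pseudocount=0.5)
        pwm = pfm_to_pwm(pfm)
        np.testing.assert_allclose(pwm.frequencies(), pfm.frequencies, atol=1e-12)

    def test_zero_frequency_demands_pseudocount(self):
        pfm = build_pfm((["RRRAAGS"], W7), pseudocount=0.0)
        with pytest.raises(ValueError, match="pseudocount"):
            pfm_to_pwm(pfm)

    @given(windows7)
    def test_expected_score_under_background_is_nonpositive(self, windows):
        # E_bg[weight] = -KL(bg || f) <= 0 at every position
        pfm = build_pfm((windows, W7), pseudocount=0.5)
        pwm = pfm_to_pwm(pfm)
        expected = (uniform_background()[None, :] * pwm.weights).sum(axis=1)
        assert np.all(expected <= 1e-12)


class TestInformationContent:
    def test_background_column_carries_zero_bits(self):
        assert information_content(_pfm(np.full((7, 20), 1 / 20))).max() < 1e-12

    def test_indicator_column_is_log2_20_bits(self):
        pfm = build_pfm((["RRRAAGS"], W7), pseudocount=0.0)
        np.testing.assert_allclose(information_content(pfm), np.log2(20), atol=1e-12)

    @given(windows7)
    def test_matches_direct_summation_oracle(self, windows):
        pfm = build_pfm((windows, W7), pseudocount=0.5)
        direct = np.array(
            [
                sum(f * np.log2(f / 0.05) for f in col if f > 0)
                for col in pfm.frequencies
            ]
        )
        np.testing.assert_allclose(information_content(pfm), direct, atol=1e-12)


class TestDeriveConsensus:
    def test_aspase_style_matrix(self):
        freqs = np.full((7, 20), 1 / 20)
        for i, pref in [(0, "FYW"), (1, "D"), (3, "D")]:
            col = np.full(20, 0.1 / (20 - len(pref)))
            for aa in pref:
                col[AA_INDEX[aa]] = 0.9 / len(pref)
            freqs[i] = col
        pattern = derive_consensus(_pfm(freqs))
        assert pattern.allowed[0] == frozenset("FYW")
        assert pattern.allowed[1] == frozenset("D")
        assert pattern.allowed[3] == frozenset("D")
        assert "P1" in pattern.required

    def test_class_positions_from_split_mass(self):
        # F/Y at P2, K at P1, R/K at P3' - the F/Y-K tryptase shape
        freqs = np.full((7, 20), 1 / 20)
        for i, pref in [(2, "FY"), (3, "K"), (6, "RK")]:
            col = np.full(20, 0.1 / (20 - len(pref)))
            for aa in pref:
                col[AA_INDEX[aa]] = 0.9 / len(pref)
            freqs[i] = col
        pattern = derive_consensus(_pfm(freqs))
        assert pattern.allowed[3] == frozenset("K")
        assert pattern.allowed[6] == frozenset("KR")
        assert pattern.allowed[2] is not None and {"F", "Y"} <= pattern.allowed[2]

    def test_uniform_matrix_gives_all_any(self):
        pattern = derive_consensus(_pfm(np.full((7, 20), 1 / 20)))
        assert all(a is None for a in pattern.allowed)
        assert pattern.required == frozenset({"P1"})

    def test_depleted_class_becomes_forbidden(self):
        freqs = np.full((7, 20), (1 - 2e-3) / 18)
        freqs[:, AA_INDEX["D"]] = 1e-3
        freqs[:, AA_INDEX["E"]] = 1e-3
        pattern = derive_consensus(_pfm(freqs))
        assert ("acidic", 3) in pattern.forbidden_classes

    def test_single_window_consensus_matches_itself_exactly(self):
        window = "WDSDRLK"
        pfm = build_pfm(([window], W7), pseudocount=0.0)
        pattern = derive_consensus(pfm)
        passes, mismatches = match_pattern(pattern, window)
        assert passes and mismatches == 0

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            derive_consensus(_pfm(np.full((7, 20), 1 / 20)), majority_threshold=0.0)


class TestClassification:
    @pytest.mark.parametrize(
        "mass,label",
        [
            ({"R": 0.9}, "tryptase"),
            ({"D": 0.85}, "asp-ase"),
            ({"F": 0.5, "Y": 0.3}, "chymase"),
            ({"V": 0.45, "L": 0.3}, "elastase"),
            ({"R": 0.45, "F": 0.35}, "dual(tryptase+chymase)"),
            ({}, "undetermined"),
        ],
    )
    def test_p1_mass_drives_the_label(self, mass, label):
        freqs = np.full((7, 20), 1 / 20)
        if mass:
            col = np.full(20, (1 - sum(mass.values())) / (20 - len(mass)))
            for aa, m in mass.items():
                col[AA_INDEX[aa]] = m
            freqs[3] = col
        call = classify_specificity_from_pwm(_pfm(freqs))
        assert call.label == label

    def test_accepts_pwm_and_pfm_equally(self):
        freqs = np.full((7, 20), 1 / 20)
        col = np.full(20, 0.1 / 19)
        col[AA_INDEX["R"]] = 0.9
        freqs[3] = col
        pfm = _pfm(freqs)
        assert (
            classify_specificity_from_pwm(pfm).label
            == classify_specificity_from_pwm(pfm_to_pwm(pfm)).label
        )


class TestPatternGrammar:
    CASES = [
        "P4:[FWY] P3:D P2:. P1:D! P1':. ; mm<=0",
        "P2:[FY] P1:K! P1':. P2':. P3':[KR] ; forbid[DE]±3 ; mm<=1",
        "P4:. P3:. P2:. P1:R! P1':. P2':. P3':. ; mm<=2",
    ]

    @pytest.mark.parametrize("text", CASES)
    def test_round_trip_lossless(self, text):
        pattern = ConsensusPattern.from_string(text)
        assert ConsensusPattern.from_string(pattern.to_string()) == pattern

    @pytest.mark.parametrize(
        "bad", ["P1:Z@", "P1:D! ; forbid[QZ]±3", "P1:D! ; mm<=x", ""]
    )
    def test_malformed_patterns_report_position(self, bad):
        with pytest.raises(PatternGrammarError, match="character"):
            ConsensusPattern.from_string(bad)


class TestMatchPattern:
    def aspase_pattern(self):
        return ConsensusPattern.from_string(
            "P6:. P5:. P4:[FWY] P3:D! P2:. P1:D! P1':. P2':. ; mm<=1"
        )

    def test_mucin_octamer_passes(self):
        passes, mismatches = match_pattern(self.aspase_pattern(), "EWFDVDYP")
        assert passes and mismatches == 0

    def test_fkrlk_window_passes_fk_pattern(self):
        pattern = ConsensusPattern.from_string("P2:[FY] P1:K! P1':. P2':. P3':[KR]")
        passes, _ = match_pattern(pattern, "FKRLK")
        assert passes

    def test_forbidden_acidic_near_p1_fails(self):
        pattern = ConsensusPattern.from_string(
            "P2:[FY] P1:K! P1':. P2':. P3':[KR] ; forbid[DE]±3 ; mm<=1"
        )
        passes, _ = match_pattern(pattern, "FKRDK")
        assert not passes

    def test_required_failure_counts_but_fails(self):
        passes, mismatches = match_pattern(self.aspase_pattern(), "EWFAVDYP")
        assert not passes and mismatches == 1
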