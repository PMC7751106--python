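"""Feature encodings: compositions, correlation factors, profile descriptors."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memdetect.constants import (
    AMINO_ACIDS,
    HYDROPHILICITY_HOPP_WOODS,
    HYDROPHOBICITY_TANFORD,
    SIDE_CHAIN_MASS,
)
from memdetect.encoders import (
    AminoAcidScaleSet,
    encode_aac,
    encode_paac,
    encode_pseaac,
    encode_psepssm,
    encode_saac,
    standardize_profile,
    theta_factors,
)
from memdetect.seqio import ProfileMatrix, ProteinRecord

sequences = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=80)


def hand_standardize(table):
    """Independent scale standardization: plain-Python population z-score."""
    vals = [table[aa] for aa in AMINO_ACIDS]
    mu = statistics.fmean(vals)
    sd = statistics.pstdev(vals)
    return {aa: (table[aa] - mu) / sd for aa in AMINO_ACIDS}


def hand_theta(seq, k):
    """Independent correlation factor: explicit loops over the three scales."""
    h1 = hand_standardize(HYDROPHOBICITY_TANFORD)
    h2 = hand_standardize(HYDROPHILICITY_HOPP_WOODS)
    m = hand_standardize(SIDE_CHAIN_MASS)
    total = 0.0
    for i in range(len(seq) - k):
        a, b = seq[i], seq[i + k]
        total += (
            (h1[b] - h1[a]) ** 2 + (h2[b] - h2[a]) ** 2 + (m[b] - m[a]) ** 2
        ) / 3.0
    return total / (len(seq) - k)


class TestAAC:
    def test_single_letter_sequence(self):
        v = encode_aac(ProteinRecord("p", "AAAA")).values
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform_sequence(self):
        v = encode_aac(ProteinRecord("p", AMINO_ACIDS)).values
        np.testing.assert_allclose(v, 0.05)

    @given(seq=sequences)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_is_a_distribution(self, seq):
        v = encode_aac(ProteinRecord("p", seq)).values
        assert v.shape == (20,) and (v >= 0).all()
        assert abs(v.sum() - 1.0) < 1e-9


class TestPAAC:
    def test_examples(self):
        v = encode_paac(ProteinRecord("p", "AAA")).values
        assert v[0] == 1.0 and v.sum() == 1.0
        v = encode_paac(ProteinRecord("p", "ACA")).values
        ia_c = AMINO_ACIDS.index("C")
        assert v[ia_c] == 0.5  # (A,C)
        assert v[ia_c * 20] == 0.5  # (C,A)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            encode_paac(ProteinRecord("p", "A"))

    @given(seq=sequences)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_is_a_distribution(self, seq):
        v = encode_paac(ProteinRecord("p", seq)).values
        assert v.shape == (400,) and abs(v.sum() - 1.0) < 1e-9


class TestThetaAndPseAAC:
    def test_homopolymer_thetas_vanish(self):
        rec = ProteinRecord("p", "A" * 10)
        np.testing.assert_allclose(theta_factors(rec, 3), 0.0)

    def test_lambda_zero_is_empty(self):
        assert theta_factors(ProteinRecord("p", "ACDE"), 0).size == 0

    @pytest.mark.parametrize("seq,lam", [("AC", 1), ("ACWY", 2), ("MKVLIT", 3)])
    def test_matches_hand_evaluation(self, seq, lam):
        thetas = theta_factors(ProteinRecord("p", seq), lam)
        expected = [hand_theta(seq, k) for k in range(1, lam + 1)]
        np.testing.assert_allclose(thetas, expected, atol=1e-9)

    def test_lambda_at_length_errors(self):
        with pytest.raises(ValueError):
            theta_factors(ProteinRecord("p", "AC"), 2)

    @given(seq=sequences)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pseaac_lambda_zero_equals_aac(self, seq):
        rec = ProteinRecord("p", seq)
        np.testing.assert_allclose(
            encode_pseaac(rec, 0).values, encode_aac(rec).values, atol=1e-12
        )

    def test_homopolymer_pseudo_block_is_zero(self):
        rec = ProteinRecord("p", "W" * 30)
        v = encode_pseaac(rec, 5).values
        np.testing.assert_allclose(v[20:], 0.0)
        np.testing.assert_allclose(v[:20], encode_aac(rec).values)

    def test_two_residue_hand_computation(self):
        rec = ProteinRecord("p", "AC")
        theta1 = hand_theta("AC", 1)
        denom = 1.0 + 0.05 * theta1
        v = encode_pseaac(rec, 1, omega=0.05).values
        assert v.shape == (21,)
        np.testing.assert_allclose(v[AMINO_ACIDS.index("A")], 0.5 / denom, atol=1e-9)
        np.testing.assert_allclose(v[20], 0.05 * theta1 / denom, atol=1e-9)
        assert abs(v.sum() - 1.0) < 1e-9

    @given(seq=st.text(alphabet=AMINO_ACIDS, min_size=8, max_size=60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_pseaac_sums_to_one(self, seq):
        v = encode_pseaac(ProteinRecord("p", seq), 5).values
        assert abs(v.sum() - 1.0) < 1e-9 and (v >= 0).all()


class TestSAAC:
    def test_boundary_length_50(self):
        v = encode_saac(ProteinRecord("p", "A" * 50)).values
        assert v.shape == (60,)
        assert v[0] == 1.0  # N block, residue A
        np.testing.assert_allclose(v[20:40], 0.0)  # empty middle segment
        assert v[40] == 1.0  # C block

    def test_middle_segment_composition(self):
        seq = "A" * 25 + "C" * 25 + "A" * 25
        v = encode_saac(ProteinRecord("p", seq)).values
        assert v[20 + AMINO_ACIDS.index("C")] == 1.0

    def test_below_floor_errors(self):
        with pytest.raises(ValueError):
            encode_saac(ProteinRecord("p", "A" * 49))

    @given(seq=st.text(alphabet=AMINO_ACIDS, min_size=51, max_size=120))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_blocks_are_distributions(self, seq):
        v = encode_saac(ProteinRecord("p", seq)).values
        for block in (v[:20], v[20:40], v[40:]):
            assert abs(block.sum() - 1.0) < 1e-9


class TestProfileStandardization:
    def test_constant_row_becomes_zero(self):
        p = ProfileMatrix("q", np.ones((3, 20)))
        np.testing.assert_allclose(standardize_profile(p).scores, 0.0)

    def test_rows_have_zero_mean_unit_sd(self, rng):
        p = ProfileMatrix("q", rng.normal(size=(6, 20)))
        out = standardize_profile(p).scores
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose((out**2).mean(axis=1), 1.0, atol=1e-9)

    def test_hand_zscore(self):
        row = np.zeros(20)
        row[0] = 2.0
        out = standardize_profile(ProfileMatrix("q", row[None, :])).scores[0]
        # hand arithmetic: mean 0.1, population SD sqrt((1.9^2+19*0.01)/20)
        sd = np.sqrt((1.9**2 + 19 * 0.01) / 20)
        np.testing.assert_allclose(out[0], 1.9 / sd, atol=1e-9)
        np.testing.assert_allclose(out[1], -0.1 / sd, atol=1e-9)

    def test_center_only_flag(self, rng):
        p = ProfileMatrix("q", rng.normal(size=(4, 20)))
        out = standardize_profile(p, center_only=True).scores
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        assert not np.allclose((out**2).mean(axis=1), 1.0)


def hand_psepssm(scores, lam):
    """Brute-force descriptor: independent loops over the standardized rows."""
    rows = []
    for row in scores:
        mu = statistics.fmean(row)
        sd = statistics.pstdev(row)
        rows.append([(v - mu) / sd if sd > 0 else 0.0 for v in row])
    L = len(rows)
    means = [statistics.fmean(r[j] for r in rows) for j in range(20)]
    if lam == 0:
        lags = [0.0] * 20
    else:
        lags = [
            statistics.fmean((rows[i][j] - rows[i + lam][j]) ** 2 for i in range(L - lam))
            for j in range(20)
        ]
    return means + lags


class TestPsePSSM:
    def test_lambda_zero_lag_block_is_zero(self, rng):
        p = ProfileMatrix("q", rng.integers(-7, 8, size=(9, 20)).astype(float))
        v = encode_psepssm(p, 0).values
        assert v.shape == (40,)
        np.testing.assert_allclose(v[20:], 0.0)

    def test_two_row_profile_hand_arithmetic(self, rng):
        raw = rng.integers(-7, 8, size=(2, 20)).astype(float)
        v = encode_psepssm(ProfileMatrix("q", raw), 1).values
        np.testing.assert_allclose(v, hand_psepssm(raw.tolist(), 1), atol=1e-9)

    def test_all_zero_profile_is_zero_vector(self):
        v = encode_psepssm(ProfileMatrix("q", np.zeros((5, 20))), 2).values
        np.testing.assert_allclose(v, 0.0)

    @pytest.mark.parametrize("lam", [0, 1, 2])
    def test_brute_force_recomputation_on_random_profiles(self, lam, rng):
        for _ in range(10):
            raw = rng.integers(-9, 10, size=(5, 20)).astype(float)
            v = encode_psepssm(ProfileMatrix("q", raw), lam).values
            np.testing.assert_allclose(v, hand_psepssm(raw.tolist(), lam), atol=1e-9)

    def test_lambda_bound_errors(self, rng):
        p = ProfileMatrix("q", rng.normal(size=(4, 20)))
        with pytest.raises(ValueError):
            encode_psepssm(p, 4)


class TestScales:
    def test_standardized_scales_have_zero_mean_unit_sd(self):
        scales = AminoAcidScaleSet.default()
        for arr in (scales.h1, scales.h2, scales.mass):
            assert abs(arr.mean()) < 1e-9
            assert abs((arr**2).mean() - 1.0) < 1e-9

    def test_scale_tables_are_replaceable(self):
        table = {aa: float(i) for i, aa in enumerate(AMINO_ACIDS)}
        custom = AminoAcidScaleSet.from_tables(table, table, table)
        assert abs(custom.h1.mean()) < 1e-9
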