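"""Fixed-length protein feature encodings.

Five encodings are provided, each mapping one protein to a numeric vector of
declared dimension:

==========  =========  ==========================================================
encoding    dimension  content
==========  =========  ==========================================================
AAC         20         normalized amino-acid occurrence frequencies
PAAC        400        normalized dipeptide (pair) frequencies
PseAAC      20 + λ     AAC plus λ sequence-order correlation factors built from
                       standardized hydrophobicity/hydrophilicity/mass scales
SAAC        60         AAC of the N-terminal 25, interior, and C-terminal 25
Pse-PSSM    40         per-column profile means plus mean squared λ-lag
                       differences of a row-standardized PSSM
==========  =========  ==========================================================

Each encoding is exposed both as a function on a single record and as a
scikit-learn transformer operating on lists of records (or profiles).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import (
    AA_INDEX,
    AMINO_ACIDS,
    HYDROPHILICITY_HOPP_WOODS,
    HYDROPHOBICITY_TANFORD,
    SIDE_CHAIN_MASS,
    scale_array,
)
from .seqio import ProfileMatrix, ProteinRecord

ENCODING_DIMS = {"AAC": 20, "PAAC": 400, "SAAC": 60, "PsePSSM": 40}


def _standardize_scale(raw: np.ndarray) -> np.ndarray:
    # Population SD: the 20 amino acids are the whole population.
    centered = raw - raw.mean()
    return centered / np.sqrt((centered**2).mean())


@dataclasses.dataclass(frozen=True)
class AminoAcidScaleSet:
    """Raw and standardized physicochemical scales over the 20 amino acids.

    Standardization subtracts the mean over the 20 residues and divides by
    the population standard deviation, so each standardized scale has mean 0
    and SD 1 exactly.
    """

    h1_raw: np.ndarray
    h2_raw: np.ndarray
    mass_raw: np.ndarray

    @property
    def h1(self) -> np.ndarray:
        return _standardize_scale(self.h1_raw)

    @property
    def h2(self) -> np.ndarray:
        return _standardize_scale(self.h2_raw)

    @property
    def mass(self) -> np.ndarray:
        return _standardize_scale(self.mass_raw)

    @classmethod
    def default(cls) -> "AminoAcidScaleSet":
        """Tanford hydrophobicity, Hopp-Woods hydrophilicity, side-chain mass."""
        return cls(
            scale_array(HYDROPHOBICITY_TANFORD),
            scale_array(HYDROPHILICITY_HOPP_WOODS),
            scale_array(SIDE_CHAIN_MASS),
        )

    @classmethod
    def from_tables(
        cls,
        h1: dict[str, float],
        h2: dict[str, float],
        mass: dict[str, float],
    ) -> "AminoAcidScaleSet":
        return cls(scale_array(h1), scale_array(h2), scale_array(mass))


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """A named fixed-length encoding of one protein."""

    protein_id: str
    encoding: str
    lam: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def _counts(sequence: str) -> np.ndarray:
    counts = np.zeros(20)
    for ch in sequence:
        counts[AA_INDEX[ch]] += 1
    return counts


def _aac_values(sequence: str) -> np.ndarray:
    if not sequence:
        return np.zeros(20)
    return _counts(sequence) / len(sequence)


def encode_aac(rec: ProteinRecord) -> FeatureVector:
    """Amino-acid composition: occurrence frequency of each residue / L."""
    if rec.length < 1:
        raise ValueError("AAC requires a non-empty sequence")
    return FeatureVector(rec.id, "AAC", 0, _aac_values(rec.sequence))


def encode_paac(rec: ProteinRecord) -> FeatureVector:
    """Pair (dipeptide) composition over the 400 ordered residue pairs."""
    if rec.length < 2:
        raise ValueError(f"PAAC requires L >= 2, got L={rec.length}")
    counts = np.zeros((20, 20))
    seq = rec.sequence
    for a, b in zip(seq, seq[1:]):
        counts[AA_INDEX[a], AA_INDEX[b]] += 1
    return FeatureVector(rec.id, "PAAC", 0, counts.ravel() / (rec.length - 1))


def theta_factors(
    rec: ProteinRecord, lam: int, scales: AminoAcidScaleSet | None = None
) -> np.ndarray:
    """Sequence-order correlation factors θ_1..θ_λ.

    θ_k averages, over all residue pairs k apart, the correlation function
    Θ(R_i, R_{i+k}) = mean of the squared differences of the three
    standardized scales (hydrophobicity, hydrophilicity, side-chain mass).
    """
    if lam < 0 or lam >= rec.length:
        raise ValueError(f"need 0 <= lambda < L, got lambda={lam}, L={rec.length}")
    if lam == 0:
        return np.zeros(0)
    scales = scales or AminoAcidScaleSet.default()
    props = np.stack([scales.h1, scales.h2, scales.mass])  # 3 x 20
    idx = np.array([AA_INDEX[ch] for ch in rec.sequence])
    seq_props = props[:, idx]  # 3 x L
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        diffs = seq_props[:, k:] - seq_props[:, :-k]
        thetas[k - 1] = (diffs**2).mean(axis=0).mean()
    return thetas


def encode_pseaac(
    rec: ProteinRecord,
    lam: int,
    omega: float = 0.05,
    scales: AminoAcidScaleSet | None = None,
) -> FeatureVector:
    """Pseudo amino-acid composition: AAC plus λ weighted correlation factors.

    The weight ω (default 0.05) balances the sequence-order block against the
    composition block; both blocks share the denominator Σf + ωΣθ, so the
    full vector sums to 1.
    """
    thetas = theta_factors(rec, lam, scales)
    freqs = _aac_values(rec.sequence)
    denom = freqs.sum() + omega * thetas.sum()
    values = np.concatenate([freqs / denom, omega * thetas / denom])
    return FeatureVector(rec.id, "PseAAC", lam, values)


def encode_saac(
    rec: ProteinRecord, n_term: int = 25, c_term: int = 25
) -> FeatureVector:
    """Split amino-acid composition: AAC of N-terminus, interior, C-terminus.

    With the default 25+25 split the minimum legal length is 50; at exactly
    50 the interior segment is empty and its block is the zero vector.
    """
    if rec.length < n_term + c_term:
        raise ValueError(
            f"SAAC requires L >= {n_term + c_term}, got L={rec.length}"
        )
    seq = rec.sequence
    values = np.concatenate(
        [
            _aac_values(seq[:n_term]),
            _aac_values(seq[n_term : rec.length - c_term]),
            _aac_values(seq[rec.length - c_term :]),
        ]
    )
    return FeatureVector(rec.id, "SAAC", 0, values)


def standardize_profile(p: ProfileMatrix, center_only: bool = False) -> ProfileMatrix:
    """Standardize each profile row to mean 0 (and SD 1 unless ``center_only``).

    A constant row has no substitution preference signal; it becomes the zero
    row rather than dividing by zero.
    """
    scores = p.scores
    centered = scores - scores.mean(axis=1, keepdims=True)
    if center_only:
        return ProfileMatrix(p.protein_id, centered)
    sd = np.sqrt((centered**2).mean(axis=1, keepdims=True))
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return ProfileMatrix(p.protein_id, out)


def encode_psepssm(
    p: ProfileMatrix, lam: int, standardized: bool = False, center_only: bool = False
) -> FeatureVector:
    """Pseudo-PSSM descriptor: 20 column means plus 20 mean squared λ-lag diffs.

    The profile is row-standardized first (unless the caller already did so).
    For λ = 0 the lag block is identically zero.
    """
    if lam < 0 or lam >= p.length:
        raise ValueError(f"need 0 <= lambda < L, got lambda={lam}, L={p.length}")
    if not standardized:
        p = standardize_profile(p, center_only=center_only)
    e = p.scores
    means = e.mean(axis=0)
    if lam == 0:
        lag = np.zeros(20)
    else:
        diffs = e[:-lam] - e[lam:]
        lag = (diffs**2).mean(axis=0)
    return FeatureVector(p.protein_id, "PsePSSM", lam, np.concatenate([means, lag]))


def feature_names(encoding: str, lam: int = 0) -> list[str]:
    """Component names for a TSV header, matching the CLI output convention."""
    enc = encoding.lower()
    if enc == "aac":
        return [f"aac_{aa}" for aa in AMINO_ACIDS]
    if enc == "paac":
        return [f"paac_{a}{b}" for a, b in itertools.product(AMINO_ACIDS, repeat=2)]
    if enc == "pseaac":
        return [f"pseaac_{aa}" for aa in AMINO_ACIDS] + [
            f"pseaac_theta{j}" for j in range(1, lam + 1)
        ]
    if enc == "saac":
        return [
            f"saac_{block}_{aa}"
            for block in ("N", "M", "C")
            for aa in AMINO_ACIDS
        ]
    if enc == "psepssm":
        return [f"psepssm_mean_{aa}" for aa in AMINO_ACIDS] + [
            f"psepssm_g_{aa}" for aa in AMINO_ACIDS
        ]
    raise ValueError(f"unknown encoding {encoding!r}")


class _RecordEncoder(BaseEstimator, TransformerMixin):
    """Base for stateless sequence encoders with the sklearn transform API."""

    def fit(self, X: Sequence[ProteinRecord], y=None):  # noqa: N803
        self.n_features_out_ = len(self.get_feature_names_out())
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> np.ndarray:  # noqa: N803
        return np.vstack([self._encode(rec).values for rec in X])

    def _encode(self, rec: ProteinRecord) -> FeatureVector:
        raise NotImplementedError


class AACEncoder(_RecordEncoder):
    """20-component amino-acid composition transformer."""

    def _encode(self, rec):
        return encode_aac(rec)

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names("aac"))


class PAACEncoder(_RecordEncoder):
    """400-component dipeptide composition transformer."""

    def _encode(self, rec):
        return encode_paac(rec)

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names("paac"))


class PseAACEncoder(_RecordEncoder):
    """(20+λ)-component pseudo amino-acid composition transformer."""

    def __init__(self, lam: int = 0, omega: float = 0.05, scales=None):
        self.lam = lam
        self.omega = omega
        self.scales = scales

    def _encode(self, rec):
        return encode_pseaac(rec, self.lam, self.omega, self.scales)

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names("pseaac", self.lam))


class SAACEncoder(_RecordEncoder):
    """60-component split amino-acid composition transformer."""

    def __init__(self, n_term: int = 25, c_term: int = 25):
        self.n_term = n_term
        self.c_term = c_term

    def _encode(self, rec):
        return encode_saac(rec, self.n_term, self.c_term)

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names("saac"))


class PsePSSMEncoder(BaseEstimator, TransformerMixin):
    """40-component pseudo-PSSM transformer over profile matrices."""

    def __init__(self, lam: int = 0, center_only: bool = False):
        self.lam = lam
        self.center_only = center_only

    def fit(self, X: Sequence[ProfileMatrix], y=None):  # noqa: N803
        self.n_features_out_ = 40
        return self

    def transform(self, X: Sequence[ProfileMatrix]) -> np.ndarray:  # noqa: N803
        return np.vstack(
            [
                encode_psepssm(p, self.lam, center_only=self.center_only).values
                for p in X
            ]
        )

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names("psepssm"))


ENCODERS = {
    "aac": AACEncoder,
    "paac": PAACEncoder,
    "pseaac": PseAACEncoder,
    "saac": SAACEncoder,
    "psepssm": PsePSSMEncoder,
}
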