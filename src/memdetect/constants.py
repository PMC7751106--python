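"""Amino-acid alphabet, physicochemical scale tables, and background frequencies.

The canonical residue order used throughout the toolkit is alphabetical by
one-letter code.  Every reader permutes external column orders into this one,
so feature components line up regardless of the source file's convention.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino-acid order: alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity codes mapped to their nearest standard residue under the
#: permissive normalization policy.  X stays unmappable by design.
AMBIGUOUS_MAP: dict[str, str] = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

# Tanford hydrophobicity scale (free energy of transfer, kcal/mol),
# as used by the pseudo amino-acid composition literature.
HYDROPHOBICITY_TANFORD: dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

# Hopp-Woods hydrophilicity scale.
HYDROPHILICITY_HOPP_WOODS: dict[str, float] = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

# Side-chain masses (Da), standard biochemistry values.
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

# Swiss-Prot-style background amino-acid frequencies used by the synthetic
# sequence generator; renormalized at use.
BACKGROUND_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0664, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

#: Hydrophobic residues that make up synthetic transmembrane stretches.
HYDROPHOBIC_SET: str = "AILMFVW"


def scale_array(table: dict[str, float]) -> np.ndarray:
    """Return a scale table as a length-20 array in canonical residue order."""
    return np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)


def background_array() -> np.ndarray:
    """Background frequencies in canonical order, renormalized to sum to 1."""
    freqs = scale_array(BACKGROUND_FREQUENCIES)
    return freqs / freqs.sum()
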