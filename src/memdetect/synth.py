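"""Deterministic synthetic fixtures: sequences, profiles, topology calls.

The generator emulates the class structure the membrane-detection problem
presents: positive (membrane) proteins mostly carry 1-7 hydrophobic
transmembrane-like stretches of 18-25 residues embedded in a background
composition, while a configurable minority (default 20%) are "surface-bound"
— no stretch, only a mild compositional shift — mirroring the peripheral /
lipid-anchored proteins that topology predictors systematically miss.
Negatives are background-only.  Profile matrices are substitution-matrix rows
for each residue plus seeded integer noise, so they are parseable through
the ASCII PSSM round trip and carry the same class signal as the sequences.

Everything is a pure function of the config seed: the same config yields
byte-identical datasets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from Bio.Align import substitution_matrices

from .constants import AMINO_ACIDS, HYDROPHOBIC_SET, background_array
from .seqio import LabeledDataset, ProfileMatrix, ProteinRecord, TopologyCall


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    The 50-residue length floor matches the fragment-removal rule applied to
    real data; the hydrophobic stretch geometry (1-7 segments of 18-25
    residues) matches typical transmembrane helices.
    """

    n_per_class: int = 60
    length_range: tuple[int, int] = (50, 400)
    tms_count_range: tuple[int, int] = (1, 7)
    tms_length_range: tuple[int, int] = (18, 25)
    hydrophobic_set: str = HYDROPHOBIC_SET
    surface_fraction: float = 0.2
    profile_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 50:
            raise ValueError("minimum synthetic length is 50 residues")
        for lo, hi in (self.length_range, self.tms_count_range, self.tms_length_range):
            if lo > hi or lo < 0:
                raise ValueError("ranges must be non-empty and non-negative")
        if not 0 <= self.surface_fraction <= 1:
            raise ValueError("surface_fraction must be in [0, 1]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


@dataclasses.dataclass
class SynthDataset(LabeledDataset):
    """LabeledDataset plus the generator's ground truth.

    ``tms_truth`` maps each id to its true number of inserted stretches
    (0 for negatives and surface-bound positives); ``surface_ids`` marks the
    surface-bound positives.
    """

    tms_truth: dict[str, int] = dataclasses.field(default_factory=dict)
    surface_ids: set[str] = dataclasses.field(default_factory=set)


def _sample_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> list[str]:
    idx = rng.choice(20, size=length, p=probs)
    return [AMINO_ACIDS[i] for i in idx]


def _surface_probs() -> np.ndarray:
    """Background shifted toward the hydrophobic set (surface-signal shift)."""
    probs = background_array().copy()
    for aa in HYDROPHOBIC_SET:
        probs[AMINO_ACIDS.index(aa)] *= 1.6
    return probs / probs.sum()


def gen_dataset(cfg: SynthConfig) -> SynthDataset:
    """Generate a labeled two-class protein dataset.

    Positives outnumber their stretch budget never: segment counts are capped
    so the stretches always fit the sampled length with flanking background.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    probs = background_array()
    surf_probs = _surface_probs()
    hydro = list(cfg.hydrophobic_set)
    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    tms_truth: dict[str, int] = {}
    surface_ids: set[str] = set()

    n_surface = int(round(cfg.surface_fraction * cfg.n_per_class))
    for i in range(cfg.n_per_class):
        pid = f"pos{i:04d}"
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        is_surface = i < n_surface
        if is_surface:
            seq = _sample_sequence(rng, length, surf_probs)
            tms = 0
            surface_ids.add(pid)
        else:
            seq = _sample_sequence(rng, length, probs)
            want = int(rng.integers(cfg.tms_count_range[0], cfg.tms_count_range[1] + 1))
            max_fit = max(1, length // (cfg.tms_length_range[1] + 5))
            tms = min(want, max_fit)
            # one stretch per equal-width slot keeps segments disjoint
            slot = length // tms
            for s in range(tms):
                seg_len = int(
                    rng.integers(cfg.tms_length_range[0], cfg.tms_length_range[1] + 1)
                )
                seg_len = min(seg_len, slot)
                start = s * slot + int(rng.integers(0, slot - seg_len + 1))
                stretch = rng.choice(len(hydro), size=seg_len)
                seq[start : start + seg_len] = [hydro[j] for j in stretch]
        records.append(ProteinRecord(pid, "".join(seq)))
        labels[pid] = 1
        tms_truth[pid] = tms

    for i in range(cfg.n_per_class):
        pid = f"neg{i:04d}"
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        records.append(ProteinRecord(pid, "".join(_sample_sequence(rng, length, probs))))
        labels[pid] = 0
        tms_truth[pid] = 0

    return SynthDataset(
        records=records,
        labels=labels,
        tms_truth=tms_truth,
        surface_ids=surface_ids,
    )


_BLOSUM = None


def _blosum_rows() -> np.ndarray:
    """BLOSUM62 rows for the 20 residues, columns in canonical order."""
    global _BLOSUM
    if _BLOSUM is None:
        mat = substitution_matrices.load("BLOSUM62")
        _BLOSUM = np.array(
            [[float(mat[a, b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS]
        )
    return _BLOSUM


def gen_profiles(dataset: LabeledDataset, cfg: SynthConfig) -> dict[str, ProfileMatrix]:
    """Integer profile matrices: substitution rows plus seeded noise.

    Each row is the BLOSUM62 row of the residue at that position perturbed by
    uniform integer noise of magnitude ``round(profile_noise)``, so profiles
    inherit the sequences' class signal and survive the ASCII round trip
    exactly.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    rows = _blosum_rows()
    amp = int(round(cfg.profile_noise))
    profiles: dict[str, ProfileMatrix] = {}
    for rec in dataset.records:
        idx = [AMINO_ACIDS.index(ch) for ch in rec.sequence]
        mat = rows[idx]
        if amp > 0:
            mat = mat + rng.integers(-amp, amp + 1, size=mat.shape)
        profiles[rec.id] = ProfileMatrix(rec.id, mat.astype(float))
    return profiles


def gen_topology_calls(
    dataset: SynthDataset,
    cfg: SynthConfig,
    sensitivity: float = 0.72,
    specificity: float = 0.997,
) -> list[TopologyCall]:
    """Simulate an external transmembrane-topology predictor.

    Stretch-bearing positives are detected with the given sensitivity
    (reporting their true segment count); surface-bound positives are never
    detected, since topology tools see no transmembrane segment in them;
    negatives are falsely called at rate 1 - specificity.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng([cfg.seed, 3])
    calls = []
    for rec in dataset.records:
        truth_tms = dataset.tms_truth.get(rec.id, 0)
        label = dataset.labels[rec.id]
        if label == 1 and truth_tms > 0:
            tms = truth_tms if rng.random() < sensitivity else 0
        elif label == 1:
            tms = 0
        else:
            tms = 1 if rng.random() > specificity else 0
        calls.append(TopologyCall(rec.id, tms))
    return calls
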