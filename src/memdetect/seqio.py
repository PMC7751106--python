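"""Readers and writers for the toolkit's external formats.

Formats handled here: multi-record FASTA, the PSI-BLAST ``-out_ascii_pssm``
profile dialect, the topology-call table (TSV ``id<TAB>tms_count``), the label
table (TSV ``id<TAB>label``), and flat key-value config files.  All readers
validate their input and normalize residue columns into the canonical
alphabetical amino-acid order of :mod:`memdetect.constants`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AA_INDEX, AMBIGUOUS_MAP, AMINO_ACIDS

#: Column order used by PSI-BLAST ASCII exports.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

AlphabetPolicy = Literal["strict", "map"]


class FormatError(ValueError):
    """Raised when an external file violates its declared format."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-standard residue(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class ProfileMatrix:
    """L x 20 substitution-score profile, columns in canonical residue order.

    Row *i* holds the position-specific scores for residue position *i + 1*;
    column *j* is the score of substituting into amino acid ``AMINO_ACIDS[j]``.
    """

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise FormatError(
                f"profile {self.protein_id!r}: expected Lx20 matrix, "
                f"got shape {scores.shape}"
            )
        if scores.shape[0] == 0:
            raise FormatError(f"profile {self.protein_id!r}: zero rows")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


@dataclasses.dataclass(frozen=True)
class TopologyCall:
    """An external topology predictor's call for one protein.

    A protein is regarded as membrane when at least one transmembrane
    segment is predicted.
    """

    protein_id: str
    tms_count: int

    def __post_init__(self) -> None:
        if self.tms_count < 0:
            raise FormatError(
                f"topology call {self.protein_id!r}: negative tms_count"
            )

    @property
    def is_membrane(self) -> bool:
        return self.tms_count >= 1


@dataclasses.dataclass
class LabeledDataset:
    """Records plus per-id binary labels, optional profiles and topology calls.

    Labels are 1 for membrane (positive class) and 0 for nonmembrane.
    """

    records: list[ProteinRecord]
    labels: dict[str, int]
    profiles: dict[str, ProfileMatrix] | None = None
    topology: dict[str, TopologyCall] | None = None

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        missing = set(self.labels) - ids
        if missing:
            raise ValueError(f"labels reference unknown ids: {sorted(missing)[:5]}")
        if self.profiles:
            by_id = {r.id: r for r in self.records}
            for pid, prof in self.profiles.items():
                rec = by_id.get(pid)
                if rec is not None and prof.length != rec.length:
                    raise ValueError(
                        f"profile {pid!r} has {prof.length} rows but the "
                        f"sequence has {rec.length} residues"
                    )

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def y(self) -> np.ndarray:
        """Label vector aligned with record order."""
        return np.array([self.labels[r.id] for r in self.records], dtype=int)


def normalize_sequence(seq: str, rec_id: str = "?", policy: AlphabetPolicy = "strict") -> str:
    """Uppercase a raw sequence and resolve non-standard residue codes.

    Under ``strict`` any character outside the 20-letter alphabet is an
    error.  Under ``map`` the ambiguity codes B/Z/J/U/O are replaced by their
    nearest standard residue; X is always an error because it carries no
    compositional information.
    """
    seq = seq.upper().replace("*", "").replace("-", "")
    out = []
    for ch in seq:
        if ch in AA_INDEX:
            out.append(ch)
        elif policy == "map" and ch in AMBIGUOUS_MAP:
            out.append(AMBIGUOUS_MAP[ch])
        else:
            raise FormatError(
                f"record {rec_id!r}: unmappable character {ch!r} "
                f"(policy={policy})"
            )
    return "".join(out)


def read_fasta(path: str | Path, policy: AlphabetPolicy = "strict") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited token of the header.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(rec.id, normalize_sequence(str(rec.seq), rec.id, policy))
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_pssm(path: str | Path, protein_id: str | None = None) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM export into a :class:`ProfileMatrix`.

    Only the first numeric block (the 20 log-odds columns) feeds the profile;
    the weighted-percentage block and the two trailing per-row statistics are
    validated for presence but discarded.  Columns are permuted from the
    file's declared order into the canonical alphabetical order.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    lines = path.read_text().splitlines()

    header_order: str | None = None
    header_idx = -1
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 40 and all(t in AA_INDEX for t in tokens[:40]):
            header_order = "".join(tokens[:20])
            header_idx = i
            break
    if header_order is None:
        raise FormatError(f"{path}: no PSSM column-header line found")
    if sorted(header_order) != sorted(AMINO_ACIDS):
        raise FormatError(f"{path}: header is not a 20-residue permutation")

    rows: list[list[float]] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            break
        if not tokens[0].isdigit():
            break
        numeric = tokens[2:]
        # 40 score fields, optionally followed by information / weight columns.
        if len(numeric) < 40:
            raise FormatError(
                f"{path}:{lineno}: expected 40 score fields, got {len(numeric)}"
            )
        try:
            scores = [float(t) for t in numeric[:40]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric score field") from exc
        if int(tokens[0]) != expected_pos:
            raise FormatError(
                f"{path}:{lineno}: position {tokens[0]} out of order"
            )
        expected_pos += 1
        rows.append(scores[:20])

    if not rows:
        raise FormatError(f"{path}: PSSM contains no residue rows")

    raw = np.array(rows, dtype=float)
    perm = [header_order.index(aa) for aa in AMINO_ACIDS]
    return ProfileMatrix(protein_id, raw[:, perm])


def write_pssm(
    record: ProteinRecord,
    profile: ProfileMatrix,
    path: str | Path,
    column_order: str = PSIBLAST_ORDER,
) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read by :func:`read_pssm`.

    The percentage block is emitted as zeros; the reader ignores it.
    """
    if profile.length != record.length:
        raise ValueError("profile rows must match sequence length")
    perm = [AA_INDEX[aa] for aa in column_order]
    mat = profile.scores[:, perm]
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "           " + "  ".join(column_order) + "   " + "   ".join(column_order),
    ]
    for i, (res, row) in enumerate(zip(record.sequence, mat), start=1):
        scores = " ".join(f"{v:6.0f}" if v == int(v) else f"{v:6.2f}" for v in row)
        pcts = " ".join("0" for _ in range(20))
        lines.append(f"{i:5d} {res} {scores}  {pcts}  0.00 0.00")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology_calls(path: str | Path) -> list[TopologyCall]:
    """Read a TSV topology-call table with columns ``id`` and ``tms_count``."""
    calls: list[TopologyCall] = []
    seen: set[str] = set()
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields[0].lower() == "id":
            continue
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected id<TAB>tms_count")
        pid = fields[0]
        if pid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate id {pid!r}")
        seen.add(pid)
        try:
            tms = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer tms_count") from exc
        calls.append(TopologyCall(pid, tms))
    return calls


def write_topology_calls(calls: Iterable[TopologyCall], path: str | Path) -> None:
    lines = ["id\ttms_count"] + [f"{c.protein_id}\t{c.tms_count}" for c in calls]
    Path(path).write_text("\n".join(lines) + "\n")


LABEL_NAMES = {"membrane": 1, "nonmembrane": 0}


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a TSV label table ``id<TAB>label``, label in {membrane, nonmembrane}."""
    labels: dict[str, int] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() == "id":
            continue
        if len(fields) < 2 or fields[1] not in LABEL_NAMES:
            raise FormatError(
                f"{path}:{lineno}: expected id<TAB>{{membrane,nonmembrane}}"
            )
        if fields[0] in labels:
            raise FormatError(f"{path}:{lineno}: duplicate id {fields[0]!r}")
        labels[fields[0]] = LABEL_NAMES[fields[1]]
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    inv = {1: "membrane", 0: "nonmembrane"}
    lines = ["id\tlabel"] + [f"{pid}\t{inv[v]}" for pid, v in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}: malformed config line {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        cfg[key] = value
    return cfg


def validate_min_length(
    records: list[ProteinRecord], min_len: int = 50
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (kept, removed) by the minimum-length rule.

    Sequences shorter than ``min_len`` residues (default 50) are removed as
    likely fragments; input order is preserved in both partitions.
    """
    kept = [r for r in records if r.length >= min_len]
    removed = [r for r in records if r.length < min_len]
    return kept, removed
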