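"""Reading, validation and in-memory representation of labeled RNA site datasets.

A sample is a fixed, odd-length RNA window centered on a uridine; the binary
label says whether that central U is pseudouridylated (positive, coded +1) or
not (negative, coded -1). Datasets arrive either as a pair of FASTA files
(one per class) or as a single CSV with columns ``id,sequence,label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

POSITIVE = 1
NEGATIVE = -1

_ALPHABET = frozenset("ACGU")

#: accepted label spellings -> internal +1/-1 coding
LABEL_MAP = {
    "1": POSITIVE,
    "+1": POSITIVE,
    "pos": POSITIVE,
    "positive": POSITIVE,
    "0": NEGATIVE,
    "-1": NEGATIVE,
    "neg": NEGATIVE,
    "negative": NEGATIVE,
}


class SequenceValidationError(ValueError):
    """Base class for per-record validation failures."""


class LengthError(SequenceValidationError):
    pass


class AlphabetError(SequenceValidationError):
    pass


class CenterError(SequenceValidationError):
    pass


class DatasetError(ValueError):
    """Dataset-level problems: duplicate ids, empty files, mixed lengths..."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA window: odd length, alphabet {A,C,G,U}, U at the center.

    Positions are 1-based in user-facing messages; the center sits at
    position (L+1)/2.
    """

    residues: str

    def __post_init__(self) -> None:
        s = self.residues
        if len(s) % 2 == 0 or len(s) == 0:
            raise LengthError(f"sequence length {len(s)} is not a positive odd number")
        bad = set(s) - _ALPHABET
        if bad:
            raise AlphabetError(f"invalid residues {sorted(bad)} (alphabet is A,C,G,U)")
        c = len(s) // 2
        if s[c] != "U":
            raise CenterError(
                f"residue at center position {c + 1} is {s[c]!r}, expected U"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def validate_sequence(raw: str, expected_length: int, record_id: str = "?") -> RnaSequence:
    """Validate ``raw``, uppercasing and transliterating T->U (DNA-alphabet
    deposits are common); any other IUPAC ambiguity code is rejected.

    ``record_id`` is only used to name the offending record in error messages.
    """
    if not raw:
        raise LengthError(f"record {record_id}: empty sequence")
    s = raw.strip().upper().replace("T", "U")
    if len(s) != expected_length:
        raise LengthError(
            f"record {record_id}: length {len(s)}, expected {expected_length}"
        )
    bad = set(s) - _ALPHABET
    if bad:
        raise AlphabetError(
            f"record {record_id}: invalid residues {sorted(bad)} (alphabet is A,C,G,U/T)"
        )
    center = (expected_length + 1) // 2
    if s[center - 1] != "U":
        raise CenterError(
            f"record {record_id}: residue at center position {center} is "
            f"{s[center - 1]!r}, expected U"
        )
    return RnaSequence(s)


@dataclass
class LabeledDataset:
    """An ordered collection of (id, sequence, label) records of one length."""

    ids: list[str]
    sequences: list[RnaSequence]
    labels: np.ndarray  # +1 / -1, aligned with sequences
    species_tag: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.ids) == len(self.sequences) == len(self.labels)):
            raise DatasetError("ids, sequences and labels must align")
        if len(self.ids) == 0:
            raise DatasetError("dataset is empty")
        if len(set(self.ids)) != len(self.ids):
            seen, dups = set(), set()
            for i in self.ids:
                (dups if i in seen else seen).add(i)
            raise DatasetError(f"duplicate ids: {sorted(dups)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise DatasetError(f"mixed sequence lengths {sorted(lengths)}")
        if not set(np.unique(self.labels)) <= {POSITIVE, NEGATIVE}:
            raise DatasetError("labels must be +1/-1")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == POSITIVE))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == NEGATIVE))

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            species_tag=self.species_tag,
        )

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise DatasetError("fitting requires at least one record of each class")


def read_fasta(path_pos, path_neg, expected_length: int, species_tag: str = "") -> LabeledDataset:
    """Read a positive/negative FASTA pair; positives first, order preserved."""
    ids: list[str] = []
    seqs: list[RnaSequence] = []
    labels: list[int] = []
    for path, label in ((path_pos, POSITIVE), (path_neg, NEGATIVE)):
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise DatasetError(f"{path}: no FASTA records found")
        for rec in records:
            ids.append(rec.id)
            seqs.append(validate_sequence(str(rec.seq), expected_length, rec.id))
            labels.append(label)
    return LabeledDataset(ids, seqs, np.array(labels), species_tag)


def write_fasta(dataset: LabeledDataset, path_pos, path_neg) -> None:
    """Inverse of :func:`read_fasta` (used for round-trips and the simulator CLI)."""
    pos = [
        SeqRecord(Seq(str(s)), id=i, description="")
        for i, s, y in zip(dataset.ids, dataset.sequences, dataset.labels)
        if y == POSITIVE
    ]
    neg = [
        SeqRecord(Seq(str(s)), id=i, description="")
        for i, s, y in zip(dataset.ids, dataset.sequences, dataset.labels)
        if y == NEGATIVE
    ]
    SeqIO.write(pos, str(path_pos), "fasta")
    SeqIO.write(neg, str(path_neg), "fasta")


def read_csv_dataset(path, expected_length: int, species_tag: str = "") -> LabeledDataset:
    """Read an ``id,sequence,label`` CSV; labels may be 1/0, 1/-1 or pos/neg."""
    df = pd.read_csv(path, dtype=str)
    missing = {"id", "sequence", "label"} - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing columns {sorted(missing)}")
    ids, seqs, labels = [], [], []
    for _, row in df.iterrows():
        token = str(row["label"]).strip().lower()
        if token not in LABEL_MAP:
            raise DatasetError(f"record {row['id']}: unknown label token {row['label']!r}")
        ids.append(str(row["id"]))
        seqs.append(validate_sequence(str(row["sequence"]), expected_length, str(row["id"])))
        labels.append(LABEL_MAP[token])
    return LabeledDataset(ids, seqs, np.array(labels), species_tag)


def write_csv_dataset(dataset: LabeledDataset, path) -> None:
    pd.DataFrame(
        {
            "id": dataset.ids,
            "sequence": [str(s) for s in dataset.sequences],
            "label": [1 if y == POSITIVE else 0 for y in dataset.labels],
        }
    ).to_csv(path, index=False)
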