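"""FASTA input/output, sequence validation, and labeled-dataset assembly.

Protein sequences are modelled over the 20 standard amino-acid letters.
Records carrying ambiguous or non-standard letters (B, X, Z, and also the
rare translated U/O, gap '-' and stop '*') cannot be encoded as composition
vectors and are rejected at validation time with a per-record reason.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FastaParseError(ValueError):
    """Raised when a FASTA file is syntactically malformed or empty."""


class ValidationError(ValueError):
    """Raised by validate_records(policy='fail') on an invalid sequence."""


class DatasetError(ValueError):
    """Raised when labeled records cannot form a coherent dataset."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    the full header line is retained as ``description``.
    """

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RejectedRecord:
    record: ProteinRecord
    reason: str


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into ProteinRecords (no validation applied).

    Sequence lines are concatenated and uppercased. Raises
    :class:`FastaParseError` on an empty file or on sequence data
    appearing before the first header.
    """
    path = Path(path)
    text = path.read_text()
    stripped = [ln for ln in text.splitlines() if ln.strip()]
    if not stripped:
        raise FastaParseError(f"{path}: empty FASTA file")
    if not stripped[0].startswith(">"):
        raise FastaParseError(
            f"{path}: sequence data before first '>' header"
        )
    records = [
        ProteinRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            description=rec.description,
        )
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to ``path`` in FASTA format (60-column wrap)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or r.id)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecords, handle, "fasta")


def _invalid_reason(sequence: str) -> str | None:
    if len(sequence) == 0:
        return "empty-sequence"
    for ch in sequence:
        if ch in STANDARD_AMINO_ACIDS:
            continue
        if ch == "-":
            return "gap-character"
        if ch == "*":
            return "stop-character"
        return f"nonstandard-letter:{ch}"
    return None


def validate_records(
    records: Iterable[ProteinRecord],
    policy: Literal["drop", "fail"] = "drop",
) -> tuple[list[ProteinRecord], list[RejectedRecord]]:
    """Canonicalize to uppercase and screen out non-standard sequences.

    Any sequence containing a character outside the 20-letter alphabet
    (including B/X/Z ambiguity codes, U/O, gaps and stops) is rejected.
    With ``policy='drop'`` the offenders are returned in the rejected
    list with a reason code; with ``policy='fail'`` the first offender
    raises :class:`ValidationError`.

    Validation is idempotent: a second pass over ``kept`` rejects nothing.
    """
    if policy not in ("drop", "fail"):
        raise ValueError(f"unknown policy {policy!r}")
    kept: list[ProteinRecord] = []
    rejected: list[RejectedRecord] = []
    for rec in records:
        seq = rec.sequence.upper()
        reason = _invalid_reason(seq)
        if reason is None:
            if seq != rec.sequence:
                rec = ProteinRecord(rec.id, seq, rec.description)
            kept.append(rec)
        elif policy == "fail":
            raise ValidationError(f"record {rec.id!r}: {reason}")
        else:
            rejected.append(RejectedRecord(rec, reason))
    return kept, rejected


@dataclass
class LabeledDataset:
    """Protein records paired one-to-one with binary class labels.

    Label 1 marks the positive class (antioxidant), 0 the negative
    class (non-antioxidant). Record ids must be unique.
    """

    records: list[ProteinRecord]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != len(self.labels):
            raise DatasetError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise DatasetError("labels must be binary (0/1)")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == 0).sum())

    def class_counts(self) -> tuple[int, int]:
        """(n_pos, n_neg)."""
        return self.n_pos, self.n_neg

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(
            [self.records[i] for i in indices], self.labels[indices]
        )


def load_labeled(
    pos_fasta: str | Path,
    neg_fasta: str | Path,
    policy: Literal["drop", "fail"] = "drop",
) -> LabeledDataset:
    """Load a positive/negative FASTA pair into a LabeledDataset.

    Records from ``pos_fasta`` are labeled 1, from ``neg_fasta`` 0.
    Both files are validated with ``policy``. A record id appearing in
    both files is an error; an empty class after validation is only a
    warning.
    """
    pos, pos_rej = validate_records(read_fasta(pos_fasta), policy)
    neg, neg_rej = validate_records(read_fasta(neg_fasta), policy)
    overlap = {r.id for r in pos} & {r.id for r in neg}
    if overlap:
        raise DatasetError(
            f"ids present in both classes: {sorted(overlap)[:5]}"
        )
    for name, kept in (("positive", pos), ("negative", neg)):
        if not kept:
            warnings.warn(
                f"{name} class is empty after validation", stacklevel=2
            )
    records = pos + neg
    labels = np.concatenate(
        [np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)]
    )
    return LabeledDataset(records, labels)


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` table with labels in {0,1}."""
    table: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DatasetError(f"{path}:{lineno}: expected 'id<TAB>label'")
        ident, label = parts[0].strip(), parts[1].strip()
        if label not in ("0", "1"):
            raise DatasetError(f"{path}:{lineno}: label must be 0 or 1")
        if ident in table:
            raise DatasetError(f"{path}:{lineno}: duplicate id {ident!r}")
        table[ident] = int(label)
    return table


def write_label_table(ds: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec, lab in zip(ds.records, ds.labels):
            fh.write(f"{rec.id}\t{int(lab)}\n")


def load_labeled_table(
    fasta: str | Path,
    label_table: str | Path,
    policy: Literal["drop", "fail"] = "drop",
) -> LabeledDataset:
    """Load one annotated FASTA whose labels come from a TSV table."""
    kept, _ = validate_records(read_fasta(fasta), policy)
    table = read_label_table(label_table)
    missing = [r.id for r in kept if r.id not in table]
    if missing:
        raise DatasetError(f"ids missing from label table: {missing[:5]}")
    labels = np.array([table[r.id] for r in kept], dtype=int)
    return LabeledDataset(kept, labels)
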