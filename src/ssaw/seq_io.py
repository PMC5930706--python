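"""Sequence and label I/O plus the alphabet model shared by all stages.

Sequences are plain residue strings over a declared alphabet (DNA = ACGT,
protein = the 20 standard one-letter codes).  Residues are uppercased on
read; ``U`` is mapped to ``T`` under the DNA alphabet; any other symbol
outside the alphabet is rejected with an error naming the record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Alphabet",
    "DNA",
    "PROTEIN",
    "SequenceRecord",
    "SequenceCollection",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet.

    Symbols are kept in strict lexicographic order; k-mer slot ranking
    depends on this ordering.
    """

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.symbols) != sorted(self.symbols):
            raise ValueError(f"alphabet {self.name} symbols must be sorted")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


DNA = Alphabet("DNA", tuple("ACGT"))
PROTEIN = Alphabet("PROTEIN", tuple("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SequenceRecord:
    """One identified sequence; ``length`` is the residue count M."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


class SequenceCollection:
    """An ordered set of records over one alphabet, optionally labelled.

    Record order is preserved exactly as given (file order for FASTA input);
    ids must be unique and every label key must name an existing record.
    """

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        alphabet: Alphabet,
        labels: dict[str, str] | None = None,
    ) -> None:
        self.records = list(records)
        self.alphabet = alphabet
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        self._by_id = {r.id: r for r in self.records}
        self.labels: dict[str, str] = {}
        if labels:
            for rid, lab in labels.items():
                if rid not in self._by_id:
                    raise KeyError(f"label refers to unknown id {rid!r}")
                self.labels[rid] = lab

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rid: str) -> SequenceRecord:
        return self._by_id[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceCollection):
            return NotImplemented
        return (
            self.records == other.records
            and self.alphabet == other.alphabet
            and self.labels == other.labels
        )

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def mean_length(self) -> float:
        if not self.records:
            raise ValueError("empty collection has no mean length")
        return sum(r.length for r in self.records) / len(self.records)

    def with_labels(self, labels: dict[str, str]) -> "SequenceCollection":
        return SequenceCollection(self.records, self.alphabet, labels)

    def subset(self, ids: Iterable[str]) -> "SequenceCollection":
        ids = list(ids)
        records = [self._by_id[i] for i in ids]
        labels = {i: self.labels[i] for i in ids if i in self.labels}
        return SequenceCollection(records, self.alphabet, labels)


def _normalize(residues: str, alphabet: Alphabet, record_id: str) -> str:
    residues = residues.upper()
    if alphabet.name == "DNA":
        residues = residues.replace("U", "T")
    allowed = set(alphabet.symbols)
    for sym in residues:
        if sym not in allowed:
            raise ValueError(
                f"record {record_id!r} contains symbol {sym!r} outside "
                f"the {alphabet.name} alphabet"
            )
    return residues


def read_fasta(path: str | Path, alphabet: Alphabet = DNA) -> SequenceCollection:
    """Read a FASTA file into a :class:`SequenceCollection`.

    Wrapped sequence lines are concatenated; residues are normalized
    (uppercase, U->T for DNA) and validated against the alphabet.  Sequence
    data appearing before the first ``>`` header is a parse error naming the
    line.  An empty file yields an empty collection.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first "
                    "FASTA header"
                )
            break
    records = [
        SequenceRecord(rec.id, _normalize(str(rec.seq), alphabet, rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return SequenceCollection(records, alphabet)


def write_fasta(collection: SequenceCollection, path: str | Path, width: int = 70) -> None:
    """Write a collection as FASTA, wrapping sequence lines at ``width``."""
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in collection]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_labels(path: str | Path, collection: SequenceCollection) -> SequenceCollection:
    """Attach family labels from a two-column TSV (id, family).

    Ids absent from the TSV stay unlabelled; TSV rows naming an id missing
    from the collection are skipped with a logged warning.
    """
    labels: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two TSV columns")
            rid, fam = parts[0], parts[1]
            if rid not in collection:
                logger.warning("label file names unknown id %r; row skipped", rid)
                continue
            labels[rid] = fam
    return collection.with_labels(labels)


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rid, fam in labels.items():
            fh.write(f"{rid}\t{fam}\n")


def write_matrix(
    rows: Sequence[Sequence[float]],
    row_ids: Sequence[str],
    path: str | Path,
    col_ids: Sequence[str] | None = None,
) -> None:
    """Write a rectangular numeric table as TSV with full repr precision.

    The output round-trips bit-identically through :func:`read_matrix`.
    """
    rows = [list(r) for r in rows]
    if len(rows) != len(row_ids):
        raise ValueError("row_ids length must match number of rows")
    ncol = len(rows[0]) if rows else 0
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged rows: all rows must have equal length")
    if col_ids is None:
        col_ids = [f"c{j + 1}" for j in range(ncol)]
    if len(col_ids) != ncol:
        raise ValueError("col_ids length must match number of columns")
    with Path(path).open("w") as fh:
        fh.write("\t".join(["id", *col_ids]) + "\n")
        for rid, row in zip(row_ids, rows):
            fh.write("\t".join([rid, *(repr(float(v)) for v in row)]) + "\n")


def read_matrix(path: str | Path) -> tuple[list[str], list[list[float]], list[str]]:
    """Read a TSV written by :func:`write_matrix` -> (row_ids, rows, col_ids)."""
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_ids = header[1:]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return row_ids, rows, col_ids
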