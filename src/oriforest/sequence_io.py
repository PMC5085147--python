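"""FASTA input/output and labelled benchmark assembly.

The unit of analysis is a pre-cut, fixed-length DNA segment.  A benchmark
is two FASTA files — one per class — whose sequences all share a single
common length L.  Class membership is carried by file membership, never by
header tags.

Ambiguity codes (N, R, Y, ...) are rejected rather than skipped: the
propensity algebra downstream has no defined frequency contribution for
them, and silently dropping them would corrupt per-position denominators.
Lowercase (soft-masked) input is accepted and uppercased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import (
    AlphabetError,
    ContaminationError,
    EmptyInputError,
    InputDataError,
    LengthMismatchError,
)

ALPHABET = "ACGT"
_ALPHABET_SET = frozenset(ALPHABET)

__all__ = [
    "ALPHABET",
    "SequenceRecord",
    "BenchmarkDataset",
    "read_fasta",
    "write_fasta",
    "load_benchmark",
]


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus a fixed-length DNA string over {A, C, G, T}.

    The sequence is uppercased on construction; any other character raises
    :class:`AlphabetError` naming the record and the offending character.
    A record must hold at least one dinucleotide (length >= 2).
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _ALPHABET_SET
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains non-ACGT character(s): "
                f"{', '.join(repr(c) for c in sorted(bad))}"
            )
        if len(self.seq) < 2:
            raise InputDataError(
                f"record {self.id!r} is shorter than one dinucleotide "
                f"(length {len(self.seq)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class BenchmarkDataset:
    """Labelled positive/negative collections of equal-length records.

    Attributes
    ----------
    positives, negatives : list of SequenceRecord
        The two class subsets.  Every record has length exactly ``length``.
    length : int
        The common segment length L in bp.
    """

    positives: list[SequenceRecord]
    negatives: list[SequenceRecord]
    length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.length == 0:
            pool = self.positives or self.negatives
            if not pool:
                raise EmptyInputError("benchmark dataset has no records at all")
            self.length = len(pool[0])
        offenders = [
            r.id
            for r in [*self.positives, *self.negatives]
            if len(r) != self.length
        ]
        if offenders:
            raise LengthMismatchError(
                f"expected every sequence to have length {self.length}; "
                f"offending record(s): {', '.join(offenders[:10])}"
                + (" ..." if len(offenders) > 10 else "")
            )
        shared = {r.seq for r in self.positives} & {r.seq for r in self.negatives}
        if shared:
            raise ContaminationError(
                f"{len(shared)} identical sequence(s) appear in both classes"
            )

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def records(self) -> list[SequenceRecord]:
        """All records, positives first, in stored order."""
        return [*self.positives, *self.negatives]

    def labels(self) -> list[int]:
        """Binary labels aligned with :meth:`records` (1 = positive)."""
        return [1] * self.n_pos + [0] * self.n_neg

    def counts(self) -> dict:
        return {"n_pos": self.n_pos, "n_neg": self.n_neg, "length": self.length}

    def counts_json(self) -> str:
        return json.dumps(self.counts())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Wrapped and single-line dialects are both accepted, CRLF tolerated
    (Biopython handles both).  Sequences are uppercased; U is *not* mapped
    to T — the input is DNA.
    """
    path = Path(path)
    try:
        with open(path) as handle:
            bio_records = list(SeqIO.parse(handle, "fasta"))
    except OSError as exc:
        raise InputDataError(f"cannot read FASTA file {path}: {exc}") from exc
    except ValueError as exc:
        raise InputDataError(f"cannot parse {path} as FASTA: {exc}") from exc
    if not bio_records:
        raise EmptyInputError(f"FASTA file {path} contains no records")
    return [SequenceRecord(id=r.id, seq=str(r.seq)) for r in bio_records]


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records to ``path`` in 60-column wrapped FASTA.

    Round-trip guarantee: ``read_fasta`` on the written file reproduces
    (id, seq) pairs exactly.
    """
    if not records:
        raise EmptyInputError("refusing to write an empty FASTA file")
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    try:
        with open(path, "w") as handle:
            SeqIO.write(bio, handle, "fasta")
    except OSError as exc:
        raise InputDataError(f"cannot write FASTA file {path}: {exc}") from exc


def load_benchmark(pos_path: str | Path, neg_path: str | Path) -> BenchmarkDataset:
    """Assemble a labelled benchmark from one positive and one negative FASTA.

    All sequences across both files must share one common length; mixed
    lengths raise :class:`LengthMismatchError` listing offenders, and a
    sequence present in both files raises :class:`ContaminationError`.
    """
    positives = read_fasta(pos_path)
    negatives = read_fasta(neg_path)
    return BenchmarkDataset(positives=positives, negatives=negatives)


def records_from_strings(seqs: Iterable[str], prefix: str = "seq") -> list[SequenceRecord]:
    """Convenience: wrap bare strings as records with generated ids."""
    return [SequenceRecord(id=f"{prefix}_{i}", seq=s) for i, s in enumerate(seqs)]
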