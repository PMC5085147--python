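"""Dinucleotide position-specific propensity (DPSP) feature encoding.

The encoding represents a length-L DNA segment as a real vector of
dimension Z = L - 1 under the general pseudo K-tuple nucleotide
composition framework.  Component u of the vector is the *propensity*
P(i, u) of the dinucleotide i observed at position u of the segment,
where the propensity matrix

    P(i, j) = Q+(2mer_i | j) - Q-(2mer_i | j)

is the difference between the per-position occurrence frequencies of
dinucleotide i at position j in the positive (origin) and negative
(non-origin) training sequences.  For the canonical 300 bp segments this
is a 16 x 299 matrix and Z = 299.

Positions are 1-based at every public interface: position j refers to the
pair (N_j, N_{j+1}).  The frequency denominator is the number of
sequences in the class subset — each sequence contributes exactly one
dinucleotide token per position, so Q(.|j) is a per-position categorical
distribution over the 16 dinucleotides.

The machinery is parameterised by the tuple size k (rows = 4**k,
columns = L - k + 1); k = 2 is the canonical, fully tested configuration.
No smoothing is applied by default; a pseudocount knob exists for
small-sample work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    AlphabetError,
    ConfigError,
    EmptyInputError,
    InputDataError,
    LengthMismatchError,
)
from .sequence_io import ALPHABET, BenchmarkDataset, SequenceRecord

__all__ = [
    "DINUCLEOTIDES",
    "dinucleotide_rank",
    "PositionalFrequencyTable",
    "PropensityMatrix",
    "positional_frequencies",
    "build_propensity",
    "encode",
    "encode_all",
    "frequency_profile",
    "DPSPEncoder",
    "save_propensity",
    "load_propensity",
]

#: The 16 dinucleotides in lexicographic order; rank r is DINUCLEOTIDES[r-1].
DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in ALPHABET for b in ALPHABET)

_BASE_INDEX = {base: i for i, base in enumerate(ALPHABET)}

# uint8 lookup from ASCII code to base index, 255 = invalid
_ASCII_TO_BASE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ASCII_TO_BASE[ord(_b)] = _i


def kmer_codes(k: int) -> tuple[str, ...]:
    """All 4**k k-mers over ACGT in lexicographic order."""
    codes = [""]
    for _ in range(k):
        codes = [c + b for c in codes for b in ALPHABET]
    return tuple(codes)


def dinucleotide_rank(code: str) -> int:
    """Lexicographic rank (1..16) of a dinucleotide: AA -> 1, ..., TT -> 16."""
    if len(code) != 2:
        raise AlphabetError(f"expected a two-character dinucleotide, got {code!r}")
    code = code.upper()
    try:
        return 4 * _BASE_INDEX[code[0]] + _BASE_INDEX[code[1]] + 1
    except KeyError:
        bad = next(c for c in code if c not in _BASE_INDEX)
        raise AlphabetError(
            f"dinucleotide {code!r} contains non-ACGT character {bad!r}"
        ) from None


def _as_base_matrix(records: Sequence[SequenceRecord | str], length: int) -> np.ndarray:
    """(n, L) uint8 matrix of base indices; validates alphabet and lengths."""
    if len(records) == 0:
        raise EmptyInputError("no sequences supplied")
    seqs = [r.seq if isinstance(r, SequenceRecord) else str(r).upper() for r in records]
    bad = [i for i, s in enumerate(seqs) if len(s) != length]
    if bad:
        raise LengthMismatchError(
            f"expected length {length}; sequence(s) at index "
            f"{', '.join(map(str, bad[:10]))} differ"
        )
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = _ASCII_TO_BASE[raw].reshape(len(seqs), length)
    if (mat == 255).any():
        i, j = np.argwhere(mat == 255)[0]
        raise AlphabetError(
            f"sequence index {i} has non-ACGT character {seqs[i][j]!r} "
            f"at base position {j + 1}"
        )
    return mat


def _kmer_code_matrix(base_mat: np.ndarray, k: int) -> np.ndarray:
    """(n, L-k+1) matrix of 0-based k-mer ranks from a base-index matrix."""
    n, length = base_mat.shape
    cols = length - k + 1
    codes = np.zeros((n, cols), dtype=np.int64)
    for offset in range(k):
        codes = codes * 4 + base_mat[:, offset : offset + cols]
    return codes


@dataclass
class PositionalFrequencyTable:
    """Per-position k-mer occurrence frequencies of one class subset.

    ``values[i, j]`` is the fraction of sequences whose k-mer starting at
    (1-based) position j+1 equals the rank-(i+1) k-mer.  Each column is a
    categorical distribution (sums to 1); with no smoothing every entry is
    a multiple of 1/n_sequences.
    """

    values: np.ndarray
    n_sequences: int
    class_tag: str = "unlabelled"
    k: int = 2

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def row(self, code: str) -> np.ndarray:
        """Frequency series of one k-mer across all positions."""
        if self.k == 2:
            return self.values[dinucleotide_rank(code) - 1]
        return self.values[kmer_codes(self.k).index(code.upper())]


@dataclass
class PropensityMatrix:
    """Position-specific propensity matrix P = Q+ - Q-.

    Shape is (4**k, L - k + 1); entries lie in [-1, 1] and each column
    sums to 0.  ``provenance`` records the training subsets that produced
    the matrix so downstream artefacts can state what they were fit on.
    """

    values: np.ndarray
    length: int
    k: int = 2
    provenance: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def lookup(self, code: str, position: int) -> float:
        """P(code, position) with the 1-based position convention."""
        if not 1 <= position <= self.n_positions:
            raise ConfigError(
                f"position {position} outside 1..{self.n_positions}"
            )
        if self.k == 2:
            row = dinucleotide_rank(code) - 1
        else:
            row = kmer_codes(self.k).index(code.upper())
        return float(self.values[row, position - 1])


def positional_frequencies(
    records: Sequence[SequenceRecord | str],
    length: int | None = None,
    *,
    k: int = 2,
    class_tag: str = "unlabelled",
    pseudocount: float = 0.0,
) -> PositionalFrequencyTable:
    """Count per-position k-mer occurrence frequencies over a class subset.

    Entry (i, j) is the number of records whose k-mer starting at 1-based
    position j equals the rank-i k-mer, divided by the number of records.
    With ``pseudocount`` alpha > 0, counts become (c + alpha) /
    (n + 4**k * alpha) — off by default.
    """
    if len(records) == 0:
        raise EmptyInputError("cannot compute frequencies over zero sequences")
    if length is None:
        first = records[0]
        length = len(first.seq if isinstance(first, SequenceRecord) else first)
    base_mat = _as_base_matrix(records, length)
    codes = _kmer_code_matrix(base_mat, k)
    n, cols = codes.shape
    counts = np.zeros((4**k, cols), dtype=np.float64)
    np.add.at(counts, (codes, np.broadcast_to(np.arange(cols), codes.shape)), 1.0)
    values = (counts + pseudocount) / (n + (4**k) * pseudocount)
    return PositionalFrequencyTable(
        values=values, n_sequences=n, class_tag=class_tag, k=k
    )


def build_propensity(
    pos: PositionalFrequencyTable,
    neg: PositionalFrequencyTable,
    *,
    provenance: dict | None = None,
) -> PropensityMatrix:
    """Element-wise difference of positive and negative frequency tables."""
    if pos.values.shape != neg.values.shape or pos.k != neg.k:
        raise LengthMismatchError(
            f"frequency tables disagree in shape: {pos.values.shape} (k={pos.k}) "
            f"vs {neg.values.shape} (k={neg.k})"
        )
    prov = {
        "n_pos": pos.n_sequences,
        "n_neg": neg.n_sequences,
        "k": pos.k,
    }
    if provenance:
        prov.update(provenance)
    return PropensityMatrix(
        values=pos.values - neg.values,
        length=pos.n_positions + pos.k - 1,
        k=pos.k,
        provenance=prov,
    )


def encode(record: SequenceRecord | str, matrix: PropensityMatrix) -> np.ndarray:
    """Encode one sequence as its Z = L - k + 1 dimensional propensity vector.

    Component u is the matrix entry for the k-mer observed at position u of
    the sequence — a pure lookup, no arithmetic on the sequence itself.
    """
    return encode_all([record], matrix)[0]


def encode_all(
    records: Sequence[SequenceRecord | str], matrix: PropensityMatrix
) -> np.ndarray:
    """Vectorised :func:`encode`; returns an (n, Z) array, row order preserved."""
    base_mat = _as_base_matrix(records, matrix.length)
    codes = _kmer_code_matrix(base_mat, matrix.k)
    return matrix.values[codes, np.arange(codes.shape[1])]


def frequency_profile(
    dataset: BenchmarkDataset, code: str, *, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position frequency series of one k-mer in each class.

    Returns ``(positive_series, negative_series)``, each of length
    L - k + 1, where entry j-1 is the class frequency of ``code`` at
    1-based position j.  This is the raw material of the classic
    two-line positional profile plot.
    """
    pos = positional_frequencies(dataset.positives, dataset.length, k=k,
                                 class_tag="positive")
    neg = positional_frequencies(dataset.negatives, dataset.length, k=k,
                                 class_tag="negative")
    return pos.row(code), neg.row(code)


class DPSPEncoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer computing the DPSP encoding.

    ``fit(X, y)`` estimates the propensity matrix from labelled training
    sequences (``X`` a sequence of equal-length ACGT strings or
    :class:`SequenceRecord`; ``y`` binary with 1 = positive class);
    ``transform(X)`` encodes sequences against the fitted matrix.

    Parameters
    ----------
    k : int, default 2
        Tuple size; rows of the matrix are the 4**k k-mers.
    pseudocount : float, default 0.0
        Additive smoothing of the per-position counts.  The canonical
        encoding uses raw frequencies (0.0).
    positive_label : default 1
        The label in ``y`` denoting the positive (origin) class.

    Attributes
    ----------
    propensity_ : PropensityMatrix
        The fitted (4**k, L - k + 1) propensity matrix.
    sequence_length_ : int
        Common training sequence length L.
    n_features_out_ : int
        Encoding dimension Z = L - k + 1.
    """

    def __init__(self, k: int = 2, pseudocount: float = 0.0, positive_label=1):
        self.k = k
        self.pseudocount = pseudocount
        self.positive_label = positive_label

    def fit(self, X, y):
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be non-negative")
        X = list(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise LengthMismatchError(
                f"{len(X)} sequences but {len(y)} labels"
            )
        mask = y == self.positive_label
        pos = [X[i] for i in np.flatnonzero(mask)]
        neg = [X[i] for i in np.flatnonzero(~mask)]
        if not pos or not neg:
            raise EmptyInputError(
                "both a positive and a negative subset are required to "
                "estimate propensities"
            )
        first = X[0]
        length = len(first.seq if isinstance(first, SequenceRecord) else first)
        ptab = positional_frequencies(pos, length, k=self.k,
                                      class_tag="positive",
                                      pseudocount=self.pseudocount)
        ntab = positional_frequencies(neg, length, k=self.k,
                                      class_tag="negative",
                                      pseudocount=self.pseudocount)
        self.propensity_ = build_propensity(ptab, ntab)
        self.sequence_length_ = length
        self.n_features_out_ = self.propensity_.n_positions
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "propensity_")
        return encode_all(list(X), self.propensity_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "propensity_")
        return np.asarray(
            [f"phi_{u}" for u in range(1, self.n_features_out_ + 1)], dtype=object
        )

    def _more_tags(self):
        return {"X_types": ["string"], "requires_y": True}


def save_propensity(matrix: PropensityMatrix, path: str | Path) -> None:
    """Serialise a propensity matrix as a labelled TSV (rows AA..TT).

    Columns are ``pos_1 .. pos_{L-k+1}`` following the 1-based position
    convention.  Provenance travels in a JSON sidecar written by the CLI.
    """
    labels = kmer_codes(matrix.k)
    frame = pd.DataFrame(
        matrix.values,
        index=list(labels),
        columns=[f"pos_{j}" for j in range(1, matrix.n_positions + 1)],
    )
    frame.to_csv(path, sep="\t", index_label="kmer", float_format="%.10g")


def load_propensity(path: str | Path, *, provenance: dict | None = None) -> PropensityMatrix:
    """Read a propensity matrix written by :func:`save_propensity`."""
    frame = pd.read_csv(path, sep="\t", index_col="kmer")
    k = len(str(frame.index[0]))
    expected = list(kmer_codes(k))
    if list(frame.index) != expected:
        raise InputDataError(
            f"propensity TSV rows are not the {4**k} k-mers in lexicographic order"
        )
    return PropensityMatrix(
        values=frame.to_numpy(dtype=np.float64),
        length=frame.shape[1] + k - 1,
        k=k,
        provenance=provenance or {},
    )
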