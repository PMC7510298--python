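"""Nucleotide-sequence primitives.

Validation, one-hot encoding of the twelve -35/-10 box nucleotides, and the
descriptive statistics (GC fraction, mean pairwise conservation) used for
dataset quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

#: Fixed channel order of the one-hot encoding. Training and prediction must
#: agree on this ordering; it is part of the model container format.
ALPHABET = "ACGT"

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

BOX_LENGTH = 6
PAIR_LENGTH = 2 * BOX_LENGTH

#: sigma-70 consensus elements.
CONSENSUS_35 = "TTGACA"
CONSENSUS_10 = "TATAAT"


class SequenceError(ValueError):
    """Raised for sequences outside the strict A/C/G/T alphabet."""


def clean_sequence(seq: str, *, name: str = "sequence") -> str:
    """Uppercase *seq* and verify it contains only A/C/G/T.

    Ambiguity codes (N, R, Y, ...) are rejected at this layer; callers that
    scan genomic windows skip ambiguous windows instead of imputing.
    """
    if not isinstance(seq, str):
        raise SequenceError(f"{name} must be a string, got {type(seq).__name__}")
    s = seq.upper()
    if len(s) == 0:
        raise SequenceError(f"{name} is empty; length >= 1 required")
    for pos, ch in enumerate(s):
        if ch not in _BASE_INDEX:
            raise SequenceError(
                f"{name} contains non-ACGT character {ch!r} at position {pos}"
            )
    return s


def is_acgt(seq: str) -> bool:
    """True if *seq* is non-empty and contains only A/C/G/T (any case)."""
    s = seq.upper()
    return len(s) > 0 and all(c in _BASE_INDEX for c in s)


@dataclass(frozen=True)
class BoxPair:
    """A -35 box and a -10 box, each exactly six nucleotides.

    The concatenation (box35 then box10) is the 12-mer the classifier sees;
    the spacer between the boxes is metadata carried elsewhere.
    """

    box35: str
    box10: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "box35", clean_sequence(self.box35, name="box35"))
        object.__setattr__(self, "box10", clean_sequence(self.box10, name="box10"))
        if len(self.box35) != BOX_LENGTH:
            raise SequenceError(
                f"box35 must be {BOX_LENGTH} nt, got {len(self.box35)}"
            )
        if len(self.box10) != BOX_LENGTH:
            raise SequenceError(
                f"box10 must be {BOX_LENGTH} nt, got {len(self.box10)}"
            )

    @property
    def concatenated(self) -> str:
        return self.box35 + self.box10

    @classmethod
    def from_concatenated(cls, twelve_mer: str) -> "BoxPair":
        s = clean_sequence(twelve_mer, name="12-mer")
        if len(s) != PAIR_LENGTH:
            raise SequenceError(f"expected {PAIR_LENGTH} nt, got {len(s)}")
        return cls(s[:BOX_LENGTH], s[BOX_LENGTH:])


CONSENSUS_PAIR = BoxPair(CONSENSUS_35, CONSENSUS_10)


def _as_twelve_mer(x: Union[BoxPair, str]) -> str:
    if isinstance(x, BoxPair):
        return x.concatenated
    s = clean_sequence(x, name="12-mer")
    if len(s) != PAIR_LENGTH:
        raise SequenceError(f"expected {PAIR_LENGTH} nt, got {len(s)}")
    return s


def one_hot_encode(pair: Union[BoxPair, str]) -> np.ndarray:
    """Encode a box pair (or concatenated 12-mer) as a 12 x 4 binary matrix.

    Rows are positions (box35 positions 0-5, box10 positions 6-11), columns
    follow :data:`ALPHABET` order A,C,G,T. Each row has exactly one 1; the
    mapping is bijective and :func:`one_hot_decode` inverts it.
    """
    s = _as_twelve_mer(pair)
    mat = np.zeros((PAIR_LENGTH, 4), dtype=np.uint8)
    for i, ch in enumerate(s):
        mat[i, _BASE_INDEX[ch]] = 1
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Invert :func:`one_hot_encode`. Raises on non-one-hot rows."""
    m = np.asarray(matrix)
    if m.shape != (PAIR_LENGTH, 4):
        raise SequenceError(f"expected shape ({PAIR_LENGTH}, 4), got {m.shape}")
    if not np.isin(m, (0, 1)).all() or not (m.sum(axis=1) == 1).all():
        raise SequenceError("matrix rows must be one-hot (binary, summing to 1)")
    return "".join(ALPHABET[j] for j in m.argmax(axis=1))


def encode_batch(pairs: Sequence[Union[BoxPair, str]]) -> np.ndarray:
    """Stack one-hot encodings into an (n, 12, 4) uint8 array."""
    if len(pairs) == 0:
        return np.zeros((0, PAIR_LENGTH, 4), dtype=np.uint8)
    return np.stack([one_hot_encode(p) for p in pairs])


def gc_fraction(seq: str) -> float:
    """(G + C) / length of the sequence, in [0, 1].

    The sigma-70 consensus TTGACA-TATAAT scores 2/12 (~17% when rounded to
    integer percent), far below the ~61% GC of the Pseudomonas genome — one
    reason box composition alone already carries signal.
    """
    s = clean_sequence(seq)
    return (s.count("G") + s.count("C")) / len(s)


def at_fraction(seq: str) -> float:
    """Complement of :func:`gc_fraction`."""
    return 1.0 - gc_fraction(seq)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; an involution on valid sequences."""
    s = clean_sequence(seq)
    return s.translate(_COMPLEMENT)[::-1]


def hamming_matches(a: str, b: str) -> int:
    """Number of positions at which equal-length sequences agree."""
    if len(a) != len(b):
        raise SequenceError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x == y for x, y in zip(a, b))


def mean_pairwise_conservation(pairs: Iterable[Union[BoxPair, str]]) -> float:
    """Mean positional identity over all unordered pairs of distinct 12-mers.

    For each unordered pair of distinct items, count the positions (out of 12)
    at which the two concatenated 12-mers carry the same base; return the mean
    of those counts. Self-pairs are excluded. A set of identical 12-mers gives
    12.0; i.i.d. uniform random 12-mers give 3.0 in expectation (12 x 1/4).

    Computed from per-position base counts in O(n * 12) rather than the
    O(n^2) double loop: the number of agreeing pairs at one position is
    sum_b C(count_b, 2).
    """
    seqs = [_as_twelve_mer(p) for p in pairs]
    n = len(seqs)
    if n < 2:
        raise SequenceError("need at least 2 sequences for pairwise conservation")
    counts = np.zeros((PAIR_LENGTH, 4), dtype=np.int64)
    for s in seqs:
        for i, ch in enumerate(s):
            counts[i, _BASE_INDEX[ch]] += 1
    agreeing_pairs = (counts * (counts - 1) // 2).sum()
    total_pairs = n * (n - 1) // 2
    return float(agreeing_pairs / total_pairs)


def expected_conservation(base_probabilities: Sequence[float] = (0.25,) * 4) -> float:
    """Expected pairwise conservation of i.i.d. 12-mers with the given
    per-base probabilities: 12 * sum(p_b^2). Uniform bases give 3.0."""
    p = np.asarray(base_probabilities, dtype=float)
    if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
        raise ValueError("base probabilities must be 4 values summing to 1")
    return float(PAIR_LENGTH * (p**2).sum())
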