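"""Sequence feature extraction: global k-mer vectors and both-end one-hot matrices.

A variable-length nucleotide sequence is summarised by two fixed-size
representations:

* a **global** k-mer occurrence vector of length ``4**k``, counted with a
  rolling Horner update (each slide of the window costs O(1) instead of
  O(k), because the next index is ``(index * 4 + digit) mod 4**k``);
* a **local** "both ends" (BE) matrix: the first ``L`` and last ``L``
  bases are concatenated into a 2L-base string and one-hot encoded over
  the channel order A, C, G, T.  Terminal structures (LTRs, TIRs,
  poly(A)/poly(T) tails) live in these windows.

Bases other than A/C/G/T never contribute: ambiguous windows are skipped
in the k-mer count and ambiguous or padded positions one-hot to a zero
row, so padding carries no signal.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

__all__ = [
    "DEFAULT_K",
    "DEFAULT_END_LENGTH",
    "kmer_index",
    "kmer_vector",
    "extract_both_ends",
    "one_hot",
    "reverse_complement",
    "FeaturePair",
    "featurize",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 7
DEFAULT_END_LENGTH = 600

_BASE_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_DIGIT_LUT = np.full(256, -1, dtype=np.int64)
for _b, _d in _BASE_DIGIT.items():
    _DIGIT_LUT[ord(_b)] = _d

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ONEHOT_LUT = np.zeros((256, 4))
for _b, _d in _BASE_DIGIT.items():
    _ONEHOT_LUT[ord(_b), _d] = 1.0


def kmer_index(window: str) -> int:
    """Decimal index of a k-length A/C/G/T word (A=0, C=1, G=2, T=3).

    The word is read as a quaternary number with the leftmost base most
    significant, evaluated by Horner's rule.

    Raises
    ------
    ValueError
        If the window contains a non-canonical base ("invalid window";
        callers counting k-mers simply skip such windows).
    """
    idx = 0
    for ch in window:
        d = _BASE_DIGIT.get(ch)
        if d is None:
            raise ValueError(f"invalid window {window!r}: non-ACGT base {ch!r}")
        idx = idx * 4 + d
    return idx


def kmer_vector(seq: str, k: int = DEFAULT_K, normalize: bool = True) -> np.ndarray:
    """Count every canonical k-mer window of `seq` into a length-4**k vector.

    Uses the incremental Horner update: the window index is maintained as
    a rolling base-4 number, so each slide does constant work.  Windows
    containing any non-ACGT symbol are skipped.  With ``normalize`` the
    counts are L1-normalised to frequencies (a zero vector stays zero).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    length = 4**k
    counts = np.zeros(length, dtype=np.float64)
    n = len(seq)
    if n < k:
        return counts
    digits = _DIGIT_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    idx = 0
    valid = 0  # canonical-base run length ending at the current position
    for d in digits:
        if d < 0:
            valid = 0
            idx = 0
            continue
        # Horner slide: append the new digit, let mod 4**k drop the oldest
        idx = (idx * 4 + d) % length
        valid += 1
        if valid >= k:
            counts[idx] += 1.0
    if normalize:
        total = counts.sum()
        if total > 0:
            counts /= total
    return counts


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_both_ends(seq: str, L: int = DEFAULT_END_LENGTH) -> str:
    """Concatenate the left-end and right-end L-base segments of `seq`.

    Sequences shorter than ``L`` are padded with ``N`` (right-padding for
    the left end, left-padding for the right end); the two segments may
    overlap when ``len(seq) < 2L``.  The result always has length 2L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        warnings.warn("extract_both_ends called on an empty sequence; returning all-N")
        return "N" * (2 * L)
    left = seq[:L].ljust(L, "N")
    right = seq[-L:].rjust(L, "N")
    return left + right


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a nucleotide string, rows ordered A, C, G, T.

    Any symbol outside A/C/G/T (including the N padding produced by
    `extract_both_ends`) encodes to an all-zero row.
    """
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ONEHOT_LUT[codes].copy()


class FeaturePair:
    """The (global, local) feature pair for one sequence.

    Attributes
    ----------
    kmer : ndarray, shape (4**k,)
        Global k-mer frequency (or count) vector.
    onehot : ndarray, shape (2L, 4)
        One-hot encoded both-end matrix.
    """

    __slots__ = ("kmer", "onehot", "k", "L")

    def __init__(self, kmer: np.ndarray, onehot: np.ndarray, k: int, L: int):
        if kmer.shape != (4**k,):
            raise ValueError(f"k-mer vector has shape {kmer.shape}, expected ({4**k},)")
        if onehot.shape != (2 * L, 4):
            raise ValueError(f"one-hot matrix has shape {onehot.shape}, expected ({2*L}, 4)")
        self.kmer = kmer
        self.onehot = onehot
        self.k = k
        self.L = L


def featurize(seq: str, k: int = DEFAULT_K, L: int = DEFAULT_END_LENGTH,
              normalize: bool = True) -> FeaturePair:
    """Compute the full feature pair for one sequence."""
    return FeaturePair(
        kmer_vector(seq, k=k, normalize=normalize),
        one_hot(extract_both_ends(seq, L=L)),
        k,
        L,
    )
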