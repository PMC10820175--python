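"""Exhaustive k-mer (hexamer) enumeration and counting over promoter sets.

The enrichment analysis asks, for every one of the 4^6 = 4096 DNA hexamers,
how often it occurs in a set of 1-kb promoters.  Occurrences are counted in
overlapping windows (step 1) on the given strand only — promoter sequences
are already oriented 5'->3' relative to their gene.  Windows containing an
ambiguous base (N) are excluded from both the counts and the valid-window
denominator, so masked sequence cannot bias composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_BASES = "ACGT"

# byte -> 2-bit code; anything outside ACGT (incl. N) codes as -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class HexamerIndex:
    """All 4^k DNA k-mers in lexicographic order with their positions."""

    k: int
    motifs: tuple[str, ...]
    index_of: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.motifs)


def enumerate_hexamers(k: int = 6) -> HexamerIndex:
    """Enumerate all 4^k k-mers, AAAAAA ... TTTTTT for k = 6, lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    motifs = tuple("".join(p) for p in product(_BASES, repeat=k))
    return HexamerIndex(k=k, motifs=motifs, index_of={m: i for i, m in enumerate(motifs)})


@dataclass
class HexamerCountVector:
    """Occurrence counts of every k-mer over a promoter set.

    ``counts[i]`` is the number of N-free length-k windows equal to motif i
    (lexicographic index); ``n_valid_windows`` is the total number of N-free
    windows scanned, so ``counts.sum() == n_valid_windows`` always.
    """

    counts: np.ndarray
    n_promoters: int
    n_valid_windows: int
    k: int = 6

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(
                f"counts must have length 4^{self.k} = {4**self.k}, got {self.counts.shape}"
            )


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Lexicographic indices of all N-free length-k windows of seq."""
    codes = _encode(seq)
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid].astype(np.int64) @ powers


def count_hexamers(seq: str, k: int = 6) -> HexamerCountVector:
    """Count overlapping k-mer occurrences in one oriented promoter sequence.

    The sequence must already be normalized to the {A,C,G,T,N} alphabet
    (see :func:`promhex.promoter_io.normalize_seq`).  Sequences shorter than
    k yield an all-zero vector with ``n_valid_windows = 0``.
    """
    vals = _window_codes(seq, k)
    counts = np.bincount(vals, minlength=4**k)
    return HexamerCountVector(counts=counts, n_promoters=1, n_valid_windows=int(vals.size), k=k)


def _seq_of(p) -> str:
    return p if isinstance(p, str) else p.seq


def count_matrix(promoters: Sequence, k: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Per-promoter count matrix (n_promoters x 4^k) and valid-window counts.

    The row order follows the input order.  This is the workhorse behind
    both aggregation and the resampling null, which repeatedly sums subsets
    of rows.
    """
    promoters = list(promoters)
    n = len(promoters)
    mat = np.zeros((n, 4**k), dtype=np.int32)
    valid = np.zeros(n, dtype=np.int64)
    for i, p in enumerate(promoters):
        vals = _window_codes(_seq_of(p), k)
        mat[i] = np.bincount(vals, minlength=4**k)
        valid[i] = vals.size
    return mat, valid


def aggregate_counts(promoters: Iterable, k: int = 6) -> HexamerCountVector:
    """Sum per-promoter count vectors over a gene set (elementwise)."""
    promoters = list(promoters)
    if not promoters:
        raise ValueError("empty promoter set")
    mat, valid = count_matrix(promoters, k=k)
    return HexamerCountVector(
        counts=mat.sum(axis=0, dtype=np.int64),
        n_promoters=len(promoters),
        n_valid_windows=int(valid.sum()),
        k=k,
    )


def reverse_complement(motif: str) -> str:
    """Watson-Crick reverse complement of a concrete ACGT motif."""
    bad = set(motif) - set(_BASES)
    if bad:
        raise ValueError(f"non-ACGT character(s) in motif: {sorted(bad)}")
    return motif.translate(_COMPLEMENT)[::-1]
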