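"""Canonical multi-k k-mer frequency featurization.

Every classifier in this package consumes the same representation: for each
k in [k_min, k_max] (default 3..7) the sequence is scanned with a width-k
sliding window, each window is collapsed to its canonical form (the
lexicographically smaller of the k-mer and its reverse complement, with
A < C < G < T), and the counts of each k are normalized to frequencies.
The per-k blocks are concatenated, ordered by increasing k and
lexicographically within a block.  For k = 3..7 the total dimension is
10952.

Windows containing any non-ACGT character are skipped; a sequence shorter
than k, or containing no valid window of width k, yields an all-zero block
for that k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte value -> 2-bit code; 255 marks an ambiguous character
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Return the canonical form of a k-mer.

    The canonical form is the lexicographic minimum of the k-mer and its
    reverse complement (under A < C < G < T).  Raises ``ValueError`` on
    any character outside {A, C, G, T}; callers must pre-filter ambiguous
    windows.
    """
    if any(c not in _BASES for c in kmer):
        raise ValueError(f"k-mer contains non-ACGT character: {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def index_size(k_min: int, k_max: int) -> int:
    """Number of distinct canonical k-mers over k in [k_min, k_max].

    For a single k this is 4^k/2 when k is odd and (4^k + 4^{k/2})/2 when
    k is even (the extra term counts reverse-complement palindromes, which
    exist only for even k).  index_size(3, 7) == 10952.
    """
    if k_min < 1 or k_min > k_max:
        raise ValueError(f"invalid k range: ({k_min}, {k_max})")
    total = 0
    for k in range(k_min, k_max + 1):
        if k % 2 == 1:
            total += 4**k // 2
        else:
            total += (4**k + 4 ** (k // 2)) // 2
    return total


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of 2-bit-packed k-mer codes."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def _canonical_column_map(k: int) -> tuple[np.ndarray, int]:
    """Map every 2-bit-packed k-mer code to its canonical column rank.

    Columns are the canonical k-mers of width k in lexicographic order
    (identical to numeric order of their packed codes).  Returns the map
    (length 4^k) and the block size.
    """
    codes = np.arange(4**k, dtype=np.int64)
    rc = _revcomp_codes(codes, k)
    canon = np.minimum(codes, rc)
    canon_codes = np.unique(canon)
    col = np.searchsorted(canon_codes, canon)
    return col.astype(np.int64), len(canon_codes)


@dataclass
class KmerIndex:
    """Frozen layout of the canonical k-mer feature space.

    The layout (canonical = lexicographic min of strand pair; blocks by
    ascending k, lexicographic within block) is versioned through
    ``signature`` and serialized with trained models so that weights are
    only ever applied to the layout they were fitted on.
    """

    k_min: int = 3
    k_max: int = 7
    _col_maps: dict = field(default_factory=dict, repr=False, compare=False)
    _block_sizes: dict = field(default_factory=dict, repr=False, compare=False)

    LAYOUT_VERSION = 1

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_min > self.k_max:
            raise ValueError(f"invalid k range: ({self.k_min}, {self.k_max})")
        offset = 0
        self.block_offsets: dict[int, int] = {}
        for k in range(self.k_min, self.k_max + 1):
            col_map, size = _canonical_column_map(k)
            self._col_maps[k] = col_map
            self._block_sizes[k] = size
            self.block_offsets[k] = offset
            offset += size
        self.D = offset

    @property
    def signature(self) -> str:
        return f"canonical-lex/v{self.LAYOUT_VERSION}/k{self.k_min}-{self.k_max}"

    def block_size(self, k: int) -> int:
        return self._block_sizes[k]

    def position(self, kmer: str) -> int:
        """Feature-vector position of a k-mer (canonicalized first)."""
        k = len(kmer)
        if not self.k_min <= k <= self.k_max:
            raise ValueError(f"k-mer length {k} outside range [{self.k_min}, {self.k_max}]")
        code = 0
        for c in canonical(kmer):
            code = (code << 2) | _BASES.index(c)
        return self.block_offsets[k] + int(self._col_maps[k][code])


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def featurize(seq: str, index: KmerIndex | None = None) -> np.ndarray:
    """Canonical k-mer frequency vector of a sequence.

    For each k, every valid width-k window (no ambiguous characters)
    increments the count of its canonical k-mer; each k-block is then
    normalized by that k's total valid-window count, so each block sums
    to 1 whenever the sequence contains at least one valid window of that
    width and is all-zero otherwise.
    """
    if index is None:
        index = KmerIndex()
    if hasattr(seq, "sequence"):
        seq = seq.sequence
    if len(seq) == 0:
        raise ValueError("cannot featurize an empty sequence")
    enc = _encode(seq.upper()).astype(np.int64)
    valid_base = enc != 255
    out = np.zeros(index.D, dtype=np.float64)
    n = len(enc)
    for k in range(index.k_min, index.k_max + 1):
        n_win = n - k + 1
        if n_win <= 0:
            continue
        codes = np.zeros(n_win, dtype=np.int64)
        valid = np.ones(n_win, dtype=bool)
        for j in range(k):
            codes = (codes << 2) | (enc[j : j + n_win] & 3)
            valid &= valid_base[j : j + n_win]
        good = codes[valid]
        if good.size == 0:
            continue
        cols = index._col_maps[k][good]
        counts = np.bincount(cols, minlength=index.block_size(k)).astype(np.float64)
        off = index.block_offsets[k]
        out[off : off + index.block_size(k)] = counts / good.size
    return out


def featurize_batch(
    seqs: Sequence,
    index: KmerIndex | None = None,
    workers: int = 1,
) -> np.ndarray:
    """Featurize many sequences, preserving input order.

    Results are identical for any number of workers; parallelism only
    distributes independent per-sequence counting.
    Returns a ``(len(seqs), D)`` array.
    """
    if index is None:
        index = KmerIndex()
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if len(seqs) == 0:
        return np.zeros((0, index.D), dtype=np.float64)
    if workers == 1 or len(seqs) < 4:
        rows = [featurize(s, index) for s in seqs]
    else:
        rows = Parallel(n_jobs=workers, prefer="threads")(
            delayed(featurize)(s, index) for s in seqs
        )
    return np.vstack(rows)
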