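"""Probabilistic and exact k-mer set membership.

A Bloom filter answers "have I seen this k-mer?" with no false negatives
and a tunable false-positive rate (FPR) that depends on the bit-array
size, the number of hash functions and the number of insertions.  A
cascading Bloom filter stacks several of them: each occurrence of a k-mer
advances it one level, so the last level holds only k-mers observed at
least L times ("solid" k-mers), which discards most k-mers created by
sequencing errors.

Hashing is double hashing over two 64-bit halves of a blake2b digest of
the canonical k-mer string: probe i lands at (h1 + i*h2) mod m.  The
scheme is deterministic across runs and platforms.

``ExactKmerSet`` implements the same insert/solid contract with exact
counts; it serves as an oracle in tests and as a backend for small
inputs.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from typing import BinaryIO, Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")
_VALID = frozenset("ACGT")

MAGIC = b"EXOGRAPH_FILTER"
FORMAT_VERSION = 1
HASH_SCHEME = "blake2b-128/double"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def canonical_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    """Yield (position, canonical k-mer) for every valid window of ``seq``.

    Windows containing characters outside {A,C,G,T} (case-insensitive) are
    skipped; positions of the remaining windows are preserved.  A sequence
    shorter than k yields nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return
    # next_bad[p] = smallest index >= p holding a non-ACGT character
    bad = [i for i, c in enumerate(seq) if c not in _VALID]
    if not bad:
        for p in range(n - k + 1):
            yield p, canonical(seq[p : p + k])
        return
    bad_arr = np.asarray(bad)
    for p in range(n - k + 1):
        # window [p, p+k) is clean iff no bad index falls inside it
        j = np.searchsorted(bad_arr, p)
        if j < len(bad_arr) and bad_arr[j] < p + k:
            continue
        yield p, canonical(seq[p : p + k])


def _hash_pair(kmer: str) -> tuple[int, int]:
    digest = hashlib.blake2b(kmer.encode("ascii"), digest_size=16).digest()
    return struct.unpack("<QQ", digest)


@dataclass
class BloomFilter:
    """Fixed-size bit array answering approximate k-mer membership.

    Parameters
    ----------
    k : k-mer length in bases.
    m : number of bits in the array.
    h : number of hash functions (probes per k-mer); four by default.
    """

    k: int
    m: int
    h: int = 4
    bits: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    n_inserted: int = 0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"m must be > 0, got {self.m}")
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.bits is None:
            self.bits = np.zeros((self.m + 7) // 8, dtype=np.uint8)

    def _positions(self, kmer: str) -> list[int]:
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer length {len(kmer)} does not match filter k={self.k}"
            )
        h1, h2 = _hash_pair(kmer)
        h2 = h2 | 1  # odd step avoids degenerate probing cycles
        return [(h1 + i * h2) % self.m for i in range(self.h)]

    def insert(self, kmer: str) -> None:
        for pos in self._positions(kmer):
            self.bits[pos >> 3] |= 1 << (pos & 7)
        self.n_inserted += 1

    def contains(self, kmer: str) -> bool:
        bits = self.bits
        for pos in self._positions(kmer):
            if not bits[pos >> 3] & (1 << (pos & 7)):
                return False
        return True

    __contains__ = contains

    def fpr(self) -> float:
        """Analytic false-positive rate (1 - e^{-hn/m})^h.

        ``n_inserted`` counts insert calls, a proxy for cardinality; the
        estimate is conservative when duplicates are inserted.
        """
        if self.n_inserted == 0:
            return 0.0
        return float(
            (1.0 - np.exp(-self.h * self.n_inserted / self.m)) ** self.h
        )

    def occupancy(self) -> float:
        """Fraction of bits set (over the logical m bits)."""
        set_bits = int(np.unpackbits(self.bits, count=self.m).sum())
        return set_bits / self.m


# module-level aliases matching the operation names used in the docs
def bf_insert(f: BloomFilter, kmer: str) -> BloomFilter:
    f.insert(kmer)
    return f


def bf_contains(f: BloomFilter, kmer: str) -> bool:
    return f.contains(kmer)


def bf_fpr(f: BloomFilter) -> float:
    return f.fpr()


@dataclass
class CascadingBloomFilter:
    """Stack of Bloom filters whose last level holds solid k-mers.

    Inserting a k-mer places it into the first level that does not already
    contain it, so presence at level i implies at least i+1 observations
    (up to Bloom false positives).  Solidity is membership in the last
    level; with L levels a k-mer must be seen >= L times to become solid.
    """

    k: int
    m_per_level: int
    levels: int = 2
    h: int = 4
    filters: list[BloomFilter] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.filters is None:
            self.filters = [
                BloomFilter(k=self.k, m=self.m_per_level, h=self.h)
                for _ in range(self.levels)
            ]

    def insert(self, kmer: str) -> None:
        for f in self.filters:
            if not f.contains(kmer):
                f.insert(kmer)
                return
        # present everywhere already: no change

    def is_solid(self, kmer: str) -> bool:
        return self.filters[-1].contains(kmer)

    def level_fprs(self) -> list[float]:
        return [f.fpr() for f in self.filters]

    def analysis_fpr(self) -> float:
        """FPR of the last level, the one used for exon prediction."""
        return self.filters[-1].fpr()

    def save(self, fh: BinaryIO) -> None:
        header = struct.pack(
            "<HIIIQ",
            FORMAT_VERSION,
            self.k,
            self.h,
            self.levels,
            self.m_per_level,
        )
        fh.write(MAGIC)
        fh.write(header)
        scheme = HASH_SCHEME.encode("ascii")
        fh.write(struct.pack("<H", len(scheme)))
        fh.write(scheme)
        for f in self.filters:
            fh.write(struct.pack("<Q", f.n_inserted))
            fh.write(f.bits.tobytes())

    @classmethod
    def load(cls, fh: BinaryIO) -> "CascadingBloomFilter":
        magic = fh.read(len(MAGIC))
        if magic != MAGIC:
            raise ValueError("not an exograph filter file (bad magic)")
        version, k, h, levels, m = struct.unpack("<HIIIQ", fh.read(22))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported filter format version {version}")
        (scheme_len,) = struct.unpack("<H", fh.read(2))
        scheme = fh.read(scheme_len).decode("ascii")
        if scheme != HASH_SCHEME:
            raise ValueError(f"unsupported hash scheme {scheme!r}")
        cbf = cls(k=k, m_per_level=m, levels=levels, h=h)
        nbytes = (m + 7) // 8
        for f in cbf.filters:
            (f.n_inserted,) = struct.unpack("<Q", fh.read(8))
            f.bits = np.frombuffer(fh.read(nbytes), dtype=np.uint8).copy()
        return cbf


def cbf_insert(c: CascadingBloomFilter, kmer: str) -> CascadingBloomFilter:
    c.insert(kmer)
    return c


def cbf_solid(c: CascadingBloomFilter, kmer: str) -> bool:
    return c.is_solid(kmer)


class ExactKmerSet:
    """Exact-count backend implementing the cascade insert/solid contract.

    Counts every insert; a k-mer is solid once its count reaches ``levels``.
    Used as the test oracle for the Bloom cascade and as the exact backend
    for small inputs.
    """

    def __init__(self, k: int, levels: int = 2):
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if levels < 1:
            raise ValueError(f"levels must be >= 1, got {levels}")
        self.k = k
        self.levels = levels
        self.counts: dict[str, int] = {}

    def insert(self, kmer: str) -> None:
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer length {len(kmer)} does not match set k={self.k}"
            )
        self.counts[kmer] = self.counts.get(kmer, 0) + 1

    def is_solid(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer length {len(kmer)} does not match set k={self.k}"
            )
        return self.counts.get(kmer, 0) >= self.levels

    def contains(self, kmer: str) -> bool:
        return kmer in self.counts

    def analysis_fpr(self) -> float:
        return 0.0
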