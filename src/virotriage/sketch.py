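"""MinHash sketching and Mash-style distances.

A sketch is the ``size`` smallest distinct 64-bit hash values over the
canonical k-mers of a sequence (k = 21, size = 10,000 by default). Two
sketches support a bottom-sketch Jaccard estimate, and the Jaccard estimate
converts to a mutation-rate-like distance via the usual Poisson transform
d = -(1/k) * ln(2j / (1 + j)).

Hashing is a fixed splitmix64 finalizer over the 2-bit packed k-mer, so
sketches are bit-stable across runs and platforms. k-mers containing
characters outside {A,C,G,T} are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Contig

__all__ = [
    "Sketch",
    "make_sketch",
    "jaccard_estimate",
    "sketch_distance",
    "canonical_kmer_hashes",
]

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _v in zip(b"ACGT", (0, 1, 2, 3)):
    _BASE_CODE[_b] = _v

_U64 = np.uint64


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer; a fixed, well-mixed 64-bit hash."""
    x = (x + _U64(0x9E3779B97F4A7C15)).astype(_U64)
    x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
    return x ^ (x >> _U64(31))


def canonical_kmer_hashes(sequence: str, k: int) -> np.ndarray:
    """Hash every valid canonical k-mer of ``sequence``; unsorted, with repeats.

    Canonical = the numerically smaller of the 2-bit packings of the k-mer
    and its reverse complement (equivalent to a fixed total order on
    strands). Requires k <= 31 so the packing fits in 62 bits.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k-mer size above 31 is not supported by the packed hasher")
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=_U64)
    valid = codes != 255
    c64 = codes.astype(_U64)
    rc64 = (_U64(3) - c64) % _U64(4)  # complement; junk where invalid
    # 2-bit pack every window of the forward strand and of the reverse
    # complement (reverse complement of window i uses the same positions in
    # reversed order, so its place values simply run the other way)
    place_f = (_U64(4) ** np.arange(k - 1, -1, -1, dtype=_U64)).astype(_U64)
    place_r = (_U64(4) ** np.arange(k, dtype=_U64)).astype(_U64)
    win_f = np.lib.stride_tricks.sliding_window_view(c64, k)
    win_r = np.lib.stride_tricks.sliding_window_view(rc64, k)
    windows_f = (win_f * place_f).sum(axis=1, dtype=_U64)
    windows_r = (win_r * place_r).sum(axis=1, dtype=_U64)
    # window is valid iff all k bases are valid
    ok = np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    canon = np.minimum(windows_f[ok], windows_r[ok])
    return _splitmix64(canon)


@dataclass(frozen=True)
class Sketch:
    """A bottom MinHash sketch: the smallest distinct k-mer hashes."""

    k: int
    size: int
    hashes: tuple[int, ...]
    seq_id: str = ""

    def __post_init__(self) -> None:
        h = self.hashes
        if any(h[i] >= h[i + 1] for i in range(len(h) - 1)):
            raise ValueError("sketch hashes must be strictly increasing")
        if len(h) > self.size:
            raise ValueError("sketch holds more hashes than its size")


def make_sketch(contig: Contig, k: int = 21, size: int = 10000) -> Sketch:
    """Sketch a contig: keep the ``size`` smallest distinct canonical-k-mer hashes."""
    hashes = canonical_kmer_hashes(contig.sequence, k)
    distinct = np.unique(hashes)  # sorted
    kept = distinct[:size]
    return Sketch(k=k, size=size, hashes=tuple(int(h) for h in kept), seq_id=contig.id)


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Bottom-sketch Jaccard: |A ∩ B ∩ bottom_s(A ∪ B)| / |bottom_s(A ∪ B)|."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if a.size != b.size:
        raise ValueError(f"sketch size mismatch: {a.size} vs {b.size}")
    ha = np.asarray(a.hashes, dtype=_U64)
    hb = np.asarray(b.hashes, dtype=_U64)
    union = np.union1d(ha, hb)[: a.size]
    if union.size == 0:
        return 0.0
    shared = np.intersect1d(ha, hb, assume_unique=True)
    n_shared = np.isin(shared, union, assume_unique=True).sum()
    return float(n_shared) / float(union.size)


def sketch_distance(j: float, k: int) -> float:
    """Mash-style distance from a Jaccard estimate.

    d = -(1/k) ln(2j / (1+j)), capped at 1; j = 0 maps to 1 (the transform
    diverges there) and j = 1 maps to 0.
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"jaccard {j} outside [0, 1]")
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    return min(1.0, -(1.0 / k) * math.log(2.0 * j / (1.0 + j)))
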