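"""Bisulfite-aware, Hamming-aware de Bruijn hash over DNA patterns.

The fingerprint of a length-``m`` pattern is computed by collapsing the
pattern to a bit-string (C/T -> 0, G/A -> 1, position 0 at the most
significant bit), splitting it into ``w``-bit blocks -- all leading blocks
non-overlapping, the final block anchored at the pattern's end and possibly
overlapping its predecessor -- and XOR-ing the blocks together.

Three properties follow from this construction and are exercised by the
test suite:

* de Bruijn: overlapping patterns yield overlapping fingerprints, so the
  hash of a whole text is well defined by concatenation;
* bisulfite invariance: C->T and G->A substitutions do not change the
  fingerprint;
* Hamming awareness: patterns within Hamming distance ``k`` map to
  fingerprints within XOR-distance ``2k``, so candidate lookups only need
  to enumerate the radius-``2k`` Hamming ball around the query fingerprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import List

import numpy as np

from ._seq import ALPHA_OF_CODE, encode


@dataclass(frozen=True)
class Fingerprint:
    """A ``width``-bit hash value."""

    value: int
    width: int

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("fingerprint width must be >= 1")
        if not 0 <= self.value < (1 << self.width):
            raise ValueError(
                f"fingerprint value {self.value} does not fit in {self.width} bits"
            )

    def bits(self) -> str:
        return format(self.value, f"0{self.width}b")


@dataclass(frozen=True)
class HashParams:
    """Seed length ``m`` (bases) and fingerprint width ``w`` (bits)."""

    m: int
    w: int

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("fingerprint width must be >= 1")
        if self.w > self.m:
            raise ValueError(f"width w={self.w} must not exceed seed length m={self.m}")


def default_width(n: int) -> int:
    """Default fingerprint width for a text of length ``n``.

    Keeps the fingerprint space a generous multiple of the number of
    indexed positions, so that spurious bucket hits stay rare even when a
    whole Hamming ball of fingerprints is probed per query, while the
    bucket table stays desk-scale.
    """
    if n < 2:
        return 12
    return min(32, max(12, math.ceil(math.log2(n)) + 4))


def encode_alpha(seq: str) -> str:
    """Collapse a DNA string to its C/T=0, G/A=1 bit-string (MSB = pos 0)."""
    codes = encode(seq)
    return "".join(map(str, ALPHA_OF_CODE[codes].tolist()))


def alpha_value(seq: str) -> int:
    """``encode_alpha`` interpreted as an integer (empty string -> 0)."""
    bits = encode_alpha(seq)
    return int(bits, 2) if bits else 0


def fingerprint(P: str, params: HashParams) -> Fingerprint:
    """Hash a length-``m`` pattern to a ``w``-bit fingerprint."""
    m, w = params.m, params.w
    if len(P) != m:
        raise ValueError(f"pattern length {len(P)} != m={m}")
    a = alpha_value(P)
    mask = (1 << w) - 1
    nblocks = -(-m // w)  # ceil
    v = 0
    for i in range(nblocks - 1):  # leading non-overlapping blocks
        v ^= (a >> (m - (i + 1) * w)) & mask
    v ^= a & mask  # final block, anchored at offset m - w
    return Fingerprint(v, w)


def window_fingerprints(codes: np.ndarray, params: HashParams) -> np.ndarray:
    """Fingerprints of every length-``m`` window of an encoded text.

    Vectorised equivalent of calling :func:`fingerprint` on each window;
    returns a uint64 array of length ``n - m + 1``.
    """
    m, w = params.m, params.w
    n = len(codes)
    if n < m:
        raise ValueError(f"text length {n} < m={m}")
    bits = ALPHA_OF_CODE[codes]
    # W[i] = integer value of the w alpha-bits starting at position i
    nw = n - w + 1
    W = np.zeros(nw, dtype=np.uint64)
    for j in range(w):
        W = (W << np.uint64(1)) | bits[j : j + nw].astype(np.uint64)
    L = n - m + 1
    fp = np.zeros(L, dtype=np.uint64)
    nblocks = -(-m // w)
    for i in range(nblocks - 1):
        fp ^= W[i * w : i * w + L]
    fp ^= W[m - w : m - w + L]
    return fp


def global_hash(T: str, params: HashParams) -> str:
    """Hash of a whole text: the unique bit-string of length ``n - m + w``
    whose every ``w``-bit window equals the fingerprint of the corresponding
    length-``m`` text window."""
    fps = window_fingerprints(encode(T), params)
    w = params.w
    head = format(int(fps[0]), f"0{w}b")
    tail = "".join(str(int(v) & 1) for v in fps[1:])
    return head + tail


@lru_cache(maxsize=32)
def ball_deltas(w: int, radius: int) -> np.ndarray:
    """XOR-deltas of the radius-``radius`` Hamming ball over ``w``-bit words.

    Enumeration order is fixed: by flip count, then lexicographically by
    flipped bit positions counted from the most significant bit.
    """
    if radius < 0 or radius > w:
        raise ValueError(f"radius {radius} outside [0, {w}]")
    deltas: List[int] = []
    for count in range(radius + 1):
        for positions in combinations(range(w), count):
            d = 0
            for p in positions:  # p = 0 is the MSB
                d |= 1 << (w - 1 - p)
            deltas.append(d)
    return np.array(deltas, dtype=np.uint64)


def hamming_ball(center: Fingerprint, radius: int) -> List[Fingerprint]:
    """All fingerprints within XOR-popcount ``radius`` of ``center``,
    in the deterministic order of :func:`ball_deltas`."""
    w = center.width
    deltas = ball_deltas(w, radius)
    c = np.uint64(center.value)
    return [Fingerprint(int(c ^ d), w) for d in deltas]
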