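"""Base-level sequence utilities shared across the package.

DNA bases are encoded as uint8 codes A=0, C=1, G=2, T=3 so that the
complement of a code is simply ``3 - code``.
"""

from __future__ import annotations

import gzip
from typing import IO, Iterator

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3

_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_OF[ord(_b)] = _i
    _CODE_OF[ord(_b.lower())] = _i

_BASE_OF = np.frombuffer(BASES.encode(), dtype=np.uint8)

# bisulfite-aware bit encoding: C and T collapse to 0, G and A to 1
ALPHA_OF_CODE = np.array([1, 0, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes; rejects non-ACGT characters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_OF[raw]
    if codes.size and codes.max() > 3:
        bad = chr(int(raw[int(np.argmax(codes > 3))]))
        raise ValueError(f"invalid DNA character {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASE_OF[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def open_text(path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip-compressed text transparently (by suffix)."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a FASTQ file (.gz supported)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq, qual
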