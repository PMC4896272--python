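"""Reference preprocessing and the fingerprint->positions index.

The reference is held as one concatenated text (contig end markers and
ambiguous bases are randomised away with a recorded seed); the index maps
every window fingerprint to the ascending list of text positions carrying
it.  Lookup structures are flat sorted arrays queried with binary search,
which keeps bucket contents position-sorted and serialisation trivial.
"""

from __future__ import annotations

import io
import json
import struct
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from . import _seq
from .bshash import Fingerprint, HashParams, window_fingerprints

_MAGIC = b"BKIX"
_VERSION = 1


class FormatError(ValueError):
    """Raised when an index container file is corrupt or unsupported."""


@dataclass
class EncodedReference:
    """Concatenated, randomised genome text plus the contig coordinate map."""

    codes: np.ndarray  # uint8 codes over {A,C,G,T}
    contigs: List[Tuple[str, int, int]]  # (name, start, length), ordered
    rng_seed: int

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def text(self) -> str:
        return _seq.decode(self.codes)

    def contig_starts(self) -> np.ndarray:
        return np.array([s for _, s, _ in self.contigs], dtype=np.int64)

    def contig_of(self, pos: int) -> Tuple[str, int, int]:
        """(name, start, length) of the contig containing text position pos."""
        starts = self.contig_starts()
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= self.contigs[i][1] + self.contigs[i][2]:
            raise IndexError(f"position {pos} outside reference")
        return self.contigs[i]


def preprocess_reference(fasta_source, rng_seed: int = 0) -> EncodedReference:
    """Load a FASTA file, concatenate contigs in file order, and randomise
    every non-ACGT character (N, end markers, IUPAC codes) to a uniform base
    drawn with the recorded seed."""
    if isinstance(fasta_source, (str, bytes)) or hasattr(fasta_source, "__fspath__"):
        handle = _seq.open_text(fasta_source)
        close = True
    else:
        handle, close = fasta_source, False
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError("no FASTA records found")

    rng = np.random.default_rng(rng_seed)
    pieces = []
    contigs: List[Tuple[str, int, int]] = []
    offset = 0
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty contig {rec.id!r}")
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = _seq._CODE_OF[raw]
        bad = codes > 3
        if bad.any():
            codes = codes.copy()
            codes[bad] = rng.integers(0, 4, size=int(bad.sum()), dtype=np.uint8)
        pieces.append(codes)
        contigs.append((rec.id, offset, len(codes)))
        offset += len(codes)
    return EncodedReference(np.concatenate(pieces), contigs, rng_seed)


@dataclass
class DBHashIndex:
    """Succinct-style index: the text plus a table over its window hash."""

    params: HashParams
    reference: EncodedReference
    # positions sorted by (fingerprint, position); queried by binary search
    sorted_fps: np.ndarray = field(repr=False)  # uint64
    sorted_pos: np.ndarray = field(repr=False)  # int64, ascending per bucket
    _bucket_starts: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n_positions(self) -> int:
        return len(self.sorted_fps)

    def bucket_starts(self) -> np.ndarray:
        """Direct bucket-extent table: ``starts[f] .. starts[f+1]`` is the
        slice of ``sorted_pos`` holding fingerprint ``f``.  Built lazily
        (2^w + 1 uint32 entries); only offered for w <= 26."""
        if self._bucket_starts is None:
            w = self.params.w
            if w > 26:
                raise ValueError("direct bucket table too large for w > 26")
            counts = np.bincount(
                self.sorted_fps.astype(np.int64), minlength=(1 << w)
            )
            starts = np.zeros((1 << w) + 1, dtype=np.uint32)
            np.cumsum(counts, dtype=np.uint32, out=starts[1:])
            self._bucket_starts = starts
        return self._bucket_starts

    def buckets(self) -> dict:
        """Materialise the fingerprint -> positions mapping (small indexes
        only; the flat arrays are the canonical representation)."""
        out: dict = {}
        for fp, pos in zip(self.sorted_fps.tolist(), self.sorted_pos.tolist()):
            out.setdefault(fp, []).append(pos)
        return out


def build_index(ref: EncodedReference, params: HashParams) -> DBHashIndex:
    """Index every length-``m`` window of the reference by its fingerprint."""
    fps = window_fingerprints(ref.codes, params)
    order = np.argsort(fps, kind="stable")
    return DBHashIndex(
        params=params,
        reference=ref,
        sorted_fps=fps[order],
        sorted_pos=order.astype(np.int64),
    )


def lookup(index: DBHashIndex, g: Fingerprint) -> np.ndarray:
    """Ascending text positions whose window fingerprint equals ``g``."""
    if g.width != index.params.w:
        raise ValueError(f"fingerprint width {g.width} != index width {index.params.w}")
    v = np.uint64(g.value)
    lo = int(np.searchsorted(index.sorted_fps, v, side="left"))
    hi = int(np.searchsorted(index.sorted_fps, v, side="right"))
    return index.sorted_pos[lo:hi]


def lookup_many(index: DBHashIndex, fps: np.ndarray) -> np.ndarray:
    """Union of bucket contents for an array of uint64 fingerprints."""
    lo = np.searchsorted(index.sorted_fps, fps, side="left")
    hi = np.searchsorted(index.sorted_fps, fps, side="right")
    nz = np.flatnonzero(hi > lo)
    if nz.size == 0:
        return np.empty(0, dtype=np.int64)
    chunks = [index.sorted_pos[lo[i] : hi[i]] for i in nz.tolist()]
    return np.concatenate(chunks)


def _write_chunk(fh, payload: bytes) -> None:
    fh.write(struct.pack("<Q", len(payload)))
    fh.write(payload)


def _read_chunk(fh) -> bytes:
    head = fh.read(8)
    if len(head) != 8:
        raise FormatError("truncated index file")
    (size,) = struct.unpack("<Q", head)
    payload = fh.read(size)
    if len(payload) != size:
        raise FormatError("truncated index file")
    return payload


def save_index(index: DBHashIndex, path) -> None:
    """Write a small versioned binary container; round-trips bit-exactly."""
    header = {
        "m": index.params.m,
        "w": index.params.w,
        "rng_seed": index.reference.rng_seed,
        "n": index.reference.n,
        "contigs": [list(c) for c in index.reference.contigs],
    }
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<H", _VERSION))
        _write_chunk(fh, json.dumps(header).encode())
        _write_chunk(fh, index.reference.codes.tobytes())
        _write_chunk(fh, index.sorted_fps.tobytes())
        _write_chunk(fh, index.sorted_pos.tobytes())


def load_index(path) -> DBHashIndex:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise FormatError(f"bad magic {magic!r}")
        ver_raw = fh.read(2)
        if len(ver_raw) != 2:
            raise FormatError("truncated index file")
        (version,) = struct.unpack("<H", ver_raw)
        if version != _VERSION:
            raise FormatError(f"unsupported index version {version}")
        header = json.loads(_read_chunk(fh).decode())
        codes = np.frombuffer(_read_chunk(fh), dtype=np.uint8)
        fps = np.frombuffer(_read_chunk(fh), dtype=np.uint64)
        pos = np.frombuffer(_read_chunk(fh), dtype=np.int64)
    if len(codes) != header["n"]:
        raise FormatError("reference length mismatch")
    ref = EncodedReference(
        codes=codes.copy(),
        contigs=[tuple(c) for c in header["contigs"]],
        rng_seed=header["rng_seed"],
    )
    return DBHashIndex(
        params=HashParams(header["m"], header["w"]),
        reference=ref,
        sorted_fps=fps.copy(),
        sorted_pos=pos.copy(),
    )
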