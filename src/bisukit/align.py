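"""Seed-and-extend alignment of directional bisulfite reads.

A read is searched in two conversion modes: as-is against the forward
reference allowing C->T (genome->read) mismatches for free (``fwd-CT``),
and as its reverse complement allowing G->A for free (``rev-GA``).  For
each mode the first ``m`` bases of the searched sequence form the seed;
candidate placements are the union of index buckets over the radius-``2k``
Hamming ball around the seed fingerprint, which by construction cannot
miss any placement with at most ``k`` seed mismatches.  Candidates are
verified ungapped over the full read length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple, Union

import numpy as np
import pysam

from . import _seq
from ._seq import A, C, G, T
from .bshash import ball_deltas, window_fingerprints
from .index import DBHashIndex

# A placement is labelled by orientation (fwd/rev: whether the sequence
# matching the forward reference is the read or its reverse complement)
# and by the conversion rule used during verification (CT: genome C may
# read T; GA: genome G may read A).  Read 1 of a directional library can
# only produce fwd-CT or rev-GA placements; read 2 observes the
# complement of a converted strand and produces rev-CT or fwd-GA.
MODE_CT = "fwd-CT"
MODE_GA = "rev-GA"
MODE_RC = "rev-CT"
MODE_FG = "fwd-GA"

_RULE_OF_MODE = {MODE_CT: "CT", MODE_GA: "GA", MODE_RC: "CT", MODE_FG: "GA"}


def mode_is_reverse(mode: str) -> bool:
    return mode.startswith("rev")


def mode_rule(mode: str) -> str:
    return _RULE_OF_MODE[mode]

STATUS_UNIQUE = "unique"
STATUS_MULTIPLE = "multiple"
STATUS_UNMAPPED = "unmapped"


@dataclass(frozen=True)
class AlignParams:
    """Alignment knobs; defaults follow the tool's stock configuration
    (30 bp seed, 2 seed errors, 5 % full-read mismatch budget)."""

    seed_errors: int = 2
    seed_length: int = 30
    max_mismatches: Union[int, float] = 0.05
    insert_min: int = 0
    insert_max: int = 1000

    def __post_init__(self) -> None:
        if self.seed_errors < 0:
            raise ValueError("seed_errors must be >= 0")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min > insert_max")

    def mismatch_budget(self, read_length: int) -> int:
        if isinstance(self.max_mismatches, float):
            return math.ceil(self.max_mismatches * read_length)
        return int(self.max_mismatches)


@dataclass
class ReadAlignment:
    read_id: str
    contig: Optional[str]
    position: int  # 0-based, contig-relative, leftmost on forward strand
    mode: Optional[str]  # MODE_CT | MODE_GA | None when unmapped
    mismatches: int
    status: str
    length: int
    seq: str = ""
    qual: str = ""

    @property
    def is_mapped(self) -> bool:
        return self.status != STATUS_UNMAPPED


def bs_match(genome_base: str, read_base: str, mode: str) -> bool:
    """Bisulfite-aware base equivalence.

    Asymmetric by design: a genomic C may read as T (unmethylated,
    converted) but a genomic T never legitimately reads as C; mirrored
    for G/A on the reverse mode.
    """
    if mode not in _RULE_OF_MODE:
        raise ValueError(f"unknown mode {mode!r}")
    if genome_base == read_base:
        return True
    if mode_rule(mode) == "CT":
        return genome_base == "C" and read_base == "T"
    return genome_base == "G" and read_base == "A"


@dataclass
class _Placement:
    global_pos: int
    mode: str
    mismatches: int


class Aligner:
    """Reusable alignment engine bound to one index + parameter set."""

    def __init__(self, index: DBHashIndex, params: AlignParams = AlignParams()):
        if params.seed_length != index.params.m:
            raise ValueError(
                f"seed_length {params.seed_length} != index seed length {index.params.m}"
            )
        w = index.params.w
        if 2 * params.seed_errors > w:
            raise ValueError(
                f"ball radius 2k={2 * params.seed_errors} exceeds fingerprint width {w}"
            )
        self.index = index
        self.params = params
        self.m = index.params.m
        self.w = w
        self._deltas = ball_deltas(w, 2 * params.seed_errors)
        ref = index.reference
        self._codes = ref.codes
        self._starts = ref.contig_starts()
        self._ends = self._starts + np.array([l for _, _, l in ref.contigs])
        self._names = [name for name, _, _ in ref.contigs]
        self._pow2 = (
            np.uint64(1) << np.arange(w - 1, -1, -1, dtype=np.uint64)
        )
        self._ar_m = np.arange(self.m)
        self._bstarts = index.bucket_starts() if w <= 26 else None

    # -- internals ---------------------------------------------------------

    def _seed_fingerprint(self, qcodes: np.ndarray) -> np.uint64:
        bits = _seq.ALPHA_OF_CODE[qcodes[: self.m]].astype(np.uint64)
        m, w = self.m, self.w
        # XOR the ceil(m/w)-1 leading blocks with the end-anchored block
        val = np.uint64(0)
        nblocks = -(-m // w)
        for i in range(nblocks - 1):
            val ^= np.uint64(bits[i * w : (i + 1) * w] @ self._pow2)
        val ^= np.uint64(bits[m - w : m] @ self._pow2)
        return val

    def _candidate_positions(self, center: np.uint64) -> np.ndarray:
        """Ascending text positions in any bucket of the Hamming ball."""
        cand_fps = center ^ self._deltas
        index = self.index
        if self._bstarts is not None:
            cand = cand_fps.astype(np.int64)
            starts = self._bstarts[cand].astype(np.int64)
            ends = self._bstarts[cand + 1].astype(np.int64)
        else:
            starts = np.searchsorted(index.sorted_fps, cand_fps, side="left")
            ends = np.searchsorted(index.sorted_fps, cand_fps, side="right")
        counts = ends - starts
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64)
        nz = counts > 0
        s, c = starts[nz], counts[nz]
        # ragged gather of [s_i, s_i + c_i) ranges into sorted_pos
        offs = np.repeat(np.cumsum(c) - c, c)
        flat = np.repeat(s, c) + np.arange(total) - offs
        positions = index.sorted_pos[flat]
        positions.sort()  # each position lives in exactly one bucket
        return positions

    def _mode_placements(self, qcodes: np.ndarray, mode: str) -> List[_Placement]:
        """Verified placements of the (already oriented) query in one mode."""
        m, k = self.m, self.params.seed_errors
        L = len(qcodes)
        positions = self._candidate_positions(self._seed_fingerprint(qcodes))
        positions = positions[positions + L <= len(self._codes)]
        if positions.size == 0:
            return []
        # discard candidates whose read span crosses a contig boundary
        ci = np.searchsorted(self._starts, positions, side="right") - 1
        positions = positions[positions + L <= self._ends[ci]]
        if positions.size == 0:
            return []
        free_g, free_r = (C, T) if mode_rule(mode) == "CT" else (G, A)
        qseed = qcodes[:m]
        # vectorised seed check across all candidates
        gseed = self._codes[positions[:, None] + self._ar_m]
        mm = (gseed != qseed) & ~((gseed == free_g) & (qseed == free_r))
        positions = positions[mm.sum(axis=1) <= k]
        if positions.size == 0:
            return []
        budget = self.params.mismatch_budget(L)
        out: List[_Placement] = []
        for p in positions.tolist():
            gseq = self._codes[p : p + L]
            mm_mask = (gseq != qcodes) & ~((gseq == free_g) & (qcodes == free_r))
            total_mm = int(np.count_nonzero(mm_mask))
            if total_mm <= budget:
                out.append(_Placement(p, mode, total_mm))
        return out

    def _best_placements(
        self, seq: str, mate2: bool = False
    ) -> Tuple[List[_Placement], Optional[_Placement]]:
        qf = _seq.encode(seq)
        qr = _seq.revcomp_codes(qf)
        if mate2:
            modes = ((qf, MODE_FG), (qr, MODE_RC))
        else:
            modes = ((qf, MODE_CT), (qr, MODE_GA))
        placements = [
            p for q, mode in modes for p in self._mode_placements(q, mode)
        ]
        if not placements:
            return [], None
        best_mm = min(p.mismatches for p in placements)
        best = [p for p in placements if p.mismatches == best_mm]
        best.sort(key=lambda p: (p.global_pos, p.mode))
        return best, best[0]

    def _to_alignment(
        self, read_id: str, seq: str, qual: str, best: List[_Placement]
    ) -> ReadAlignment:
        if not best:
            return ReadAlignment(
                read_id, None, -1, None, -1, STATUS_UNMAPPED, len(seq), seq, qual
            )
        top = best[0]
        name, start, _ = self.index.reference.contig_of(top.global_pos)
        status = STATUS_UNIQUE if len(best) == 1 else STATUS_MULTIPLE
        return ReadAlignment(
            read_id,
            name,
            top.global_pos - start,
            top.mode,
            top.mismatches,
            status,
            len(seq),
            seq,
            qual,
        )

    # -- public API --------------------------------------------------------

    def placements(self, seq: str, mate2: bool = False) -> List[Tuple[int, str, int]]:
        """All verified placements of a read as (global_pos, mode, mismatches),
        sorted by (mismatches, position, mode)."""
        seq = seq.upper()
        if len(seq) < self.m:
            return []
        qf = _seq.encode(seq)
        qr = _seq.revcomp_codes(qf)
        modes = ((qf, MODE_FG), (qr, MODE_RC)) if mate2 else ((qf, MODE_CT), (qr, MODE_GA))
        out = [
            (p.global_pos, p.mode, p.mismatches)
            for q, mode in modes
            for p in self._mode_placements(q, mode)
        ]
        out.sort(key=lambda t: (t[2], t[0], t[1]))
        return out

    def align_read(
        self, read_id: str, seq: str, qual: str = "", mate2: bool = False
    ) -> ReadAlignment:
        seq = seq.upper()
        if len(seq) < self.m:
            return ReadAlignment(
                read_id, None, -1, None, -1, STATUS_UNMAPPED, len(seq), seq, qual
            )
        best, _ = self._best_placements(seq, mate2=mate2)
        return self._to_alignment(read_id, seq, qual, best)

    def align_pair(
        self,
        read1: Tuple[str, str, str],
        read2: Tuple[str, str, str],
    ) -> Tuple[ReadAlignment, ReadAlignment, bool]:
        """Align both mates independently, then assess FR-orientation
        properness; a multiple-status mate is re-anchored to the candidate
        consistent with its unique partner when exactly one such exists."""
        id1, seq1, q1 = read1
        id2, seq2, q2 = read2
        b1 = self._best_placements(seq1.upper())[0] if len(seq1) >= self.m else []
        b2 = (
            self._best_placements(seq2.upper(), mate2=True)[0]
            if len(seq2) >= self.m
            else []
        )

        if len(b1) == 1 and len(b2) > 1:
            b2 = self._rescue(b1[0], len(seq1), b2, len(seq2)) or b2
        elif len(b2) == 1 and len(b1) > 1:
            b1 = self._rescue(b2[0], len(seq2), b1, len(seq1)) or b1

        a1 = self._to_alignment(id1, seq1.upper(), q1, b1)
        a2 = self._to_alignment(id2, seq2.upper(), q2, b2)
        proper = self._is_proper(b1, b2, len(seq1), len(seq2))
        return a1, a2, proper

    def _rescue(
        self,
        anchor: _Placement,
        anchor_len: int,
        cands: List[_Placement],
        length: int,
    ) -> Optional[List[_Placement]]:
        consistent = [
            c
            for c in cands
            if self._pair_geometry_ok(anchor, c, anchor_len, length) is not None
        ]
        if len(consistent) == 1:
            return consistent
        return None

    def _pair_geometry_ok(
        self, p1: _Placement, p2: _Placement, len1: int, len2: int
    ) -> Optional[int]:
        """FR geometry: opposite orientations, forward mate leftmost,
        insert within bounds; returns the insert size or None."""
        r1, r2 = mode_is_reverse(p1.mode), mode_is_reverse(p2.mode)
        if r1 == r2:
            return None
        fwd, rev = (p1, p2) if not r1 else (p2, p1)
        rev_len = len2 if not r1 else len1
        if fwd.global_pos > rev.global_pos:
            return None
        insert = rev.global_pos + rev_len - fwd.global_pos
        if not (self.params.insert_min <= insert <= self.params.insert_max):
            return None
        return insert

    def _is_proper(
        self,
        b1: List[_Placement],
        b2: List[_Placement],
        len1: int,
        len2: int,
    ) -> bool:
        if len(b1) != 1 or len(b2) != 1:
            return False
        return self._pair_geometry_ok(b1[0], b2[0], len1, len2) is not None


def align_read(
    index: DBHashIndex, read: Tuple[str, str, str], params: AlignParams = None
) -> ReadAlignment:
    """One-shot wrapper around :class:`Aligner` (read = (id, seq, qual))."""
    params = params or AlignParams(seed_length=index.params.m)
    return Aligner(index, params).align_read(*read)


def align_pair(
    index: DBHashIndex,
    read1: Tuple[str, str, str],
    read2: Tuple[str, str, str],
    params: AlignParams = None,
) -> Tuple[ReadAlignment, ReadAlignment, bool]:
    params = params or AlignParams(seed_length=index.params.m)
    a1, a2, _proper = Aligner(index, params).align_pair(read1, read2)
    return a1, a2, _proper


def _sam_header(ref) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, _, length in ref.contigs],
        }
    )


def _segment(
    aln: ReadAlignment,
    header: pysam.AlignmentHeader,
    *,
    paired: bool = False,
    first: bool = True,
    proper: bool = False,
    mate: Optional[ReadAlignment] = None,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = aln.read_id
    flag = 0
    if paired:
        flag |= 0x1 | (0x40 if first else 0x80)
        if proper:
            flag |= 0x2
    if aln.is_mapped:
        reverse = mode_is_reverse(aln.mode)
        if reverse:
            flag |= 0x10
            seg.query_sequence = _seq.revcomp(aln.seq)
            seg.query_qualities = pysam.qualitystring_to_array(aln.qual[::-1] or "")
        else:
            seg.query_sequence = aln.seq
            seg.query_qualities = pysam.qualitystring_to_array(aln.qual or "")
        seg.reference_id = header.get_tid(aln.contig)
        seg.reference_start = aln.position
        seg.cigarstring = f"{aln.length}M"
        seg.mapping_quality = 40 if aln.status == STATUS_UNIQUE else 1
        seg.set_tag("NM", aln.mismatches)
        seg.set_tag("XB", mode_rule(aln.mode))
        seg.set_tag("XT", "U" if aln.status == STATUS_UNIQUE else "R", value_type="A")
    else:
        flag |= 0x4
        seg.query_sequence = aln.seq
        seg.query_qualities = pysam.qualitystring_to_array(aln.qual or "")
        seg.reference_id = -1
        seg.reference_start = -1
        seg.mapping_quality = 0
    if paired and mate is not None:
        if mate.is_mapped:
            if mode_is_reverse(mate.mode):
                flag |= 0x20
            seg.next_reference_id = header.get_tid(mate.contig)
            seg.next_reference_start = mate.position
        else:
            flag |= 0x8
            seg.next_reference_id = -1
            seg.next_reference_start = -1
    seg.flag = flag
    return seg


def write_sam(
    alignments: Iterable,
    ref,
    path,
) -> None:
    """Write alignments as text SAM.

    ``alignments`` yields either single :class:`ReadAlignment` objects or
    ``(aln1, aln2, proper)`` mate triples.  Coordinates are converted to
    SAM's 1-based convention by pysam; reverse-mode reads are stored
    reverse-complemented with the reverse FLAG set, so SEQ always matches
    the forward reference.
    """
    header = _sam_header(ref)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for item in alignments:
            if isinstance(item, ReadAlignment):
                out.write(_segment(item, header))
            else:
                a1, a2, proper = item
                out.write(
                    _segment(a1, header, paired=True, first=True, proper=proper, mate=a2)
                )
                out.write(
                    _segment(a2, header, paired=True, first=False, proper=proper, mate=a1)
                )
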