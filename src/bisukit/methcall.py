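"""Memory-compressed methylation calling from ungapped alignments.

Counting runs in *rank space*: a rank-supported bit-vector marks every C
and G of the reference, and two blocked counter arrays (one for primary
evidence C/G, one for converted evidence T/A) store per-cytosine counts
packed at the minimum per-block bit width, growing a block's capacity by
one bit whenever a counter overflows it.  Forward-mode alignments
contribute evidence at reference Cs, reverse-mode alignments at reference
Gs.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from ._seq import A, C, G, T
from .index import EncodedReference

_RANK_STRIDE = 512
BLOCK_LEN = 256

CONTEXT_CPG = "CpG"
CONTEXT_CHG = "CHG"
CONTEXT_CHH = "CHH"


class RankBitVector:
    """Bit-vector with sampled cumulative counts for O(1)-ish rank."""

    def __init__(self, bits: np.ndarray):
        self.bits = bits.astype(np.uint8)
        n = len(bits)
        nblocks = n // _RANK_STRIDE + 1
        samples = np.zeros(nblocks, dtype=np.int64)
        if nblocks > 1:
            per_block = np.add.reduceat(
                self.bits, np.arange(0, n, _RANK_STRIDE), dtype=np.int64
            )
            samples[1:] = np.cumsum(per_block[: nblocks - 1])
        self._samples = samples
        self.n = n

    def rank(self, i: int) -> int:
        """Number of set bits in ``[0, i)``."""
        if not 0 <= i <= self.n:
            raise IndexError(f"rank position {i} outside [0, {self.n}]")
        b = i // _RANK_STRIDE
        return int(self._samples[b] + self.bits[b * _RANK_STRIDE : i].sum())

    @property
    def total(self) -> int:
        return self.rank(self.n)


def build_cg_bitvector(ref: EncodedReference) -> RankBitVector:
    """Mark every reference C and G with a 1."""
    return RankBitVector(((ref.codes == C) | (ref.codes == G)).astype(np.uint8))


class _BlockedArray:
    """One capacity-growing blocked counter array (values always exact)."""

    def __init__(self, n_counters: int, block_len: int = BLOCK_LEN):
        self.n = n_counters
        self.bl = block_len
        nblocks = max(1, -(-n_counters // block_len))
        self.capacity = np.ones(nblocks, dtype=np.int64)  # bits per counter
        self._packed: List[np.ndarray] = [
            np.zeros(block_len // 8, dtype=np.uint8) for _ in range(nblocks)
        ]
        self.rebuilds = 0

    def _decode(self, b: int) -> np.ndarray:
        cap = int(self.capacity[b])
        bits = np.unpackbits(self._packed[b], count=self.bl * cap)
        weights = 1 << np.arange(cap - 1, -1, -1, dtype=np.int64)
        return bits.reshape(self.bl, cap).astype(np.int64) @ weights

    def _encode(self, b: int, values: np.ndarray, cap: int) -> None:
        shifts = np.arange(cap - 1, -1, -1, dtype=np.int64)
        bits = ((values[:, None] >> shifts) & 1).astype(np.uint8)
        self._packed[b] = np.packbits(bits.reshape(-1))
        self.capacity[b] = cap

    def get(self, idx: int) -> int:
        if not 0 <= idx < self.n:
            raise IndexError(f"counter index {idx} outside [0, {self.n})")
        b, off = divmod(idx, self.bl)
        return int(self._decode(b)[off])

    def increment(self, idx: int) -> None:
        if not 0 <= idx < self.n:
            raise IndexError(f"counter index {idx} outside [0, {self.n})")
        b, off = divmod(idx, self.bl)
        values = self._decode(b)
        values[off] += 1
        cap = int(self.capacity[b])
        if values[off] >= (1 << cap):  # overflow: rebuild with one extra bit
            cap += 1
            self.rebuilds += 1
        self._encode(b, values, cap)

    def add_many(self, idxs: np.ndarray) -> None:
        """Batched increments (+1 per listed index, duplicates allowed)."""
        if idxs.size == 0:
            return
        if idxs.min() < 0 or idxs.max() >= self.n:
            raise IndexError("counter index out of range")
        blocks = idxs // self.bl
        for b in np.unique(blocks).tolist():
            sel = idxs[blocks == b] - b * self.bl
            values = self._decode(b)
            np.add.at(values, sel, 1)
            cap = int(self.capacity[b])
            vmax = int(values.max())
            while vmax >= (1 << cap):
                cap += 1
                self.rebuilds += 1
            self._encode(b, values, cap)

    def to_array(self) -> np.ndarray:
        out = np.concatenate([self._decode(b) for b in range(len(self._packed))])
        return out[: self.n]


class CompressedCounters:
    """Primary (C/G) and converted (T/A) counters over rank space."""

    def __init__(self, n_counters: int, block_len: int = BLOCK_LEN):
        self.n = n_counters
        self.primary = _BlockedArray(n_counters, block_len)
        self.converted = _BlockedArray(n_counters, block_len)

    def _arr(self, which: str) -> _BlockedArray:
        if which == "primary":
            return self.primary
        if which == "converted":
            return self.converted
        raise ValueError(f"unknown counter kind {which!r}")

    def increment(self, rank_index: int, which: str) -> None:
        self._arr(which).increment(rank_index)

    def get(self, rank_index: int, which: str) -> int:
        return self._arr(which).get(rank_index)

    def add_many(self, rank_indexes: np.ndarray, which: str) -> None:
        self._arr(which).add_many(np.asarray(rank_indexes, dtype=np.int64))

    @property
    def rebuilds(self) -> int:
        return self.primary.rebuilds + self.converted.rebuilds

    def to_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.primary.to_array(), self.converted.to_array()


@dataclass
class TargetSet:
    """Merged target intervals (BED, 0-based half-open) with optional
    symmetric flank extension, in concatenated-text coordinates."""

    starts: np.ndarray  # global, sorted, merged
    ends: np.ndarray
    flank: int = 0

    @classmethod
    def from_bed(cls, path, ref: EncodedReference, flank: int = 0) -> "TargetSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
        )
        if df.empty:
            raise ValueError("empty target BED")
        offsets = {name: (start, length) for name, start, length in ref.contigs}
        ivs = []
        for row in df.itertuples(index=False):
            if row.chrom not in offsets:
                raise ValueError(f"unknown contig {row.chrom!r} in BED")
            off, length = offsets[row.chrom]
            s = max(0, int(row.start) - flank)
            e = min(length, int(row.end) + flank)
            if e > s:
                ivs.append((off + s, off + e))
        ivs.sort()
        merged: List[List[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return cls(
            starts=np.array([s for s, _ in merged], dtype=np.int64),
            ends=np.array([e for _, e in merged], dtype=np.int64),
            flank=flank,
        )

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) intersects any target interval."""
        i = int(np.searchsorted(self.starts, end, side="left")) - 1
        if i >= 0 and self.ends[i] > start:
            return True
        return i + 1 < len(self.starts) and self.starts[i + 1] < end

    def mask(self, n: int) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        for s, e in zip(self.starts.tolist(), self.ends.tolist()):
            out[s:e] = True
        return out


@dataclass
class MethylationRecord:
    contig: str
    position: int  # 0-based within contig
    strand: str  # '+' for C, '-' for G
    context: str
    count_primary: int
    count_converted: int

    @property
    def coverage(self) -> int:
        return self.count_primary + self.count_converted

    @property
    def beta(self) -> Optional[float]:
        return beta(self.count_primary, self.count_converted)


def beta(count_primary: int, count_converted: int) -> Optional[float]:
    """Methylation score primary/(primary+converted); None at coverage 0."""
    cov = count_primary + count_converted
    if cov == 0:
        return None
    return count_primary / cov


def call_status(beta_value: Optional[float], threshold: float = 0.5) -> bool:
    """Methylated iff the score is strictly greater than the threshold."""
    if beta_value is None:
        raise ValueError("beta undefined (zero coverage); filter first")
    return beta_value > threshold


def classify_context(ref: EncodedReference, position: int, strand: str) -> str:
    """Standard cytosine context: CpG, CHG, or CHH (H = A/C/T).

    Positions whose context window runs off the contig end fall back to
    CHH.
    """
    codes = ref.codes
    _, cstart, clen = ref.contig_of(position)
    cend = cstart + clen
    if strand == "+":
        if codes[position] != C:
            raise ValueError(f"no C at position {position} on + strand")
        if position + 1 < cend and codes[position + 1] == G:
            return CONTEXT_CPG
        if position + 2 < cend and codes[position + 2] == G:
            return CONTEXT_CHG
        return CONTEXT_CHH
    if strand == "-":
        if codes[position] != G:
            raise ValueError(f"no G at position {position} on - strand")
        if position - 1 >= cstart and codes[position - 1] == C:
            return CONTEXT_CPG
        if position - 2 >= cstart and codes[position - 2] == C:
            return CONTEXT_CHG
        return CONTEXT_CHH
    raise ValueError(f"unknown strand {strand!r}")


def process_alignments(
    sam_source,
    ref: EncodedReference,
    *,
    min_mapq: int = 0,
    discard_multiple: bool = True,
    targets: Optional[TargetSet] = None,
    discard_off_target: bool = False,
    rank_bv: Optional[RankBitVector] = None,
) -> CompressedCounters:
    """Stream a SAM file into compressed per-cytosine counters.

    Forward-strand (C->T mode) alignments add evidence at reference Cs:
    read C -> primary, read T -> converted.  Reverse-strand (G->A mode)
    alignments mirror this at reference Gs.  Other read bases under a
    cytosine are ignored.
    """
    if discard_off_target and targets is None:
        raise ValueError("discard_off_target requires targets")
    bv = rank_bv or build_cg_bitvector(ref)
    counters = CompressedCounters(bv.total)
    offsets = {name: start for name, start, _ in ref.contigs}
    lengths = {name: length for name, _, length in ref.contigs}
    codes = ref.codes
    bits = bv.bits

    from ._seq import _CODE_OF

    with pysam.AlignmentFile(str(sam_source), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in offsets:
                raise ValueError(f"unknown contig {rec.reference_name!r} in SAM")
            if rec.mapping_quality < min_mapq:
                continue
            if discard_multiple and rec.has_tag("XT") and rec.get_tag("XT") == "R":
                continue
            L = rec.query_length
            gstart = offsets[rec.reference_name] + rec.reference_start
            if rec.reference_start + L > lengths[rec.reference_name]:
                continue
            if discard_off_target and not targets.overlaps(gstart, gstart + L):
                continue
            rcodes = _CODE_OF[
                np.frombuffer(rec.query_sequence.encode("ascii"), dtype=np.uint8)
            ]
            gseq = codes[gstart : gstart + L]
            span_bits = bits[gstart : gstart + L]
            base_rank = bv.rank(gstart)
            span_ranks = base_rank + np.cumsum(span_bits, dtype=np.int64) - 1
            # Chemistry rule: which strand's cytosines this read informs.
            # CT-rule reads report on reference Cs, GA-rule reads on Gs.
            if rec.has_tag("XB"):
                rule = rec.get_tag("XB")
            elif rec.is_read2:
                rule = "CT" if rec.is_reverse else "GA"
            else:
                rule = "GA" if rec.is_reverse else "CT"
            if rule == "CT":
                site = gseq == C
                prim = site & (rcodes == C)
                conv = site & (rcodes == T)
            else:
                site = gseq == G
                prim = site & (rcodes == G)
                conv = site & (rcodes == A)
            if prim.any():
                counters.add_many(span_ranks[prim], "primary")
            if conv.any():
                counters.add_many(span_ranks[conv], "converted")
    return counters


def _cytosine_tables(
    ref: EncodedReference, bv: RankBitVector
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Global positions, strand codes (0='+', 1='-'), context codes
    (0=CpG, 1=CHG, 2=CHH) for every marked cytosine, vectorised."""
    codes = ref.codes
    pos = np.flatnonzero(bv.bits)
    strand = (codes[pos] == G).astype(np.int8)
    n = len(codes)
    nxt1 = np.full(pos.shape, -1, dtype=np.int64)
    nxt2 = np.full(pos.shape, -1, dtype=np.int64)
    # contig-bounded neighbour bases
    starts = ref.contig_starts()
    ends = starts + np.array([l for _, _, l in ref.contigs])
    ci = np.searchsorted(starts, pos, side="right") - 1
    cend = ends[ci]
    cstart = starts[ci]
    ctx = np.full(pos.shape, 2, dtype=np.int8)  # CHH default / fallback
    fwd = strand == 0
    ok1 = fwd & (pos + 1 < cend)
    ctx[ok1 & (np.where(ok1, codes[np.minimum(pos + 1, n - 1)], 255) == G)] = 0
    ok2 = fwd & (pos + 2 < cend) & (ctx != 0)
    ctx[ok2 & (np.where(ok2, codes[np.minimum(pos + 2, n - 1)], 255) == G)] = 1
    rev = strand == 1
    okr1 = rev & (pos - 1 >= cstart)
    ctx[okr1 & (np.where(okr1, codes[np.maximum(pos - 1, 0)], 255) == C)] = 0
    okr2 = rev & (pos - 2 >= cstart) & (ctx != 0)
    ctx[okr2 & (np.where(okr2, codes[np.maximum(pos - 2, 0)], 255) == C)] = 1
    return pos, strand, ctx


def build_record_frame(
    ref: EncodedReference,
    bv: RankBitVector,
    counters: CompressedCounters,
) -> pd.DataFrame:
    """Per-cytosine table (one row per reference C/G, both strands)."""
    pos, strand, ctx = _cytosine_tables(ref, bv)
    primary, converted = counters.to_arrays()
    starts = ref.contig_starts()
    ci = np.searchsorted(starts, pos, side="right") - 1
    names = np.array([name for name, _, _ in ref.contigs])
    df = pd.DataFrame(
        {
            "contig": names[ci],
            "position": pos - starts[ci],
            "global_position": pos,
            "strand": np.where(strand == 0, "+", "-"),
            "context": np.array([CONTEXT_CPG, CONTEXT_CHG, CONTEXT_CHH])[ctx],
            "count_primary": primary,
            "count_converted": converted,
        }
    )
    cov = df["count_primary"] + df["count_converted"]
    df["coverage"] = cov
    df["beta"] = np.where(cov > 0, df["count_primary"] / cov.replace(0, 1), np.nan)
    return df


def records_from_frame(df: pd.DataFrame) -> List[MethylationRecord]:
    return [
        MethylationRecord(
            r.contig, int(r.position), r.strand, r.context,
            int(r.count_primary), int(r.count_converted),
        )
        for r in df.itertuples(index=False)
    ]


def _fmt_beta_pct(b: float) -> str:
    return f"{100.0 * b:g}"


def emit(
    records: pd.DataFrame,
    path,
    *,
    format: str = "cov",
    compress: str = "none",
    on_target_only: bool = False,
    targets: Optional[TargetSet] = None,
) -> None:
    """Write methylation annotations.

    Formats:

    * ``cov`` -- Bismark-coverage compatible: contig, 1-based pos (twice),
      methylation percentage, primary count, converted count; covered
      cytosines only.
    * ``bed`` -- 0-based half-open: contig, start, end, strand, context,
      primary, converted, beta (``NA`` at zero coverage); all cytosines.
    * ``epp`` -- fixed-column dialect (documented in the README): contig,
      1-based pos, strand, context, primary, coverage, beta; covered only.

    ``compress='gzip'`` streams the same bytes through gzip.
    """
    if on_target_only:
        if targets is None:
            raise ValueError("on_target_only requires targets")
        gp = records["global_position"].to_numpy()
        idx = np.searchsorted(targets.starts, gp, side="right") - 1
        keep = (idx >= 0) & (targets.ends[np.maximum(idx, 0)] > gp)
        records = records[keep]
    if compress == "gzip":
        fh = gzip.open(path, "wt", newline="\n")
    elif compress == "none":
        fh = open(path, "w", newline="\n")
    else:
        raise ValueError(f"unsupported compression {compress!r}")
    with fh:
        if format == "cov":
            covered = records[records["coverage"] > 0]
            for r in covered.itertuples(index=False):
                p1 = r.position + 1
                fh.write(
                    f"{r.contig}\t{p1}\t{p1}\t{_fmt_beta_pct(r.beta)}"
                    f"\t{r.count_primary}\t{r.count_converted}\n"
                )
        elif format == "bed":
            for r in records.itertuples(index=False):
                b = "NA" if r.coverage == 0 else f"{r.beta:.6g}"
                fh.write(
                    f"{r.contig}\t{r.position}\t{r.position + 1}\t{r.strand}"
                    f"\t{r.context}\t{r.count_primary}\t{r.count_converted}\t{b}\n"
                )
        elif format == "epp":
            covered = records[records["coverage"] > 0]
            for r in covered.itertuples(index=False):
                fh.write(
                    f"{r.contig}\t{r.position + 1}\t{r.strand}\t{r.context}"
                    f"\t{r.count_primary}\t{r.coverage}\t{r.beta:.6g}\n"
                )
        else:
            raise ValueError(f"unknown output format {format!r}")


def coverage_from_sam(sam_source, ref: EncodedReference) -> np.ndarray:
    """Per-position read coverage over the concatenated text (ungapped)."""
    diff = np.zeros(ref.n + 1, dtype=np.int64)
    offsets = {name: start for name, start, _ in ref.contigs}
    with pysam.AlignmentFile(str(sam_source), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            s = offsets[rec.reference_name] + rec.reference_start
            diff[s] += 1
            diff[min(s + rec.query_length, ref.n)] -= 1
    return np.cumsum(diff[:-1])


def target_stats(
    aligned_spans: Sequence[Tuple[int, int]],
    coverage_per_position: np.ndarray,
    targets: TargetSet,
    max_distance: int = 500,
) -> Dict:
    """Target-enrichment report.

    Returns the fraction of aligned bases on target, the mean coverage over
    target positions, and mean coverage as a function of distance (1..
    ``max_distance``) from the nearest target edge, pooled over both
    flanks.
    """
    if len(targets.starts) == 0:
        raise ValueError("empty target set")
    n = len(coverage_per_position)
    tmask = targets.mask(n)
    total_bases = 0
    on_target_bases = 0
    for s, e in aligned_spans:
        s, e = max(0, s), min(n, e)
        if e <= s:
            continue
        total_bases += e - s
        on_target_bases += int(tmask[s:e].sum())
    mean_cov = float(coverage_per_position[tmask].mean()) if tmask.any() else 0.0
    # distance from the nearest target edge, outside targets only
    dist_sum = np.zeros(max_distance + 1, dtype=np.float64)
    dist_cnt = np.zeros(max_distance + 1, dtype=np.int64)
    for s, e in zip(targets.starts.tolist(), targets.ends.tolist()):
        for d in range(1, max_distance + 1):
            for p in (s - d, e - 1 + d):
                if 0 <= p < n and not tmask[p]:
                    dist_sum[d] += coverage_per_position[p]
                    dist_cnt[d] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(dist_cnt > 0, dist_sum / np.maximum(dist_cnt, 1), np.nan)
    return {
        "on_target_fraction": (on_target_bases / total_bases) if total_bases else 0.0,
        "mean_target_coverage": mean_cov,
        "coverage_by_distance": profile[1:],
    }
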