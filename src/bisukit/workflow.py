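"""Batch drivers tying the index, aligner, and caller together."""

from __future__ import annotations

import logging
from itertools import zip_longest
from typing import Dict, List, Optional, Tuple

import pysam

from . import _seq
from .align import AlignParams, Aligner, ReadAlignment, _sam_header, _segment
from .index import DBHashIndex
from .methcall import build_cg_bitvector, build_record_frame, process_alignments

log = logging.getLogger("bisukit")


def align_fastq(
    index: DBHashIndex,
    fastq1,
    fastq2=None,
    params: Optional[AlignParams] = None,
    out_sam=None,
    collect: bool = False,
) -> Dict:
    """Align a FASTQ library (paired when ``fastq2`` is given) against the
    index, optionally writing SAM and/or collecting per-read tuples of
    (read_id, mate, status, contig, position, mode) for evaluation."""
    params = params or AlignParams(seed_length=index.params.m)
    aligner = Aligner(index, params)
    header = _sam_header(index.reference)
    out = pysam.AlignmentFile(str(out_sam), "w", header=header) if out_sam else None
    counts = {"total": 0, "unique": 0, "multiple": 0, "unmapped": 0, "proper": 0}
    collected: List[Tuple] = []

    def _tally(aln: ReadAlignment, mate: int) -> None:
        counts["total"] += 1
        counts[aln.status] += 1
        if collect:
            collected.append(
                (aln.read_id, mate, aln.status, aln.contig, aln.position, aln.mode)
            )

    try:
        if fastq2 is not None:
            it = zip_longest(_seq.read_fastq(fastq1), _seq.read_fastq(fastq2))
            for r1, r2 in it:
                if r1 is None or r2 is None:
                    raise ValueError("paired FASTQ files have unequal read counts")
                a1, a2, proper = aligner.align_pair(r1, r2)
                _tally(a1, 1)
                _tally(a2, 2)
                if proper:
                    counts["proper"] += 1
                if out:
                    out.write(
                        _segment(a1, header, paired=True, first=True, proper=proper, mate=a2)
                    )
                    out.write(
                        _segment(a2, header, paired=True, first=False, proper=proper, mate=a1)
                    )
        else:
            for rid, seq, qual in _seq.read_fastq(fastq1):
                aln = aligner.align_read(rid, seq, qual)
                _tally(aln, 0)
                if out:
                    out.write(_segment(aln, header))
    finally:
        if out:
            out.close()
    log.info(
        "aligned %d reads: %d unique, %d multiple, %d unmapped",
        counts["total"], counts["unique"], counts["multiple"], counts["unmapped"],
    )
    counts["alignments"] = collected
    return counts


def call_methylation(
    sam_path,
    ref,
    *,
    min_mapq: int = 0,
    discard_multiple: bool = True,
    targets=None,
    discard_off_target: bool = False,
):
    """SAM -> per-cytosine record frame (see methcall.build_record_frame)."""
    bv = build_cg_bitvector(ref)
    counters = process_alignments(
        sam_path,
        ref,
        min_mapq=min_mapq,
        discard_multiple=discard_multiple,
        targets=targets,
        discard_off_target=discard_off_target,
        rank_bv=bv,
    )
    frame = build_record_frame(ref, bv, counters)
    log.info(
        "called %d cytosines, %d covered",
        len(frame), int((frame["coverage"] > 0).sum()),
    )
    return frame
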