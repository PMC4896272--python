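"""Exhaustive hash-law checks and the scaled end-to-end evaluation protocol.

These routines back both the acceptance test suite and the standalone
acceptance report: exhaustive verification of the fingerprint laws over
all patterns of a small length, and a full simulate -> index -> align ->
call -> evaluate pipeline on a synthetic genome.
"""

from __future__ import annotations

import os
import tempfile
from typing import Dict, Iterable, Tuple

import numpy as np

from ._seq import ALPHA_OF_CODE
from .align import AlignParams
from .bshash import HashParams, default_width
from .index import build_index, preprocess_reference
from .simulate import (
    evaluate_mapping,
    evaluate_methylation,
    simulate_genome,
    simulate_methylome,
    simulate_reads,
    write_fasta,
    write_fastq,
)
from .workflow import align_fastq, call_methylation

# base codes are 2-bit digits of the pattern id, MSB-first
_ALPHA_OF_DIGIT = ALPHA_OF_CODE.astype(np.uint64)


def all_pattern_fingerprints(m: int, w: int) -> np.ndarray:
    """Fingerprints of every pattern in {A,C,G,T}^m, indexed by the base-4
    pattern id (position 0 = most significant digit).  Vectorised
    evaluation of the block-XOR definition."""
    HashParams(m, w)  # validate
    n = 4**m
    ids = np.arange(n, dtype=np.uint64)
    bits = np.empty((n, m), dtype=np.uint64)
    for i in range(m):
        shift = np.uint64(2 * (m - 1 - i))
        bits[:, i] = _ALPHA_OF_DIGIT[(ids >> shift) & np.uint64(3)]
    pow2 = np.uint64(1) << np.arange(w - 1, -1, -1, dtype=np.uint64)
    fps = np.zeros(n, dtype=np.uint64)
    nblocks = -(-m // w)
    for i in range(nblocks - 1):
        fps ^= bits[:, i * w : (i + 1) * w] @ pow2
    fps ^= bits[:, m - w :] @ pow2
    return fps


def _substitution_neighbours(m: int, pos: int, delta: int) -> np.ndarray:
    """Pattern ids after changing digit ``pos`` by ``delta`` (mod 4)."""
    ids = np.arange(4**m, dtype=np.int64)
    shift = 2 * (m - 1 - pos)
    d = (ids >> shift) & 3
    nd = (d + delta) % 4
    return ids + ((nd - d) << shift)


def debruijn_violations(m: int, w: int) -> int:
    """Count of overlapping pattern pairs whose fingerprints do not
    overlap (must be 0 for a de Bruijn hash)."""
    fps = all_pattern_fingerprints(m, w)
    ids = np.arange(4**m, dtype=np.int64)
    mask = (1 << (2 * (m - 1))) - 1
    wmask = np.uint64((1 << (w - 1)) - 1)
    bad = 0
    for c in range(4):
        succ = ((ids & mask) << 2) | c
        bad += int(np.count_nonzero((fps & wmask) != (fps[succ] >> np.uint64(1))))
    return bad


def bisulfite_violations(m: int, w: int) -> int:
    """Count of single C->T or G->A substitutions that change the
    fingerprint (must be 0); invariance under arbitrary substitution
    subsets follows by composing single substitutions."""
    fps = all_pattern_fingerprints(m, w)
    ids = np.arange(4**m, dtype=np.int64)
    bad = 0
    for pos in range(m):
        shift = 2 * (m - 1 - pos)
        digit = (ids >> shift) & 3
        for src, dst in ((1, 3), (2, 0)):  # C->T, G->A
            sel = digit == src
            nb = ids[sel] + ((dst - src) << shift)
            bad += int(np.count_nonzero(fps[sel] != fps[nb]))
    return bad


def max_fingerprint_distance(m: int, w: int, k: int) -> Tuple[int, int]:
    """(max fingerprint Hamming distance, number of ordered pairs) over all
    pattern pairs at Hamming distance exactly ``k`` (k in {1, 2})."""
    fps = all_pattern_fingerprints(m, w)
    best = 0
    n_pairs = 0
    if k == 1:
        for pos in range(m):
            for delta in (1, 2, 3):
                nb = _substitution_neighbours(m, pos, delta)
                d = np.bitwise_count(fps ^ fps[nb])
                best = max(best, int(d.max()))
                n_pairs += len(nb)
    elif k == 2:
        for p in range(m):
            for q in range(p + 1, m):
                for dp in (1, 2, 3):
                    nb1 = _substitution_neighbours(m, p, dp)
                    for dq in (1, 2, 3):
                        nb = nb1[_substitution_neighbours(m, q, dq)]
                        d = np.bitwise_count(fps ^ fps[nb])
                        best = max(best, int(d.max()))
                        n_pairs += len(nb)
    else:
        raise ValueError("k must be 1 or 2")
    return best, n_pairs


def hamming_bound_ratio(m: int = 8, w: int = 4) -> Dict:
    """Worst-case fingerprint-distance-per-pattern-mismatch over exhaustive
    enumeration at k = 1, 2.  The hash law promises a ratio of at most 2."""
    m1, n1 = max_fingerprint_distance(m, w, 1)
    m2, n2 = max_fingerprint_distance(m, w, 2)
    # pairs at distance <= 2 include distance-1 pairs
    ratio = max(m1 / 1.0, max(m1, m2) / 2.0)
    return {"ratio": ratio, "max_d1": m1, "max_d2": m2, "n_pairs": n1 + n2}


def run_bs_pipeline(
    seed: int,
    *,
    genome_length: int = 1_000_000,
    gc_content: float = 0.36,
    coverage: float = 24.6,
    read_length: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 50.0,
    conversion_efficiency: float = 0.98,
    error_rate: float = 0.01,
    p_meth_cpg: float = 0.8,
    p_meth_non_cpg: float = 0.05,
    seed_length: int = 30,
    seed_errors: int = 2,
    min_coverage: int = 3,
    threshold: float = 0.5,
    tolerance: int = 50,
    workdir=None,
) -> Dict:
    """Simulate a directional BS-seq library, run the full file-based
    pipeline (FASTA/FASTQ/SAM), and score mapping and methylation calls
    against the simulated truth."""
    sub = np.random.SeedSequence(seed).generate_state(4)
    tmp = workdir or tempfile.mkdtemp(prefix="bisukit-accept-")
    genome = simulate_genome(genome_length, gc_content, int(sub[0]))
    methylome = simulate_methylome(genome, p_meth_cpg, p_meth_non_cpg, int(sub[1]))
    reads1, reads2, truth = simulate_reads(
        genome,
        methylome,
        coverage=coverage,
        read_length=read_length,
        paired=True,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        conversion_efficiency=conversion_efficiency,
        error_rate=error_rate,
        rng_seed=int(sub[2]),
        contig_name="sim1",
    )
    fasta = os.path.join(tmp, "genome.fa")
    fq1 = os.path.join(tmp, "reads_1.fastq")
    fq2 = os.path.join(tmp, "reads_2.fastq")
    sam = os.path.join(tmp, "aligned.sam")
    write_fasta(genome, fasta, name="sim1")
    write_fastq(reads1, fq1)
    write_fastq(reads2, fq2)

    ref = preprocess_reference(fasta, rng_seed=int(sub[3]))
    w = min(default_width(ref.n), seed_length)
    index = build_index(ref, HashParams(seed_length, w))
    params = AlignParams(seed_errors=seed_errors, seed_length=seed_length)
    align_result = align_fastq(index, fq1, fq2, params, sam, collect=True)
    mapping = evaluate_mapping(align_result["alignments"], truth, tolerance)
    frame = call_methylation(sam, ref)
    methylation = evaluate_methylation(frame, methylome, min_coverage, threshold)
    return {
        "n_pairs": len(reads1),
        "align_counts": {
            k: align_result[k]
            for k in ("total", "unique", "multiple", "unmapped", "proper")
        },
        "mapping": mapping,
        "methylation": methylation,
        "workdir": tmp,
    }
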