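"""Directional BS-seq simulator and evaluation harness.

Fragments are drawn uniformly from either original strand.  For a
top-strand fragment, read 1 observes the bisulfite-converted forward
sequence (unmethylated C -> T with probability ``conversion_efficiency``)
and read 2 the reverse complement of the converted fragment end; for a
bottom-strand fragment the roles mirror (G -> A pattern on forward
coordinates).  Uniform substitution errors are applied after conversion.
Per-read truth (contig, 0-based origin, conversion mode) is encoded in the
read names and mirrored in a sidecar TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import _seq
from ._seq import A, C, G, T
from .align import MODE_CT, MODE_FG, MODE_GA, MODE_RC, STATUS_UNIQUE
from .methcall import call_status

UNMARKED = -1  # methylome value at non-cytosine positions


def simulate_genome(
    length: int, gc_content: float = 0.5, rng_seed: int = 0
) -> str:
    """Random genome with the requested GC fraction (length >= 1 kbp)."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    codes = rng.choice(
        np.arange(4, dtype=np.uint8), size=length, p=[p_at, p_gc, p_gc, p_at]
    )
    return _seq.decode(codes)


def write_fasta(seq: str, path, name: str = "sim1", width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def simulate_methylome(
    genome: str,
    p_meth_cpg: float = 0.8,
    p_meth_non_cpg: float = 0.05,
    rng_seed: int = 0,
) -> np.ndarray:
    """Independent binary methylation state per C and G position.

    Returns an int8 array over the genome: 1 methylated, 0 unmethylated,
    -1 at non-cytosine positions.  CpG-context cytosines (C followed by G;
    G preceded by C) use ``p_meth_cpg``, all others ``p_meth_non_cpg``.
    """
    for p in (p_meth_cpg, p_meth_non_cpg):
        if not 0.0 <= p <= 1.0:
            raise ValueError("methylation probabilities must be in [0, 1]")
    codes = _seq.encode(genome)
    n = len(codes)
    rng = np.random.default_rng(rng_seed)
    state = np.full(n, UNMARKED, dtype=np.int8)
    is_c = codes == C
    is_g = codes == G
    cpg_c = is_c.copy()
    cpg_c[:-1] &= codes[1:] == G
    cpg_c[-1] = False
    cpg_g = is_g.copy()
    cpg_g[1:] &= codes[:-1] == C
    cpg_g[0] = False
    cyt = is_c | is_g
    in_cpg = cpg_c | cpg_g
    p = np.where(in_cpg, p_meth_cpg, p_meth_non_cpg)
    draws = (rng.random(n) < p).astype(np.int8)
    state[cyt] = draws[cyt]
    return state


@dataclass
class ReadTruth:
    read_id: str
    mate: int  # 1 or 2 (0 for single-end)
    contig: str
    position: int  # 0-based origin of the read on the forward reference
    mode: str  # MODE_CT | MODE_GA


def _apply_conversion(
    frag: np.ndarray,
    state: np.ndarray,
    rng: np.random.Generator,
    conversion_efficiency: float,
    strand_top: bool,
) -> np.ndarray:
    """Bisulfite-convert one fragment (given in forward coordinates)."""
    out = frag.copy()
    if strand_top:
        targets = (frag == C) & (state != 1)
        converted_code = T
    else:
        targets = (frag == G) & (state != 1)
        converted_code = A
    hit = targets & (rng.random(len(frag)) < conversion_efficiency)
    out[hit] = converted_code
    return out


def _apply_errors(
    codes: np.ndarray, rng: np.random.Generator, error_rate: float
) -> np.ndarray:
    if error_rate <= 0:
        return codes
    out = codes.copy()
    hit = rng.random(len(codes)) < error_rate
    if hit.any():
        # shift by 1..3 mod 4: always a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def simulate_reads(
    genome: str,
    methylome: np.ndarray,
    *,
    coverage: float = 20.0,
    read_length: int = 100,
    paired: bool = True,
    insert_mean: float = 300.0,
    insert_sd: float = 50.0,
    conversion_efficiency: float = 0.98,
    error_rate: float = 0.0,
    rng_seed: int = 0,
    contig_name: str = "sim1",
) -> Tuple[List[Tuple[str, str, str]], List[Tuple[str, str, str]], List[ReadTruth]]:
    """Simulate a directional paired (or single-end) library.

    Returns (reads1, reads2, truth); each read is an (id, seq, qual)
    triple, reads2 is empty for single-end libraries.
    """
    codes = _seq.encode(genome)
    n = len(codes)
    if read_length > n:
        raise ValueError("read_length exceeds genome length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(rng_seed)
    bases_per_unit = 2 * read_length if paired else read_length
    n_units = int(round(coverage * n / bases_per_unit))
    reads1: List[Tuple[str, str, str]] = []
    reads2: List[Tuple[str, str, str]] = []
    truth: List[ReadTruth] = []
    qual = "I" * read_length
    L = read_length
    for i in range(n_units):
        if paired:
            insert = int(round(rng.normal(insert_mean, insert_sd)))
            insert = max(L, min(insert, n))
        else:
            insert = L
        start = int(rng.integers(0, n - insert + 1))
        end = start + insert
        top = bool(rng.integers(0, 2))
        frag = codes[start:end]
        conv = _apply_conversion(
            frag, methylome[start:end], rng, conversion_efficiency, top
        )
        if top:
            # read 1 observes the converted top strand, read 2 its complement
            r1 = conv[:L]
            m1, p1 = MODE_CT, start
            r2 = _seq.revcomp_codes(conv[-L:])
            m2, p2 = MODE_RC, end - L
        else:
            r1 = _seq.revcomp_codes(conv[-L:])
            m1, p1 = MODE_GA, end - L
            r2 = conv[:L]
            m2, p2 = MODE_FG, start
        r1 = _apply_errors(r1, rng, error_rate)
        name = f"sim{i}"
        if paired:
            r2 = _apply_errors(r2, rng, error_rate)
            reads1.append((name, _seq.decode(r1), qual))
            reads2.append((name, _seq.decode(r2), qual))
            truth.append(ReadTruth(name, 1, contig_name, p1, m1))
            truth.append(ReadTruth(name, 2, contig_name, p2, m2))
        else:
            reads1.append((name, _seq.decode(r1), qual))
            truth.append(ReadTruth(name, 0, contig_name, p1, m1))
    return reads1, reads2, truth


def write_fastq(reads: Iterable[Tuple[str, str, str]], path) -> None:
    with _seq.open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth(truth: Iterable[ReadTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tcontig\tposition\tmode\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.mate}\t{t.contig}\t{t.position}\t{t.mode}\n")


def read_truth(path) -> List[ReadTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        ReadTruth(str(r.read_id), int(r.mate), str(r.contig), int(r.position), r.mode)
        for r in df.itertuples(index=False)
    ]


def evaluate_mapping(
    alignments: Iterable[Tuple[str, int, str, Optional[str], int, Optional[str]]],
    truth: Iterable[ReadTruth],
    tolerance: int = 50,
) -> Dict[str, float]:
    """Mapping accuracy against simulator ground truth.

    ``alignments`` yields (read_id, mate, status, contig, position, mode)
    tuples.  A unique alignment is correct iff contig and conversion mode
    match the truth and the reported position is within ``tolerance``
    bases of the true origin.
    """
    truth_by_key = {(t.read_id, t.mate): t for t in truth}
    total = 0
    unique = 0
    correct = 0
    for read_id, mate, status, contig, position, mode in alignments:
        key = (read_id, mate)
        if key not in truth_by_key:
            raise KeyError(f"read {read_id!r} mate {mate} missing from truth")
        t = truth_by_key[key]
        total += 1
        if status != STATUS_UNIQUE:
            continue
        unique += 1
        if (
            contig == t.contig
            and mode == t.mode
            and abs(position - t.position) <= tolerance
        ):
            correct += 1
    return {
        "total": total,
        "unique_fraction": unique / total if total else 0.0,
        "correct_fraction": correct / unique if unique else 0.0,
        "n_unique": unique,
        "n_correct": correct,
    }


def evaluate_methylation(
    records: pd.DataFrame,
    methylome: np.ndarray,
    min_coverage: int = 3,
    threshold: float = 0.5,
) -> Dict[str, float]:
    """Methylation-call accuracy against the simulated binary states.

    Cytosines with coverage below ``min_coverage`` are excluded from the
    accuracy denominator; a cytosine is called methylated iff beta is
    strictly greater than ``threshold``.
    """
    gp = records["global_position"].to_numpy()
    cov = records["coverage"].to_numpy()
    prim = records["count_primary"].to_numpy()
    true_state = methylome[gp]
    if (true_state == UNMARKED).any():
        raise ValueError("record at a non-cytosine position")
    n_cyt = int((methylome != UNMARKED).sum())
    covered = cov >= min_coverage
    n_cov = int(covered.sum())
    betas = prim[covered] / cov[covered]
    calls = betas > threshold
    correct = int((calls == (true_state[covered] == 1)).sum())
    return {
        "n_cytosines": n_cyt,
        "covered_fraction": n_cov / n_cyt if n_cyt else 0.0,
        "n_evaluated": n_cov,
        "accuracy": correct / n_cov if n_cov else 0.0,
    }
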