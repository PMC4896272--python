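import io

import numpy as np
import pytest

from bisukit import _seq
from bisukit.align import MODE_CT, MODE_FG, MODE_GA, MODE_RC
from bisukit.bshash import HashParams
from bisukit.index import EncodedReference, build_index, preprocess_reference


def make_reference(seq: str, name: str = "c1", rng_seed: int = 0) -> EncodedReference:
    return preprocess_reference(io.StringIO(f">{name}\n{seq}\n"), rng_seed)


def make_index(seq: str, m: int, w: int, name: str = "c1"):
    return build_index(make_reference(seq, name), HashParams(m, w))


@pytest.fixture
def tiny_index():
    """The worked 'AACGT' example: m=3, w=2, buckets {01:[0], 11:[1,2]}."""
    return make_index("AACGT", m=3, w=2)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _seq.decode(rng.integers(0, 4, size=n).astype(np.uint8))


# --- independent brute-force alignment oracle ---------------------------


def _scan_mode(gcodes, qcodes, rule, m, k, budget):
    """Full scan of one oriented query: all (pos, mm) with seed mismatches
    <= k and total mismatches <= budget, by explicit window comparison."""
    from numpy.lib.stride_tricks import sliding_window_view

    L = len(qcodes)
    n = len(gcodes)
    if n < L:
        return []
    win = sliding_window_view(gcodes, L)
    if rule == "CT":
        fg, fr = 1, 3  # genome C may read T
    else:
        fg, fr = 2, 0  # genome G may read A
    mm = (win != qcodes) & ~((win == fg) & (qcodes == fr))
    seed_mm = mm[:, :m].sum(axis=1)
    total_mm = mm.sum(axis=1)
    ok = (seed_mm <= k) & (total_mm <= budget)
    return [(int(p), int(total_mm[p])) for p in np.flatnonzero(ok)]


def brute_force_placements(ref_seq: str, read_seq: str, m: int, k: int,
                           budget: int, mate2: bool = False):
    """Oracle: every placement over all text positions and both
    orientations, independent of the fingerprint machinery."""
    gcodes = _seq.encode(ref_seq)
    qf = _seq.encode(read_seq.upper())
    qr = _seq.revcomp_codes(qf)
    if mate2:
        oriented = ((qf, "GA", MODE_FG), (qr, "CT", MODE_RC))
    else:
        oriented = ((qf, "CT", MODE_CT), (qr, "GA", MODE_GA))
    out = []
    for q, rule, mode in oriented:
        for pos, mm in _scan_mode(gcodes, q, rule, m, k, budget):
            out.append((pos, mode, mm))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out
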