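import logging

import numpy as np
import pytest

from lysovir import synthetic

logging.getLogger("lysovir").setLevel(logging.ERROR)


@pytest.fixture()
def small_host():
    return synthetic.generate_host(100_000, 0.665, seed=11)


@pytest.fixture()
def lt_spec():
    """A 46-kb pac-type prophage matching the canonical lateral-transduction
    geometry: pac 16 kb inside the left end, packaging off the attL flank."""
    return synthetic.ProphageSpec(
        id="p1",
        length_bp=46_000,
        attb_pos=50_000,
        orientation="-",
        pac_offset_bp=16_000,
        packaging_mode=synthetic.HEADFUL_IN_SITU,
        induction_weight=1.0,
        in_situ_prob=0.5,
        max_headfuls=2,
        continuation_prob=0.5,
    )


@pytest.fixture()
def small_lysogen(small_host, lt_spec):
    return synthetic.build_lysogen(small_host, [lt_spec], seed=12)


def brute_force_map(read_codes: np.ndarray, ref_codes: np.ndarray, max_mismatch: int):
    """Exhaustive-scan oracle mapper: best (mm, start, strand) over every
    position and both strands, same tie-break as the production mapper."""
    from lysovir import _seq

    rl = len(read_codes)
    n = len(ref_codes)
    if n < rl:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(ref_codes, rl)
    best = None
    for strand_rank, q in enumerate((read_codes, _seq.revcomp_codes(read_codes))):
        mm = (windows != q).sum(axis=1)
        for start in np.flatnonzero(mm <= max_mismatch):
            cand = (int(mm[start]), int(start), strand_rank)
            if best is None or cand < best:
                best = cand
    return best
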