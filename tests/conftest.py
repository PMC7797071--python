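import random

import pytest

from asotiler import TargetSeq, ThermoConfig, TilingParams


@pytest.fixture(scope="session")
def cfg():
    return ThermoConfig()


@pytest.fixture(scope="session")
def params():
    return TilingParams()


def random_rna(rng: random.Random, length: int, gc_lo: float = 0.0, gc_hi: float = 1.0) -> str:
    """Random RNA string with realized GC fraction in [gc_lo, gc_hi].

    Bases are drawn with GC probability at the band midpoint, then rejected
    if the realized fraction falls outside the band.
    """
    p_gc = (gc_lo + gc_hi) / 2
    weights = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    while True:
        s = "".join(rng.choices("ACGU", weights=weights, k=length))
        gc = sum(c in "GC" for c in s) / length
        if gc_lo <= gc <= gc_hi:
            return s


@pytest.fixture
def poly_a_target():
    def make(length: int) -> TargetSeq:
        return TargetSeq(id=f"polyA{length}", seq="A" * length)

    return make
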