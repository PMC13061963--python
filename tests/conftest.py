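import numpy as np
import pytest

from doodlekit.reads import AdapterSet, Read, ReadPool


def make_read(seq: str, q: int = 30, rid: str = "r0", **meta) -> Read:
    return Read(rid, seq, np.full(len(seq), q, dtype=int), meta=meta)


@pytest.fixture
def adapter_set() -> AdapterSet:
    return AdapterSet(("AATGTACTTCGTTCAGTTACGTATTGCT",))


@pytest.fixture
def random_pool() -> ReadPool:
    rng = np.random.default_rng(42)
    reads = []
    for i in range(30):
        n = int(rng.integers(70, 300))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        reads.append(make_read(seq, rid=f"rand_{i}"))
    return ReadPool(reads)
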