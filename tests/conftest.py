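import numpy as np
import pytest

from kmerprof import Profile, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_profile_factory(rng):
    """Random sparse-ish integer profiles for algebra/metric tests."""

    def make(k: int, density: float = 0.5, max_count: int = 20, label: str = "") -> Profile:
        n = 4**k
        counts = rng.integers(0, max_count + 1, size=n).astype(np.uint64)
        counts[rng.random(n) >= density] = 0
        return Profile(k, counts, label)

    return make


@pytest.fixture
def random_reads_factory(rng):
    def make(n_reads: int, length: int) -> list[SequenceRecord]:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        return [
            SequenceRecord(
                f"r{i}", bases[rng.integers(0, 4, size=length)].tobytes().decode()
            )
            for i in range(n_reads)
        ]

    return make
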