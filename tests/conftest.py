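import numpy as np
import pytest

from hapaudit.datasets import load_reedited_distribution
from hapaudit.io_formats import SequenceRecord


@pytest.fixture(scope="session")
def table2():
    """The packaged re-edited haplotype distribution (35 + 3 aux rows)."""
    return load_reedited_distribution()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_records(rng, n, length, n_haplotypes=None, sites=("BB", "EST", "STA")):
    """Random cohort: n individuals drawn from a pool of distinct haplotypes."""
    n_haplotypes = n_haplotypes or max(2, n // 3)
    pool = set()
    while len(pool) < n_haplotypes:
        pool.add("".join(rng.choice(list("ACGT"), size=length)))
    pool = sorted(pool)
    return [
        SequenceRecord(
            id=f"ind{i}",
            seq=pool[rng.integers(len(pool))],
            site=sites[rng.integers(len(sites))],
        )
        for i in range(n)
    ]
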