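import numpy as np
import pytest

from shadowfold.structure_io import RnaRecord
from shadowfold.synthetic_families import (FamilySpec, generate_corpus,
                                           sample_structure)


@pytest.fixture(scope="session")
def tiny_corpus() -> list[RnaRecord]:
    """Two short families, 8 members each — fast enough for folding loops."""
    specs = [
        FamilySpec(name="famA", n_members=8, length=40, structure_seed=11),
        FamilySpec(name="famB", n_members=8, length=50, structure_seed=23),
    ]
    return generate_corpus(specs, seed=7)


@pytest.fixture(scope="session")
def random_records() -> list[RnaRecord]:
    """200 random synthetic records, some with crossing pairs injected,
    for round-trip suites."""
    rng = np.random.default_rng(42)
    records = []
    for k in range(200):
        n = int(rng.integers(20, 80))
        pairs = set(sample_structure(n, int(rng.integers(2**31))))
        if k % 3 == 0:
            pairs = _inject_crossing(pairs, n, rng)
        seq = "".join(rng.choice(list("ACGU"), size=n))
        records.append(RnaRecord(id=f"r{k}", family="rand", sequence=seq,
                                 pairs=frozenset(pairs)))
    return records


def _inject_crossing(pairs: set, n: int, rng) -> set:
    used = {i for p in pairs for i in p}
    free = [i for i in range(1, n + 1) if i not in used]
    rng.shuffle(free)
    # pair up free positions at long range so some pairs cross existing ones
    while len(free) >= 2:
        i = free.pop(0)
        j = free.pop(-1)
        if j - i > 3:
            pairs.add((i, j))
        if rng.random() < 0.5:
            break
    return pairs
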