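import numpy as np
import pytest

from straysink.containers import Collection


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_925)


def make_collection(
    genotypes, name="c", role="sink-contemporary", site=None, stray=None, ids=None
) -> Collection:
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n = genotypes.shape[0]
    return Collection(
        name=name,
        genotypes=genotypes,
        ids=ids or [f"{name}_{i}" for i in range(n)],
        role=role,
        site=site or name,
        stray=stray,
    )
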