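import numpy as np
import pytest

from wtfkit.family_sim import FamilySimParams, simulate_family


@pytest.fixture(scope="session")
def default_sim():
    """One family simulation at the default study conditions, shared
    read-only across tests (5 strains, 8 loci, default rates)."""
    return simulate_family(FamilySimParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n: int) -> str:
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.integers(0, 4, n)])


def mutate_dna(rng, seq: str, rate: float) -> str:
    bases = "ACGT"
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(bases[(bases.index(ch) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(ch)
    return "".join(out)
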