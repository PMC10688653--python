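import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[c] for c in rng.integers(0, 4, size=length))


def random_protein(rng: np.random.Generator, length: int) -> str:
    symbols = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(symbols[c] for c in rng.integers(0, 20, size=length))


def mutate(rng: np.random.Generator, residues: str, n_subs: int) -> str:
    """Substitute n_subs distinct positions with a different base."""
    positions = rng.choice(len(residues), size=n_subs, replace=False)
    out = list(residues)
    for p in positions:
        out[p] = BASES[(BASES.index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
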