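import numpy as np
import pytest

from exopred import ProteinRecord, SyntheticConfig, generate

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def separable_dataset():
    """Two classes with near-disjoint preferred alphabets: trivially separable."""
    records, annotations = generate(
        SyntheticConfig(n_pos=200, n_neg=200, bias_strength=1.0, seed=11)
    )
    return records, annotations


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate-bias dataset for quick CV bookkeeping checks."""
    records, annotations = generate(
        SyntheticConfig(n_pos=50, n_neg=50, bias_strength=0.6, seed=7)
    )
    return records, annotations


@pytest.fixture()
def tiny_records():
    return [
        ProteinRecord(id="p1", sequence="ACDEFGHIKLMNPQRSTVWY" * 3),
        ProteinRecord(id="p2", sequence="MKLVFFAEDVGSNKGAIIGLMVGGVVIA"),
        ProteinRecord(id="p3", sequence="WWWWWWWWWWWWWWWWWWWWWWWWWWWWWW"),
    ]
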