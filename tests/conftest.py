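import numpy as np
import pytest

from lncpep.spectral import RESIDUE_MASSES

AMINO_ACIDS = sorted(RESIDUE_MASSES)


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), length)])


def random_peptide(rng: np.random.Generator, length: int) -> str:
    letters = np.array(AMINO_ACIDS)
    return "".join(letters[rng.integers(0, len(letters), length)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210712)


@pytest.fixture
def toy_proteome() -> list[str]:
    return [
        "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
        "CCAAAACC",
        "MSLLTEVETPIRNEWGCRCNDSSDPLVVAASIIGIVHLILWIIDRL",
    ]
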