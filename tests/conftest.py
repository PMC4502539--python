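import numpy as np
import pytest

from stretchmotif.io import MemeMotifRecord
from stretchmotif.motifs import PWM
from stretchmotif.simulate import SyntheticConfig, generate_dataset

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def consensus_matrix(consensus: str, prob: float = 1.0) -> np.ndarray:
    """One PWM row per consensus base with ``prob`` on the consensus base."""
    off = (1.0 - prob) / 3.0
    mat = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        mat[i, _BASE_IDX[b]] = prob
    return mat


def make_pwm(consensus: str, prob: float = 1.0, name: str = "toy",
             background=UNIFORM_BG, pseudocount: float = 1e-3) -> PWM:
    return PWM(
        name=name,
        matrix=consensus_matrix(consensus, prob),
        background=np.asarray(background, dtype=float),
        pseudocount=pseudocount,
    )


def make_record(consensus: str, prob: float = 1.0, name: str = "toy",
                background=UNIFORM_BG) -> MemeMotifRecord:
    return MemeMotifRecord(
        name=name,
        width=len(consensus),
        matrix=consensus_matrix(consensus, prob),
        nsites=20,
        background=np.asarray(background, dtype=float),
    )


@pytest.fixture(scope="session")
def dataset():
    """One default-config corpus shared by the unit tests (seed 3)."""
    return generate_dataset(SyntheticConfig(seed=3), with_gwas=True, with_signal=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
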