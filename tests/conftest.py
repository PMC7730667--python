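from __future__ import annotations

import numpy as np
import pytest

from symptomnet.data_model import SymptomCodebook
from symptomnet.synthetic_data import IsingModelSpec, sample


def make_codebook(p: int) -> SymptomCodebook:
    return SymptomCodebook(tuple((f"N{i}", f"node {i}") for i in range(p)))


@pytest.fixture(scope="session")
def codebook9() -> SymptomCodebook:
    return SymptomCodebook.default()


@pytest.fixture(scope="session")
def chain_spec(codebook9) -> IsingModelSpec:
    """Planted 9-node chain: couplings 1.2 along consecutive symptoms,
    thresholds -1."""
    p = 9
    beta = np.zeros((p, p))
    for j in range(p - 1):
        beta[j, j + 1] = beta[j + 1, j] = 1.2
    return IsingModelSpec(np.full(p, -1.0), beta, codebook9)


@pytest.fixture(scope="session")
def chain_sample(chain_spec):
    """n = 5000 exact draws from the planted chain, fixed seed."""
    return sample(chain_spec, 5000, seed=7)
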