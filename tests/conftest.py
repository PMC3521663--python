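import numpy as np
import pytest

from promtune import EnergyMatrix, PromoterSequence
from promtune.synth import generate_random_genome, generate_toy_matrix


@pytest.fixture
def toy2_matrix() -> EnergyMatrix:
    """Width-2 matrix: eps(A, pos -2) = 0.5, eps(C, pos -1) = -1.0, rest 0."""
    return EnergyMatrix(
        entries=np.array([[0.5, 0.0, 0.0, 0.0], [0.0, -1.0, 0.0, 0.0]]),
        units="AU",
    )


@pytest.fixture
def calibrated_toy_matrix() -> EnergyMatrix:
    """Small random matrix already on the calibrated (kBT, genome-zeroed) scale."""
    return generate_toy_matrix(seed=7, width=41)


@pytest.fixture
def random_genome() -> str:
    return generate_random_genome(seed=11, length=2000)


@pytest.fixture
def wt_like_start() -> PromoterSequence:
    from promtune import WT_LAC_PROMOTER

    return PromoterSequence(WT_LAC_PROMOTER, id="wt_lac")
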