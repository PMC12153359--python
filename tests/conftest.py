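import numpy as np
import pandas as pd
import pytest

from virorules import MiningConfig, PresenceAbsenceMatrix


@pytest.fixture
def toy_matrix() -> PresenceAbsenceMatrix:
    """10 strains: virus A present in strains 1-5, virus B in strains 1-4."""
    return PresenceAbsenceMatrix(
        pd.DataFrame(
            {"A": [1] * 5 + [0] * 5, "B": [1] * 4 + [0] * 6},
            index=[f"s{i + 1}" for i in range(10)],
        )
    )


@pytest.fixture
def toy_config() -> MiningConfig:
    """No thresholds; probabilities over all 10 strains."""
    return MiningConfig(min_support=0.0, min_confidence=0.0,
                        include_virus_free_strains=True)


def make_random_matrix(rng: np.random.Generator, n_strains: int, n_viruses: int
                       ) -> PresenceAbsenceMatrix:
    prev = rng.uniform(0.05, 0.95, size=n_viruses)
    vals = (rng.random((n_strains, n_viruses)) < prev).astype(np.int8)
    return PresenceAbsenceMatrix(
        pd.DataFrame(vals, index=[f"s{i}" for i in range(n_strains)],
                     columns=[f"V{j:02d}" for j in range(n_viruses)])
    )
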