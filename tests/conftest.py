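import numpy as np
import pytest

from sgaclock.cohort import CohortConfig, simulate_individual
from sgaclock.matrix import Character, SgaMatrix


@pytest.fixture(scope="session")
def small_individual():
    """One simulated individual with probe signals (shared, read-only)."""
    cfg = CohortConfig(
        n_probes=30_000, n_biopsies=6, n_timepoints=3, followup_years=8.0,
        n_off_timepoints=2, lam_off=1.5, lam_on=0.3, mixture_prob=0.0,
    )
    return simulate_individual(cfg, seed=11, with_signals=True)


@pytest.fixture(scope="session")
def default_individual():
    """Individual under the default study conditions (no signals)."""
    return simulate_individual(CohortConfig(), seed=7)


@pytest.fixture()
def worked_matrix():
    """The 4-biopsy / 4-character example: biopsy 1 carries {a,b},
    2 carries {a,b,c}, 3 carries {c,d}, 4 carries {d}."""
    chars = [Character("chr1", 10 * j, 10 * j + 5, "") for j in range(4)]
    data = np.array(
        [[1, 1, 0, 0],
         [1, 1, 1, 0],
         [0, 0, 1, 1],
         [0, 0, 0, 1]], dtype=np.uint8,
    )
    return SgaMatrix(["1", "2", "3", "4"], chars, data)
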