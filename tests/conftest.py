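import warnings

import numpy as np
import pytest

from vibronic import synthetic


@pytest.fixture(scope="session")
def hcn_tables():
    """Published HCN neutral/anionic mode tables (load-time rounding
    warning on the anionic C-H row silenced here)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.table1_hcn()


@pytest.fixture(scope="session")
def diatomic_pair():
    """Homonuclear displaced diatomic with closed-form Huang-Rhys factor."""
    return synthetic.make_displaced_diatomic(1.0, 1.0, 1000.0, 0.1)


@pytest.fixture(scope="session")
def polyatomic_pair():
    """Seeded 4-atom pair constructed to recover prescribed per-mode S."""
    s_targets = np.array([0.1, 0.4, 0.9, 1.6, 2.5, 0.3])
    neutral, anion = synthetic.make_random_polyatomic(4, 2024, s_targets)
    return neutral, anion, s_targets
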