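import numpy as np
import pytest

import strucpower as sp


@pytest.fixture(scope="session")
def two_pop():
    """Two isolated populations (F=0.01), 100+100 samples, 20k null SNPs."""
    model = sp.IsolatedPairModel(0.01, 100, 100)
    panel, design, truth = sp.simulate_null_snps(model, 20_000, seed=42)
    return {
        "model": model,
        "panel": panel,
        "design": design,
        "truth": truth,
        "k_true": sp.kinship_isolated_pair(model),
    }


@pytest.fixture
def small_design():
    return sp.StudyDesign(np.array([1, 1, 1, 1, 0, 0, 0, 0]))
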