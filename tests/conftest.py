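import numpy as np
import pandas as pd
import pytest

from lipidflow.containers import LipidMatrix
from lipidflow.simulate import ModuleSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (44 case / 20 control, 729 lipids)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for stages that do not need the full lipid panel."""
    cfg = SimConfig(
        n_case=44, n_ctrl=20, n_lipids=120,
        modules=[ModuleSpec(20, 0.8, 0.8), ModuleSpec(15, 0.7, 0.3)],
        effect_lipids=[(50 + i, -1.0) for i in range(5)],
        causal_chain=[60, 61], causal_coefficients=[0.8, 1.0],
        missing_rate=0.0, seed=21)
    return simulate_cohort(cfg)


def toy_matrix(values, lipid_ids=None, sample_ids=None, scale_state="log"):
    """Wrap a plain array as a LipidMatrix with dummy annotations."""
    values = np.asarray(values, dtype=float)
    lipid_ids = lipid_ids or [f"L{j}" for j in range(values.shape[1])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=sample_ids, columns=lipid_ids)
    classes = pd.Series("PC", index=df.columns)
    return LipidMatrix(values=df, lipid_classes=classes, scale_state=scale_state)
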