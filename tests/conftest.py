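import numpy as np
import pandas as pd
import pytest

from kinact import ArraySimConfig, PreprocessConfig, preprocess_experiment, simulate_array


@pytest.fixture
def balanced_array():
    """Small balanced array experiment (10+10 HER2- samples, one driver)."""
    cfg = ArraySimConfig(
        seed=11,
        n_samples=20,
        pr_pos_frac=0.5,
        her2_neg_frac=1.0,
        n_kinases=10,
        driver_kinases={"DRV1": 1.5},
    )
    exp, annot, truth = simulate_array(cfg)
    return exp, annot, truth


@pytest.fixture
def collapsed_matrix(balanced_array):
    exp, annot, truth = balanced_array
    matrix = preprocess_experiment(exp, PreprocessConfig())
    return matrix, annot, truth


@pytest.fixture
def toy_annotation():
    """Six samples, 3 PR- / 3 PR+, all ER+/HER2-."""
    return pd.DataFrame(
        {
            "er": ["pos"] * 6,
            "pr": ["neg", "neg", "neg", "pos", "pos", "pos"],
            "her2": ["neg"] * 6,
        },
        index=pd.Index([f"S{i}" for i in range(1, 7)], name="sample_id"),
    )


def make_matrix(values, peptides=None, samples=None):
    values = np.asarray(values, dtype=float)
    peptides = peptides or [f"PEP{i + 1:03d}_1_13" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=peptides, columns=samples)
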