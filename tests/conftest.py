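import numpy as np
import pandas as pd
import pytest

from mirpath import ExpressionDataset, SyntheticConfig, generate_cohort


def make_dataset(values, feature_ids, n_disease, n_control):
    """Small helper: build an ExpressionDataset from a plain array."""
    values = np.asarray(values, dtype=float)
    samples = [f"D{i}" for i in range(n_disease)] + [f"C{i}" for i in range(n_control)]
    phenotype = pd.Series(["disease"] * n_disease + ["control"] * n_control, index=samples)
    return ExpressionDataset(
        values=pd.DataFrame(values, index=feature_ids, columns=samples), phenotype=phenotype
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted structure at all."""
    cfg = SyntheticConfig(seed=7, frac_dysregulated_pathways=0.0, corr_strength=0.0, n_planted_im=0)
    return generate_cohort(cfg)
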