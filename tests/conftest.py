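import numpy as np
import pandas as pd
import pytest

from brafsig import (
    CohortSpec,
    ExpressionMatrix,
    align_to_signature,
    generate_cohort,
    make_signature,
    run_loocv,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with hand-readable values."""
    df = pd.DataFrame(
        [[1.0, 2.0], [3.5, -1.25], [0.0, 4.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2"],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def signature58():
    return make_signature(58)


@pytest.fixture(scope="session")
def small_cohort(signature58):
    """120-sample synthetic cohort aligned to the signature, with labels."""
    matrix, annotations, truth = generate_cohort(CohortSpec(n_samples=120, seed=7))
    aligned = align_to_signature(matrix, signature58)
    labels = annotations["braf_status"].to_numpy()
    return aligned, annotations, labels, truth


@pytest.fixture(scope="session")
def small_loocv(small_cohort):
    aligned, _, labels, _ = small_cohort
    return run_loocv(aligned, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
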