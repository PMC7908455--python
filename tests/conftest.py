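"""Shared fixtures: the bundled case-study inputs and small helpers."""

import numpy as np
import pytest

from swotahp import (
    bundled_example_path,
    load_config,
    validate_comparison_matrix,
)

# Case-study comparison matrices (Saaty judgments) and 0-5 strengths for the
# four SWOT groups of the bundled home-based-exercise analysis.
CASE_MATRICES = {
    "S": [[1, 2, 4, 5], ["1/2", 1, 3, 4], ["1/4", "1/3", 1, 2], ["1/5", "1/4", "1/2", 1]],
    "W": [[1, 2, "1/4"], ["1/2", 1, "1/3"], [4, 3, 1]],
    "O": [[1, 3, "1/4"], ["1/3", 1, "1/6"], [4, 6, 1]],
    "T": [[1, "1/3", "1/4"], [3, 1, "1/2"], [4, 2, 1]],
}
CASE_STRENGTHS = {"S": [5, 4, 3, 2], "W": [3, 2, 4], "O": [3, 2, 5], "T": [1, 3, 4]}


@pytest.fixture(scope="session")
def case_matrices():
    return {
        key: validate_comparison_matrix(rows, labels=[f"{key}{i+1}" for i in range(len(rows))])
        for key, rows in CASE_MATRICES.items()
    }


@pytest.fixture(scope="session")
def case_strengths():
    return dict(CASE_STRENGTHS)

@pytest.fixture(scope="session")
def case_config():
    return load_config(bundled_example_path())


def principal_eigen_weights(values: np.ndarray) -> np.ndarray:
    """Independent oracle: normalized principal eigenvector via numpy.linalg.eig."""
    vals, vecs = np.linalg.eig(values)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    return v / v.sum()


def principal_eigenvalue(values: np.ndarray) -> float:
    """Independent oracle: exact principal eigenvalue."""
    return float(np.max(np.linalg.eigvals(values).real))
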