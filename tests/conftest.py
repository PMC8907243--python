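import numpy as np
import pandas as pd
import pytest

from secdrug import DoseResponseMatrix, SimTruth, simulate_response_matrix


@pytest.fixture
def toy_matrix():
    """3 drugs x 4 lines with one missing entry (drug A, line c3)."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, np.nan], [0.5, 0.1, 2.5, 1.5], [-1.0, 0.0, 1.0, 2.0]],
        index=["A", "B", "C"],
        columns=["c1", "c2", "c3", "c4"],
    )
    return DoseResponseMatrix(df)


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "cell_line_id": ["c1", "c2", "c3", "c4", "c5"],
            "target_cell": ["B-cell", "B-cell", "T-cell", "B-cell", "B-cell"],
            "cancer_type": ["blood", "blood", "blood", "solid", "blood"],
            "tissue": ["blood", "Blood ", "blood", "lung", "blood"],
            "histology": ["lymphoid_neoplasm"] * 5,
            "site": ["haematopoietic_and_lymphoid_tissue"] * 5,
        }
    ).set_index("cell_line_id", drop=False)


@pytest.fixture(scope="session")
def planted_94():
    """94-line, 30-drug simulated panel with the default 2-drug planted combo."""
    truth = SimTruth(seed=1, effect_size=3.0)
    m, meta, truth = simulate_response_matrix(94, 30, truth)
    return m, meta, truth
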