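import numpy as np
import pytest

from gliomaquant.stats import ContingencyTable


@pytest.fixture
def localization_malignancy_counts():
    """pFGFR1 localization (membranous/cytoplasmic/negative) vs malignancy."""
    return np.array([[23, 2], [12, 5], [25, 15]])


@pytest.fixture
def localization_malignancy_table(localization_malignancy_counts):
    return ContingencyTable(
        row_labels=("membranous", "cytoplasmic", "negative"),
        col_labels=("malignant", "benign"),
        counts=localization_malignancy_counts,
    )


@pytest.fixture
def age_expression_counts():
    """Age group vs low/high expression (manual dichotomy, full cohort)."""
    return np.array([[12, 4], [29, 42], [5, 4]])
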