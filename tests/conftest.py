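import numpy as np
import pandas as pd
import pytest

from pidsle.cohort import ExpressionCohort
from pidsle.gene_db import GeneSet, GeneTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_gene_table():
    """Six genes: two Monocyte, one T cell, three untagged; 10 categories."""
    df = pd.DataFrame(
        {
            "symbol": ["A1", "B2", "C3", "D4", "E5", "F6"],
            "functional_category": ["X", "X", "Y", "Y", "Z", "Z"],
            "cell_type_tag": ["Monocyte", "Monocyte", "T cell", None, None, None],
            "is_pid": [True, True, False, False, True, False],
        }
    )
    return GeneTable(df, "toy")


def make_cohort(matrix: np.ndarray, n_group1: int, n_group2: int,
                label1: str = "SLE", label2: str = "control") -> ExpressionCohort:
    genes = [f"G{i:04d}" for i in range(matrix.shape[0])]
    samples = [f"s{j:03d}" for j in range(matrix.shape[1])]
    clinical = pd.DataFrame(
        {"cohort": [label1] * n_group1 + [label2] * n_group2}, index=samples
    )
    return ExpressionCohort(
        pd.DataFrame(matrix, index=genes, columns=samples), clinical
    )


@pytest.fixture
def null_cohort(rng):
    """50 genes x 16 samples of pure noise, 8 vs 8."""
    return make_cohort(rng.normal(7.0, 1.0, size=(50, 16)), 8, 8)
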