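"""Expression cohort container: log2 matrix + sample labels + clinical table.

The matrix is genes x samples (rows indexed by symbol, columns by sample
id); the clinical table is indexed by sample id and carries at least a
``cohort`` column ({SLE, control}) and, when simulated or supplied, the
activity traits: sledai, anti_dsdna (IU), c3 (g/L), c4 (g/L) and the
derived ``activity_class`` ({active, inactive}, threshold SLEDAI >= 6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionCohort", "SLEDAI_ACTIVE_THRESHOLD", "activity_class"]

SLEDAI_ACTIVE_THRESHOLD = 6

CLINICAL_TRAITS = ["sledai", "anti_dsdna", "c3", "c4"]


def activity_class(sledai: "pd.Series | np.ndarray | int") -> "pd.Series | np.ndarray | str":
    """active iff SLEDAI >= 6; a pure function of the score."""
    if np.isscalar(sledai):
        return "active" if sledai >= SLEDAI_ACTIVE_THRESHOLD else "inactive"
    arr = np.asarray(sledai)
    out = np.where(arr >= SLEDAI_ACTIVE_THRESHOLD, "active", "inactive")
    if isinstance(sledai, pd.Series):
        return pd.Series(out, index=sledai.index)
    return out


@dataclass
class ExpressionCohort:
    """Log2 expression matrix with aligned sample metadata."""

    matrix: pd.DataFrame  # genes x samples
    clinical: pd.DataFrame  # samples x clinical columns (incl. 'cohort')
    name: str = "cohort"

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.clinical.index):
            # allow same set in different order
            if set(self.matrix.columns) != set(self.clinical.index):
                raise ValueError("matrix columns and clinical index disagree")
            self.clinical = self.clinical.loc[self.matrix.columns]
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if "cohort" not in self.clinical.columns:
            raise ValueError("clinical table requires a 'cohort' column")

    @property
    def genes(self) -> list[str]:
        return self.matrix.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.matrix.columns.tolist()

    def group_samples(self, label: str, column: str | None = None) -> list[str]:
        """Sample ids whose cohort (or activity_class) equals ``label``."""
        if column is None:
            column = "cohort" if label in set(self.clinical["cohort"]) else "activity_class"
        return self.clinical.index[self.clinical[column] == label].tolist()

    def write(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        self.matrix.to_csv(matrix_path, sep="\t", index_label="symbol")
        self.clinical.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(
        cls,
        matrix_path: str | Path,
        samples_path: str | Path,
        name: str | None = None,
    ) -> "ExpressionCohort":
        matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
        clinical = pd.read_csv(samples_path, sep="\t", index_col=0)
        clinical.index = clinical.index.astype(str)
        matrix.columns = matrix.columns.astype(str)
        return cls(matrix=matrix, clinical=clinical,
                   name=name or Path(matrix_path).stem)
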