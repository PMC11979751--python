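"""Core genes-by-observations expression container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE_SPACES = ("logTPM", "TPM")


@dataclass
class ExpressionMatrix:
    """Expression values with genes as rows and observations as columns.

    Parameters
    ----------
    values
        Numeric data frame indexed by unique gene identifiers, with unique
        observation identifiers as columns.
    space
        Value space of the entries, either ``"logTPM"`` (log2(TPM+1)) or
        ``"TPM"`` (linear).
    """

    values: pd.DataFrame
    space: str = "logTPM"

    def __post_init__(self) -> None:
        if self.space not in VALUE_SPACES:
            raise ValueError(f"space must be one of {VALUE_SPACES}, got {self.space!r}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes[:5])}")
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate observation identifiers: {list(dupes[:5])}")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def observations(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order; error names the first missing gene."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"gene not present in matrix: {missing[0]!r}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), space=self.space)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def log_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); input must be linear TPM with non-negative values."""
    vals = matrix.values.to_numpy()
    if np.any(vals < 0):
        raise ValueError("log_tpm requires non-negative input values")
    out = pd.DataFrame(
        np.log2(vals + 1.0), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(out, space="logTPM")


def unlog_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Exact inverse of :func:`log_tpm`: elementwise 2**x - 1."""
    vals = matrix.values.to_numpy()
    if np.any(vals < 0):
        raise ValueError("unlog_tpm requires non-negative log values")
    out = pd.DataFrame(
        np.exp2(vals) - 1.0, index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(out, space="TPM")
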