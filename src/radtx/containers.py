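"""Shared in-memory containers for expression data.

The expression matrix follows the microarray convention: genes (transcripts)
as rows, samples (one hybridized array per animal) as columns. Non-assessable
reads are carried as NaN throughout; all downstream statistics use pairwise
deletion rather than imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "FoldChangeMatrix"]


def _check_labels(values: pd.DataFrame, arms: pd.Series) -> None:
    if not values.index.is_unique:
        raise ValueError("gene identifiers must be unique")
    if not values.columns.is_unique:
        raise ValueError("sample identifiers must be unique")
    missing_labels = set(values.columns) - set(arms.index)
    if missing_labels:
        raise ValueError(f"samples without arm label: {sorted(missing_labels)}")


@dataclass
class ExpressionMatrix:
    """Gene x sample intensity matrix with arm annotation.

    Parameters
    ----------
    values
        Non-negative intensities; NaN marks a non-assessable read.
    arms
        Maps each sample identifier (column of ``values``) to a treatment
        arm label, e.g. ``control``, ``EndoRT``, ``photon_EBRT``.
    """

    values: pd.DataFrame
    arms: pd.Series

    def __post_init__(self) -> None:
        _check_labels(self.values, self.arms)
        self.arms = self.arms.loc[self.values.columns]
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("intensities must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_arm(self, arm: str) -> list[str]:
        return list(self.arms.index[self.arms == arm])

    def arm_order(self) -> list[str]:
        """Arms in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for a in self.arms:
            seen.setdefault(a, None)
        return list(seen)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.arms)


@dataclass
class FoldChangeMatrix:
    """Per-gene ratios to the control-arm arithmetic mean.

    ``log2=True`` records that values are log2 ratios (0 = no change);
    otherwise values are raw ratios (1 = no change, all positive).
    """

    values: pd.DataFrame
    arms: pd.Series
    log2: bool = True
    control_arm: str | None = field(default=None)

    def __post_init__(self) -> None:
        _check_labels(self.values, self.arms)
        self.arms = self.arms.loc[self.values.columns]
        if not self.log2:
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() <= 0).any():
                    raise ValueError("raw fold-change values must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_arm(self, arm: str) -> list[str]:
        return list(self.arms.index[self.arms == arm])

    def arm_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.arms:
            seen.setdefault(a, None)
        return list(seen)

    def arm_means(self, genes=None) -> pd.DataFrame:
        """Per-gene mean profile over arms (pairwise deletion of NaN)."""
        vals = self.values if genes is None else self.values.loc[genes]
        return vals.T.groupby(self.arms).mean().T[self.arm_order()]
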