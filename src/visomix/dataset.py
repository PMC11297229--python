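"""Shared in-memory container for aligned multi-omics data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OmicsDataset:
    """Aligned methylation + expression matrices with phenotype metadata.

    All frames share the same sample index in the same order. Methylation
    holds beta values in [0, 1]; expression holds nonnegative abundance
    values (e.g. CPM); covariates are numeric (binary factors coded 0/1).
    """

    methylation: pd.DataFrame
    expression: pd.DataFrame
    phenotype: pd.Series
    cohort: pd.Series
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        idx = self.methylation.index
        for name, other in [
            ("expression", self.expression.index),
            ("phenotype", self.phenotype.index),
            ("cohort", self.cohort.index),
        ]:
            if not idx.equals(other):
                raise ValueError(f"{name} index does not match methylation index")
        if len(self.covariates) and not idx.equals(self.covariates.index):
            raise ValueError("covariates index does not match methylation index")
        for name, df in [("methylation", self.methylation), ("expression", self.expression)]:
            if df.isna().any().any():
                raise ValueError(f"{name} contains missing values; complete data required")
        vals = self.methylation.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("methylation beta values must lie in [0, 1]")
        if self.expression.size and self.expression.to_numpy().min() < 0:
            raise ValueError("expression values must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.methylation)

    @property
    def samples(self) -> pd.Index:
        return self.methylation.index

    def subset(self, samples) -> "OmicsDataset":
        """Row-subset by sample ids or boolean/positional index."""
        if isinstance(samples, (np.ndarray, list)) and len(samples) and not isinstance(
            samples[0], str
        ):
            samples = self.samples[np.asarray(samples)]
        return OmicsDataset(
            methylation=self.methylation.loc[samples],
            expression=self.expression.loc[samples],
            phenotype=self.phenotype.loc[samples],
            cohort=self.cohort.loc[samples],
            covariates=self.covariates.loc[samples] if len(self.covariates) else self.covariates,
        )
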