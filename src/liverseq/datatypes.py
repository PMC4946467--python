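"""Core containers shared across the pipeline.

A :class:`CountMatrix` couples a gene x sample integer count table with the
sample metadata needed by every downstream stage (donor, group, timepoint,
batch).  Result containers are plain dataclasses wrapping pandas objects so
they serialize to TSV without ceremony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("PRE", "DBD", "DCD")
TIMEPOINTS = ("pre", "0h", "3h", "6h")

META_COLUMNS = ["donor_id", "group", "timepoint", "batch"]


@dataclass
class CountMatrix:
    """Gene x sample read counts plus aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id;
        entries are nonnegative integers.
    meta
        DataFrame indexed by sample id with columns ``donor_id``,
        ``group`` (PRE/DBD/DCD), ``timepoint`` (pre/0h/3h/6h), ``batch``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("count columns and metadata rows must align")
        if not self.meta.index.is_unique:
            raise ValueError("sample ids must be unique")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if vals.size and not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        bad_group = ~self.meta["group"].isin(GROUPS)
        if bad_group.any():
            raise ValueError(f"unknown group labels: {set(self.meta.loc[bad_group, 'group'])}")
        # PRE group <=> 'pre' timepoint, both directions
        pre_mask = self.meta["group"] == "PRE"
        if not (self.meta.loc[pre_mask, "timepoint"] == "pre").all():
            raise ValueError("PRE samples must carry timepoint 'pre'")
        if (self.meta.loc[~pre_mask, "timepoint"] == "pre").any():
            raise ValueError("timepoint 'pre' is reserved for the PRE group")
        dup = self.meta.duplicated(subset=["donor_id", "timepoint"])
        if dup.any():
            raise ValueError("each (donor, timepoint) pair may appear at most once")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.meta.loc[sample_ids])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.meta)


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors and library sizes; factors have geometric mean 1."""

    factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


@dataclass
class BatchModel:
    """Fitted location/scale batch model on the log2 scale.

    ``gamma`` and ``delta2`` are batch x gene DataFrames holding the
    empirical-Bayes shrunken location shifts (log2 units) and squared
    scale factors applied during adjustment.  ``grand_mean`` and
    ``pooled_var`` are the per-gene standardization parameters.
    """

    gamma: pd.DataFrame
    delta2: pd.DataFrame
    grand_mean: pd.Series
    pooled_var: pd.Series

    @classmethod
    def identity(cls, genes: pd.Index, batches) -> "BatchModel":
        zeros = pd.DataFrame(0.0, index=pd.Index(batches, name="batch"), columns=genes)
        ones = pd.DataFrame(1.0, index=pd.Index(batches, name="batch"), columns=genes)
        return cls(gamma=zeros, delta2=ones,
                   grand_mean=pd.Series(0.0, index=genes),
                   pooled_var=pd.Series(1.0, index=genes))


@dataclass
class GeneSetCall:
    """DE calls per branch and the DCD-specific partition by direction."""

    de_dcd: pd.Series  # gene -> direction ('up'/'down')
    de_dbd: pd.Series
    dcd_specific_up: list = field(default_factory=list)
    dcd_specific_down: list = field(default_factory=list)

    @property
    def dcd_specific(self) -> set:
        return set(self.dcd_specific_up) | set(self.dcd_specific_down)
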