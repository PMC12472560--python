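"""Core in-memory containers shared across the pipeline.

The central object is :class:`AsvTable`, an integer count matrix of amplicon
sequence variants (taxa, rows) by samples (columns).  Sample metadata, taxonomy
and guild references are plain :class:`pandas.DataFrame` objects with fixed
column names; helpers here validate their shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("myconet")

#: The seven guild labels the pipeline recognises.  The first six are trophic
#: modes (and their mixtures) as used for soil fungi; anything a reference
#: cannot place falls into "Unassigned".
GUILDS = (
    "Saprotroph",
    "Symbiotroph",
    "Pathotroph",
    "Pathotroph-Saprotroph",
    "Saprotroph-Symbiotroph",
    "Pathotroph-Saprotroph-Symbiotroph",
)
UNASSIGNED = "Unassigned"
GUILD_LABELS = GUILDS + (UNASSIGNED,)


class ValidationError(ValueError):
    """Raised when an input table or design violates a documented invariant."""


@dataclass
class AsvTable:
    """Taxa-by-samples count matrix.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = taxon ids, columns =
        sample ids.  Ids must be unique; retained samples must have positive
        column sums.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)) or np.isnan(arr).any():
                raise ValidationError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at taxon {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        if arr.size and (arr.sum(axis=0) == 0).any():
            empty = c.columns[arr.sum(axis=0) == 0].tolist()
            raise ValidationError(f"samples with zero total counts: {empty}")

    # -- convenience accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "AsvTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return AsvTable(self.counts.loc[:, list(sample_ids)].copy())

    def subset_taxa(self, taxon_ids) -> "AsvTable":
        missing = [t for t in taxon_ids if t not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown taxon ids: {missing}")
        return AsvTable(self.counts.loc[list(taxon_ids), :].copy())


def validate_metadata(metadata: pd.DataFrame, table: AsvTable | None = None) -> pd.DataFrame:
    """Check a sample metadata frame (columns: sample_id, treatment).

    When *table* is given, every sample in the table must appear exactly once.
    """
    for col in ("sample_id", "treatment"):
        if col not in metadata.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    if metadata["sample_id"].duplicated().any():
        dups = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    if table is not None:
        missing = set(table.sample_ids) - set(metadata["sample_id"])
        if missing:
            raise ValidationError(f"samples absent from metadata: {sorted(missing)}")
    return metadata


def groups_of(metadata: pd.DataFrame) -> dict[str, list[str]]:
    """Treatment label -> ordered list of sample ids (metadata order kept)."""
    out: dict[str, list[str]] = {}
    for _, row in metadata.iterrows():
        out.setdefault(row["treatment"], []).append(row["sample_id"])
    return out
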