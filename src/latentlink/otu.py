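"""Taxon x sample count tables (OTU tables) and the singleton filter.

An OTU table holds nonnegative integer read counts with one row per taxon
(identified by a semicolon-delimited taxonomy string) and one column per
sample.  Before co-occurrence analysis, *global singletons* -- taxa whose
total count across every sample equals exactly 1 -- are removed, as is
standard for amplicon surveys where such reads are indistinguishable from
sequencing error.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["OTUTable", "filter_singletons"]


@dataclass
class OTUTable:
    counts: np.ndarray                 # (n_taxa, n_samples), nonnegative ints
    taxonomy: Sequence[str]
    sample_ids: Sequence[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d taxa x samples array")
        if self.counts.size and (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.taxonomy = list(self.taxonomy)
        self.sample_ids = list(self.sample_ids)
        if len(self.taxonomy) != self.counts.shape[0]:
            raise ValueError("taxonomy length must equal the number of taxa")
        if any(not t for t in self.taxonomy):
            raise ValueError("taxonomy strings must be non-empty")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids length must equal the number of samples")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative frequencies (columns sum to 1)."""
        colsum = self.counts.sum(axis=0).astype(float)
        if (colsum == 0).any():
            raise ValueError("cannot normalize: some sample has zero total count")
        return self.counts / colsum

    def select(self, rows: np.ndarray) -> "OTUTable":
        rows = np.asarray(rows)
        meta = {
            k: (np.asarray(v)[rows] if np.ndim(v) and len(v) == self.n_taxa else v)
            for k, v in self.metadata.items()
        }
        return OTUTable(
            self.counts[rows],
            [self.taxonomy[int(r)] for r in np.flatnonzero(rows)] if rows.dtype == bool
            else [self.taxonomy[int(r)] for r in rows],
            list(self.sample_ids),
            metadata=meta,
        )


def filter_singletons(table: OTUTable) -> tuple[OTUTable, int]:
    """Remove global singletons (total count across all samples == 1).

    Returns the filtered table and the number of taxa removed.  Taxa with a
    total of 0 or >= 2 are retained.
    """
    if table.n_taxa == 0:
        raise ValueError("empty OTU table")
    keep = table.total_counts() != 1
    removed = int((~keep).sum())
    return table.select(keep), removed
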