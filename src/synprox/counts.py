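"""Spectral-count tables for bait-vs-control proximity-labeling experiments.

A :class:`SpectralCountTable` holds one protein x sample matrix of MS/MS
spectral counts, with each sample labeled as *bait* (ligase-fusion condition)
or *control* (no ligase). It is the unit of the proteomics arm: enrichment
ratios and interaction scores are computed per protein from the bait and
control replicate columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BAIT = "bait"
CONTROL = "control"


@dataclass
class SpectralCountTable:
    """Protein x sample spectral-count matrix with condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by unique ``protein_id`` with one integer column
        per sample.
    conditions
        Mapping of each column name to ``"bait"`` or ``"control"``.
    gene_symbols
        Optional ``protein_id -> gene symbol`` mapping.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]
    gene_symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate protein_id: {dup!r}")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        bad = {c for c, v in self.conditions.items() if v not in (BAIT, CONTROL)}
        if bad:
            raise ValueError(f"conditions must be 'bait' or 'control': {sorted(bad)}")
        if not self.bait_columns or not self.control_columns:
            raise ValueError("need at least one bait and one control sample")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def bait_columns(self) -> list[str]:
        return [c for c in self.counts.columns if self.conditions[c] == BAIT]

    @property
    def control_columns(self) -> list[str]:
        return [c for c in self.counts.columns if self.conditions[c] == CONTROL]

    @property
    def protein_ids(self) -> pd.Index:
        return self.counts.index

    def bait_matrix(self) -> np.ndarray:
        """Counts of the bait replicates, shape (n_proteins, n_bait_reps)."""
        return self.counts[self.bait_columns].to_numpy()

    def control_matrix(self) -> np.ndarray:
        """Counts of the control replicates, shape (n_proteins, n_ctrl_reps)."""
        return self.counts[self.control_columns].to_numpy()

    def __len__(self) -> int:
        return len(self.counts)

    def equals(self, other: "SpectralCountTable") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.conditions == other.conditions
            and self.gene_symbols == other.gene_symbols
        )
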