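"""Gene-by-cell expression container shared across pipeline stages.

Counts are kept genes-as-rows, cells-as-columns in every text format and in
memory; derived normalizations (RPM, size-factor normalized) live in named
layers alongside the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class ExpressionMatrix:
    """A genes × cells count matrix with optional normalization layers.

    Parameters
    ----------
    counts
        Raw (non-negative) counts, genes as rows, cells as columns.
    layers
        Named transformed matrices with the same shape and labels as
        ``counts`` (e.g. ``"rpm"``, ``"norm"``).
    cell_meta
        Per-cell annotations indexed by cell id (protein-panel booleans,
        class labels, ...). May be empty.
    """

    counts: pd.DataFrame
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("expression counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def layer(self, name: str) -> pd.DataFrame:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(
                f"layer {name!r} not present; available: {sorted(self.layers)}"
            ) from None

    def genes_detected_per_cell(self) -> pd.Series:
        """Number of genes with count > 0 in each cell."""
        return (self.counts > 0).sum(axis=0)
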