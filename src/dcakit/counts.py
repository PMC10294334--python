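"""The sample-by-cell-type count table, the central observed datum."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class CellCountTable:
    """Integer cell counts per (sample, cell type).

    Rows are samples, columns cell types; ``totals`` are the per-sample
    row sums (the number of cells captured for that sample).
    """

    sample_ids: list[str]
    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.sample_ids), len(self.labels)):
            raise ValidationError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.labels)} cell types"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate cell-type labels")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if np.any(arr < 0):
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"cell type {self.labels[bad[1]]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        self.counts = np.round(arr).astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellCountTable":
        """Build from a DataFrame indexed by sample with cell-type columns."""
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.labels,
        )

    def select_samples(self, idx: Sequence[int]) -> "CellCountTable":
        idx = list(idx)
        return CellCountTable(
            [self.sample_ids[i] for i in idx], self.labels, self.counts[idx]
        )


def counts_from_cells(
    cells: pd.DataFrame, label_order: Sequence[str] | None = None
) -> CellCountTable:
    """Cross-tabulate a cell-level metadata table into a count table.

    ``cells`` needs columns ``cell_id``, ``sample_id`` and ``cluster``;
    cell types are ordered lexicographically unless ``label_order`` is
    given, and absent (sample, type) pairs get explicit zeros.
    """
    required = {"cell_id", "sample_id", "cluster"}
    missing = required - set(cells.columns)
    if missing:
        raise ValidationError(f"cell metadata missing columns {sorted(missing)}")
    if cells.empty:
        raise ValidationError("cell metadata table is empty")
    dup = cells["cell_id"][cells["cell_id"].duplicated()].unique()
    if dup.size:
        raise ValidationError(f"duplicate cell ids: {dup[:10].tolist()}")
    tab = pd.crosstab(cells["sample_id"].astype(str), cells["cluster"].astype(str))
    if label_order is not None:
        unknown = set(label_order) ^ set(tab.columns)
        if unknown:
            raise ValidationError(
                f"label_order does not match observed clusters: {sorted(unknown)}"
            )
        tab = tab[list(label_order)]
    else:
        tab = tab[sorted(tab.columns)]
    return CellCountTable.from_frame(tab)
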