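"""Library QC and log-CPM normalization.

A cell library passes QC when it expresses at least ``min_expressed``
transcripts, where "expressed" means strictly more than ``min_reads`` reads
(defaults 1000 and 2).  Retained counts are converted to log2(CPM +
pseudocount); with the default pseudocount of 1 a zero count maps to 0 and
all values are non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import CountMatrix


class EmptyOutputError(ValueError):
    """All cells were discarded by a filter."""


@dataclass
class QCReport:
    """Per-cell QC outcome: expressed-transcript count and keep/discard flag."""

    table: pd.DataFrame  # index cell_id; columns: expressed, kept
    min_expressed: int
    min_reads: int

    @property
    def kept_cells(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])

    @property
    def discarded_cells(self) -> list[str]:
        return list(self.table.index[~self.table["kept"]])


@dataclass
class ExpressionMatrix:
    """Gene x cell log-transformed counts-per-million values.

    ``values[g, c] = log(count/total * 1e6 + pseudocount)`` in base ``base``
    (default 2).
    """

    values: pd.DataFrame
    pseudocount: float = 1.0
    base: float = 2.0
    qc: QCReport | None = None
    regions: pd.Series | None = None  # cell -> axial region label

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    def cpm(self) -> pd.DataFrame:
        """Back-transform to the linear CPM scale."""
        return self.base ** self.values - self.pseudocount

    def subset_cells(self, cells) -> "ExpressionMatrix":
        cells = list(cells)
        return ExpressionMatrix(
            values=self.values[cells],
            pseudocount=self.pseudocount,
            base=self.base,
            qc=self.qc,
            regions=None if self.regions is None else self.regions.loc[cells],
        )


def filter_cells(
    cm: CountMatrix,
    min_expressed: int = 1000,
    min_reads: int = 2,
) -> tuple[CountMatrix, QCReport]:
    """Discard cell libraries with fewer than ``min_expressed`` expressed genes.

    A gene counts as expressed in a cell when its read count is strictly
    greater than ``min_reads``.  A cell with exactly ``min_expressed``
    expressed genes is kept (the discard rule is "fewer than").
    """
    if min_expressed < 0 or min_reads < 0:
        raise ValueError("thresholds must be non-negative")
    expressed = (cm.counts.to_numpy() > min_reads).sum(axis=0)
    kept = expressed >= min_expressed
    report = QCReport(
        table=pd.DataFrame(
            {"expressed": expressed, "kept": kept}, index=cm.cell_ids
        ),
        min_expressed=min_expressed,
        min_reads=min_reads,
    )
    if not kept.any():
        raise EmptyOutputError(
            f"all {cm.shape[1]} cells discarded at min_expressed="
            f"{min_expressed}, min_reads={min_reads}"
        )
    keep_ids = list(cm.cell_ids[kept])
    return cm.subset_cells(keep_ids), report


def to_log_cpm(
    cm: CountMatrix,
    pseudocount: float = 1.0,
    base: float = 2.0,
    qc: QCReport | None = None,
) -> ExpressionMatrix:
    """Convert raw counts to log(CPM + pseudocount)."""
    totals = cm.counts.to_numpy().sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = cm.cell_ids[np.where(totals == 0)[0][0]]
        raise ValueError(
            f"cell {bad!r} has zero total counts; run filter_cells first"
        )
    cpm = cm.counts.to_numpy() / totals[None, :] * 1e6
    values = np.log(cpm + pseudocount) / math.log(base)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=cm.gene_ids, columns=cm.cell_ids),
        pseudocount=pseudocount,
        base=base,
        qc=qc,
        regions=cm.regions.copy(),
    )
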