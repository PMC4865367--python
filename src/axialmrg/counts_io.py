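"""Count-matrix containers, readers/writers, and transcript-level preprocessing.

Raw data are gene-by-cell integer count matrices with per-cell metadata giving
the axial region of origin (1 = anterior tip .. n_regions = posterior tip).
Two preprocessing steps operate at the transcript level, before any
normalization: collapsing counts of transcripts belonging to the same isotig
group, and discarding reads from an exclusion list of rRNA/mitochondrial
transcripts so that they never enter the counts-per-million denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class CountMatrix:
    """Gene x cell raw integer counts with per-cell region metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = gene IDs, columns = cell IDs.
    cell_meta : pandas.DataFrame
        Indexed by cell ID; must contain a ``region`` column with integer
        region labels in ``1..n_regions``; may carry an optional ``cell_class``
        column.
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate cell ID: {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = self.counts.index[np.where(vals != np.round(vals))[0][0]]
                raise FormatError(f"non-integer count in gene {bad!r}")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = self.counts.index[np.where((vals < 0).any(axis=1))[0][0]]
            raise FormatError(f"negative count in gene {bad!r}")
        if "region" not in self.cell_meta.columns:
            raise FormatError("cell metadata lacks a 'region' column")
        missing = self.counts.columns.difference(self.cell_meta.index)
        if len(missing):
            raise FormatError(f"cells without metadata: {list(missing)[:5]}")
        self.cell_meta = self.cell_meta.loc[self.counts.columns]
        self.counts.index.name = "gene_id"
        self.counts.columns.name = "cell_id"
        self.cell_meta.index.name = "cell_id"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def regions(self) -> pd.Series:
        return self.cell_meta["region"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_cells(self, cells: Iterable[str]) -> "CountMatrix":
        cells = list(cells)
        return CountMatrix(self.counts[cells], self.cell_meta.loc[cells].copy())


@dataclass
class IsotigMap:
    """Mapping of transcript ID -> isotig group ID.

    Transcripts absent from the map pass through under their own ID; total
    counts are conserved under the collapse.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IsotigMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise FormatError(f"isotig map {path} needs two columns")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def group_of(self, transcript_id: str) -> str:
        return self.mapping.get(transcript_id, transcript_id)


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> CountMatrix:
    """Read a count matrix from MatrixMarket (.mtx) or dense TSV.

    ``genes_path`` and ``cells_path`` are TSVs; the gene file has the gene ID
    in its first column, the cell file must have ``cell_id`` and ``region``
    columns (header required).
    """
    matrix_path = Path(matrix_path)
    genes = pd.read_csv(genes_path, sep="\t", dtype={0: str})
    gene_ids = genes.iloc[:, 0].tolist()
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in cells.columns or "region" not in cells.columns:
        raise FormatError(
            f"{cells_path}: cell metadata must have 'cell_id' and 'region' columns"
        )
    cells = cells.set_index("cell_id")
    cells["region"] = cells["region"].astype(int)

    if matrix_path.suffix == ".mtx":
        mat = np.asarray(spio.mmread(matrix_path).todense())
    else:
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if list(mat.index) != gene_ids:
            absent = set(gene_ids) - set(mat.index)
            if absent:
                raise FormatError(
                    f"{matrix_path}: matrix shape {mat.shape} does not cover "
                    f"the {len(gene_ids)} listed genes (missing e.g. "
                    f"{sorted(absent)[:3]})"
                )
            mat = mat.reindex(gene_ids)
        mat = mat.to_numpy()
    if mat.shape != (len(gene_ids), len(cells)):
        raise FormatError(
            f"{matrix_path}: matrix shape {mat.shape} does not match "
            f"{len(gene_ids)} genes x {len(cells)} cells"
        )
    if not np.allclose(mat, np.round(mat)):
        raise FormatError(f"{matrix_path}: non-integer entries")
    counts = pd.DataFrame(
        mat.astype(np.int64), index=pd.Index(gene_ids, name="gene_id"),
        columns=cells.index,
    )
    return CountMatrix(counts, cells)


def write_counts(cm: CountMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write a CountMatrix as matrix.mtx + genes.tsv + cells.tsv; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "cells": out_dir / "cells.tsv",
    }
    spio.mmwrite(paths["matrix"], sparse.coo_matrix(cm.counts.to_numpy()))
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(
        paths["genes"], sep="\t", index=False
    )
    cm.cell_meta.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        paths["cells"], sep="\t", index=False
    )
    return paths


def collapse_isotigs(cm: CountMatrix, imap: IsotigMap) -> CountMatrix:
    """Sum counts of transcripts sharing an isotig group.

    Output genes are the distinct groups plus unmapped transcripts, in order
    of first appearance; per-cell totals are conserved exactly.
    """
    groups = [imap.group_of(g) for g in cm.gene_ids]
    collapsed = cm.counts.groupby(groups, sort=False).sum()
    collapsed.index.name = "gene_id"
    return CountMatrix(collapsed, cm.cell_meta.copy())


def drop_excluded(cm: CountMatrix, exclude_ids: Iterable[str]) -> CountMatrix:
    """Remove listed gene rows (e.g. rRNA/mitochondrial transcripts).

    Runs before CPM normalization so excluded reads never enter the
    denominator.  IDs absent from the matrix are ignored with a warning;
    removal is logged with the number of reads discarded.
    """
    exclude = list(exclude_ids)
    present = [g for g in exclude if g in cm.gene_ids]
    absent = sorted(set(exclude) - set(present))
    if absent:
        logger.warning("exclusion IDs not in matrix, ignored: %s", absent)
    if not present:
        return CountMatrix(cm.counts.copy(), cm.cell_meta.copy())
    discarded = int(cm.counts.loc[present].to_numpy().sum())
    logger.info(
        "dropping %d excluded transcripts (%d reads discarded)",
        len(present), discarded,
    )
    kept = cm.counts.drop(index=present)
    return CountMatrix(kept, cm.cell_meta.copy())
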