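"""Muscle-cell classification by variable-gene PCA and a marker gate.

Highly expressed, highly variable genes (4 < mean log2-CPM < 8, dispersion
> 1.2) are selected, principal components are fit on their centered,
unit-scaled values and extended to all genes, component significance is
assessed by a per-gene permutation test, and each component's sign is
oriented so that a designated muscle marker loads negatively.  A cell is
called muscle when its oriented PC1 score is negative AND its marker CPM
exceeds the gate threshold (default > 4 CPM, on the linear CPM scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .qc_normalize import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores, extended loadings, variance explained and orientation record."""

    scores: pd.DataFrame  # cell x component
    loadings: pd.DataFrame  # gene (all genes) x component
    variance_explained: np.ndarray
    pc_pvalues: np.ndarray | None = None
    orientation: dict[int, int] | None = None  # component -> sign applied
    variable_genes: list[str] | None = None


@dataclass
class CellAnnotation:
    """Per-cell muscle / non-muscle call with its gate inputs."""

    table: pd.DataFrame  # index cell_id; columns cell_class, marker_cpm, pc1
    marker_id: str
    marker_cpm_min: float

    @property
    def muscle_cells(self) -> list[str]:
        return list(self.table.index[self.table["cell_class"] == "muscle"])


def select_variable_genes(
    em: ExpressionMatrix,
    mean_lo: float = 4.0,
    mean_hi: float = 8.0,
    dispersion_min: float = 1.2,
) -> list[str]:
    """Highly expressed, highly variable genes on log-CPM.

    Selection uses strict inequalities: mean_lo < mean < mean_hi and
    dispersion > dispersion_min, where dispersion = variance / mean of
    log-CPM across cells (zero-mean genes have undefined dispersion and are
    excluded).
    """
    if em.values.shape[1] < 2:
        raise ValueError("need at least two cells")
    vals = em.values.to_numpy()
    means = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(means > 0, var / means, 0.0)
    mask = (means > mean_lo) & (means < mean_hi) & (dispersion > dispersion_min)
    genes = list(em.gene_ids[mask])
    if not genes:
        raise ValueError(
            "no variable genes selected; relax mean/dispersion thresholds"
        )
    return genes


def _standardize(values: np.ndarray) -> np.ndarray:
    """Center and unit-scale each row (gene); constant rows map to 0."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def run_pca(
    em: ExpressionMatrix,
    genes: list[str],
    n_components: int = 2,
    marker_id: str | None = None,
) -> PCAResult:
    """PCA on the variable-gene set, projected onto all genes.

    Components are fit on centered, unit-scaled variable-gene log-CPM
    (cells as observations).  Loadings for the full gene set are obtained by
    projecting every gene's standardized expression onto the unit-norm cell
    scores.  If ``marker_id`` is given, each component is sign-oriented so
    the marker's loading is negative (muscle on the negative side of PC1).
    """
    if len(genes) < n_components:
        raise ValueError("need at least n_components variable genes")
    X = _standardize(em.values.loc[genes].to_numpy())  # genes x cells
    rank = np.linalg.matrix_rank(X)
    if rank < n_components:
        logger.warning(
            "degenerate covariance: rank %d < %d components; reducing",
            rank, n_components,
        )
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.T)  # cells x components
    var_exp = pca.explained_variance_ratio_

    # Extend to all genes: correlation-like projection of standardized rows
    # onto unit-norm score vectors.
    Z_all = _standardize(em.values.to_numpy())
    norms = np.linalg.norm(scores, axis=0)
    norms[norms == 0] = 1.0
    loadings = Z_all @ (scores / norms)

    orientation: dict[int, int] = {}
    if marker_id is not None:
        if marker_id not in em.gene_ids:
            raise ValueError(f"marker {marker_id!r} not in expression matrix")
        mrow = list(em.gene_ids).index(marker_id)
        for j in range(n_components):
            sign = -1 if loadings[mrow, j] > 0 else 1
            orientation[j] = sign
            scores[:, j] *= sign
            loadings[:, j] *= sign

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=em.cell_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=em.gene_ids, columns=comp_names),
        variance_explained=var_exp,
        orientation=orientation or None,
        variable_genes=list(genes),
    )


def pc_significance(
    em: ExpressionMatrix,
    genes: list[str],
    n_components: int = 2,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for each component's variance explained.

    The null distribution is obtained by independently permuting each gene's
    values across cells and refitting; p = (1 + #{null >= observed}) /
    (n_permutations + 1).
    """
    if n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    X = _standardize(em.values.loc[genes].to_numpy())
    n_components = min(n_components, np.linalg.matrix_rank(X))
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X.T)
    observed = pca.explained_variance_ratio_

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_components)
    Xp = X.copy()
    for _ in range(n_permutations):
        for row in Xp:
            rng.shuffle(row)
        pca_null = PCA(n_components=n_components, svd_solver="full")
        pca_null.fit(Xp.T)
        exceed += pca_null.explained_variance_ratio_ >= observed
    return (1.0 + exceed) / (n_permutations + 1.0)


def call_muscle(
    pca: PCAResult,
    em: ExpressionMatrix,
    marker_id: str,
    marker_cpm_min: float = 4.0,
    doublet_quantile: float = 0.99,
) -> CellAnnotation:
    """Gate muscle cells: oriented PC1 < 0 AND marker CPM > threshold.

    The marker gate is applied on the linear CPM scale.  Cells whose
    expressed-transcript count exceeds the ``doublet_quantile`` quantile are
    flagged as putative doublets in the output but not removed.
    """
    if marker_id not in em.gene_ids:
        raise ValueError(f"marker {marker_id!r} not in expression matrix")
    marker_cpm = (
        em.base ** em.values.loc[marker_id] - em.pseudocount
    ).clip(lower=0.0)
    pc1 = pca.scores["PC1"]
    muscle = (pc1 < 0) & (marker_cpm > marker_cpm_min)

    n_detected = (em.values.to_numpy() > 0).sum(axis=0)
    cutoff = np.quantile(n_detected, doublet_quantile)
    table = pd.DataFrame({
        "cell_class": np.where(muscle, "muscle", "non_muscle"),
        "marker_cpm": marker_cpm,
        "pc1": pc1,
        "putative_doublet": n_detected > cutoff,
    }, index=em.cell_ids)
    n_doublet = int(table["putative_doublet"].sum())
    if n_doublet:
        logger.info("%d putative high-complexity doublet(s) flagged", n_doublet)
    return CellAnnotation(
        table=table, marker_id=marker_id, marker_cpm_min=marker_cpm_min
    )
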