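"""Minimum-p combination score across contrasts and ROC evaluation.

Under the null of no regional expression, a gene's minimum p-value across k
independent contrasts, p_(1) = min(p_1, ..., p_k), follows a Beta(1, k)
distribution.  The combination score is

    S_min = -ln( P(Beta(1, k) < p_(1)) ) = -ln( 1 - (1 - p_(1))^k )

which ranks genes (larger = stronger regional signal) but is not itself an
adjusted p-value.  Classification performance of S_min against a binary
validation label is summarized by an ROC curve and its AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics

__all__ = [
    "CombinedScore",
    "ROCResult",
    "s_min_score",
    "s_min",
    "roc_curve",
    "classify_mrgs",
]


@dataclass
class CombinedScore:
    """Per-gene p-vectors, minimum p, S_min and rank (1 = top score)."""

    table: pd.DataFrame  # columns p_1..p_k, p_min, s_min, rank
    k: int


@dataclass
class ROCResult:
    """ROC points (FPR, TPR) from (0,0) to (1,1) and the trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def s_min(p_min, k: int):
    """S_min = -ln(1 - (1 - p_min)^k), stabilized for small p_min.

    Uses the Beta(1, k) CDF 1 - (1 - x)^k via log1p/expm1 so that tiny
    minimum p-values do not underflow the survival term.
    """
    p = np.asarray(p_min, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be at least 1")
    p = np.clip(p, 1e-300, 1.0)
    # cdf = 1 - (1-p)^k = -expm1(k * log1p(-p))
    with np.errstate(divide="ignore"):
        log_cdf = np.log(-np.expm1(k * np.log1p(-p)))
    return -log_cdf


def s_min_score(p_values: pd.DataFrame) -> CombinedScore:
    """Combine k per-contrast p-value columns into the S_min rank score.

    ``p_values`` is gene x contrast; ranks are assigned by S_min descending
    with ties broken by gene ID for determinism.
    """
    arr = p_values.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("need a gene x contrast p-value matrix")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = arr.shape[1]
    p_min = arr.min(axis=1)
    scores = s_min(p_min, k)
    table = p_values.copy()
    table.columns = [f"p_{c}" for c in p_values.columns]
    table["p_min"] = p_min
    table["s_min"] = scores
    order = (
        table.assign(gene=table.index)
        .sort_values(by=["s_min", "gene"], ascending=[False, True])
        .index
    )
    table["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order
    ).reindex(table.index)
    return CombinedScore(table=table, k=k)


def roc_curve(scores: pd.Series | np.ndarray, labels) -> ROCResult:
    """ROC curve of a score against binary labels; AUC by trapezoid.

    Thresholds sweep the distinct score values in descending order; tied
    scores enter a single threshold step.  Raises if only one class is
    present.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for an ROC curve")
    fpr, tpr, thr = metrics.roc_curve(y, s, drop_intermediate=False)
    auc = float(metrics.auc(fpr, tpr))
    return ROCResult(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
        n_positive=n_pos, n_negative=n_neg,
    )


def classify_mrgs(
    combined: CombinedScore,
    z_flags: pd.DataFrame,
    validation_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the candidate regional-gene table.

    Joins the per-contrast Z/p columns and significance flag from
    ``z_flags`` (the output of ``diffexp.call_significant``) with p_min /
    S_min, sorted by S_min descending (ties by gene ID); appends the binary
    validation label when provided.  Deterministic under rerun.
    """
    out = z_flags.join(combined.table[["p_min", "s_min", "rank"]], how="left")
    if validation_labels is not None:
        out["validated"] = validation_labels.reindex(out.index)
    out = out.loc[
        out.assign(gene=out.index)
        .sort_values(by=["s_min", "gene"], ascending=[False, True])
        .index
    ]
    return out
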