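"""Regional differential expression over axial region contrasts.

Three methods are provided:

* ``de_dropout`` — the primary, dropout-aware Bayesian model.  Each cell
  gets an error model: a logistic dropout curve (probability of failing to
  detect a transcript falls with its expression), a background Poisson rate
  for dropped-out genes, and a global negative binomial dispersion for
  detected counts.  Per gene and cell group, a posterior over a log2
  expression grid is formed from the product of per-cell mixture
  likelihoods; the log2 fold-change posterior between groups is the discrete
  cross-correlation of the two group posteriors.  Z = posterior mean / SD of
  the fold change; p is the two-sided normal tail.

* ``de_bimod`` — a two-part likelihood-ratio test combining the detection
  fraction (binomial) and the mean of detected log-CPM (normal with pooled
  variance).

* ``de_ttest`` — Student's equal-variance t-test on log-CPM.

Fold changes are reported as group_A minus group_B (positive = enriched in
the first-named group).  Genes with |Z| > 2.58 (normal tail p < 0.005) in
any contrast are flagged as candidate regional genes; Benjamini-Hochberg
corrected values (cZ) are reported alongside but the primary call uses
uncorrected Z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from scipy.special import expit, gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .counts_io import CountMatrix
from .qc_normalize import ExpressionMatrix

logger = logging.getLogger(__name__)

Z_CUTOFF_DEFAULT = 2.58  # two-tailed normal p < 0.01; one-tail p < 0.005


@dataclass(frozen=True)
class Contrast:
    """A named comparison of two disjoint sets of axial regions."""

    name: str
    group_a: frozenset[int]
    group_b: frozenset[int]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.name!r}: empty group")
        if self.group_a & self.group_b:
            raise ValueError(f"contrast {self.name!r}: groups overlap")

    @classmethod
    def of(cls, name: str, a, b) -> "Contrast":
        return cls(name, frozenset(a), frozenset(b))

    def resolve(self, regions: pd.Series) -> tuple[list[str], list[str]]:
        """Cell IDs of each group given a cell -> region mapping."""
        a = list(regions.index[regions.isin(self.group_a)])
        b = list(regions.index[regions.isin(self.group_b)])
        if not a or not b:
            raise ValueError(f"contrast {self.name!r}: no cells in a group")
        return a, b


#: The three axial contrasts used for the regional screen:
#: anterior vs posterior thirds, head tip vs post-pharyngeal, and
#: pre-pharyngeal vs tail tip.
DEFAULT_CONTRASTS: tuple[Contrast, ...] = (
    Contrast.of("anterior_vs_posterior", {1, 2, 3}, {8, 9, 10}),
    Contrast.of("head_vs_postpharyngeal", {1}, {7, 8, 9}),
    Contrast.of("prepharyngeal_vs_tail", {2, 3, 4}, {10}),
)


@dataclass
class ErrorModel:
    """Per-cell dropout model parameters.

    p_drop(e) = 1 / (1 + exp(theta0 + theta1 * log(e + 1))), theta1 >= 0,
    so dropout probability is non-increasing in expression e (CPM).
    ``lambda0`` is the background Poisson rate of the dropout component and
    ``phi`` the global NB dispersion (variance = mu + phi * mu^2).
    """

    params: pd.DataFrame  # index cell_id; columns theta0, theta1, total_counts
    lambda0: float
    phi: float

    def p_drop(self, cell: str, e: np.ndarray) -> np.ndarray:
        th0 = self.params.at[cell, "theta0"]
        th1 = self.params.at[cell, "theta1"]
        return expit(-(th0 + th1 * np.log1p(e)))


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one contrast/method."""

    table: pd.DataFrame  # index gene; columns log2fc, z, p, cz, p_adj, flagged
    method: str
    contrast: str


def _dropout_nll(params, x, y, p0_nb, p0_bg):
    """Negative log-likelihood of the detection indicator under the mixture.

    P(zero | e) = p_drop * P(Pois(lambda0) = 0) + (1 - p_drop) * NB(0; mu, phi)
    with p_drop = sigmoid(-(theta0 + theta1 * x)), x = log(e + 1).  Accounting
    for the NB zero mass keeps sampling zeros at low expression from being
    absorbed into the dropout curve.
    """
    th0, th1 = params
    p_drop = expit(-(th0 + th1 * x))
    p_zero = np.clip(p_drop * p0_bg + (1.0 - p_drop) * p0_nb, 1e-12, 1 - 1e-12)
    ll = np.sum(np.where(y, np.log1p(-p_zero), np.log(p_zero)))
    # d ll / d p_drop, then chain through the logistic
    dll_dpzero = np.where(y, -1.0 / (1.0 - p_zero), 1.0 / p_zero)
    dpzero_dp = p0_bg - p0_nb
    dp_dth = -p_drop * (1.0 - p_drop)
    common = dll_dpzero * dpzero_dp * dp_dth
    return -ll, (-common.sum(), -(common * x).sum())


def _fit_round(
    e_hat_all: np.ndarray,
    detected: np.ndarray,
    totals: np.ndarray,
    counts: np.ndarray,
    cells: list[str],
    lambda0: float,
) -> tuple[pd.DataFrame, float]:
    """One round of per-cell dropout fits plus a global phi estimate."""
    mu_all = e_hat_all / 1e6 * totals[None, :]
    # entries with vanishing expected counts carry no dispersion signal and
    # their (x - mu)^2 residuals reflect dropout/background misfit instead
    det = detected & (mu_all > 0.25)
    x = counts[det]
    mu = mu_all[det]
    phi = float(max(np.sum((x - mu) ** 2 - mu) / np.sum(mu**2), 1e-6))

    r = 1.0 / phi
    p0_bg = float(np.exp(-lambda0))
    rows = []
    for j, cell in enumerate(cells):
        e_hat = e_hat_all[:, j]
        mask = e_hat > 0
        if mask.sum() < 50:
            raise ValueError(
                f"cell {cell!r}: only {int(mask.sum())} genes with positive "
                "reference expression; insufficient signal"
            )
        x = np.log1p(e_hat[mask])
        y = detected[mask, j]
        mu = mu_all[mask, j]
        p0_nb = np.exp(r * (np.log(r) - np.log(r + mu)))
        res = optimize.minimize(
            _dropout_nll, x0=(0.0, 1.0), args=(x, y, p0_nb, p0_bg), jac=True,
            method="L-BFGS-B", bounds=[(-50.0, 50.0), (0.0, 50.0)],
        )
        rows.append({
            "cell_id": cell, "theta0": res.x[0], "theta1": res.x[1],
            "total_counts": totals[j],
        })
    return pd.DataFrame(rows).set_index("cell_id"), phi


def fit_error_models(
    cm: CountMatrix,
    em: ExpressionMatrix,
    cells: list[str],
    lambda0: float = 0.1,
    trim: float = 0.2,
    n_iter: int = 3,
) -> ErrorModel:
    """Fit per-cell dropout curves and a global NB dispersion.

    For each cell, a reference expression e_hat per gene is the 20%-trimmed
    mean of CPM over the *other* cells in the set; the logistic dropout
    parameters are fit by maximum likelihood on the binary detection
    indicator against log(e_hat + 1) (slope constrained >= 0), with the
    detection probability including the NB zero mass so sampling zeros are
    not mistaken for dropout.  The NB dispersion phi is fit globally by
    method of moments on detected counts.

    Because the observed mean expression of a gene is itself depressed by
    dropout (E[observed cpm] ~ e * (1 - p_drop(e))), a second iteration
    inverts the pooled fitted dropout curve to de-bias the reference
    expression and refits.
    """
    if len(cells) < 5:
        raise ValueError("need at least 5 cells to fit error models")
    counts = cm.counts[cells].to_numpy().astype(float)
    totals = counts.sum(axis=0)
    cpm = counts / totals[None, :] * 1e6
    detected = counts > 0

    e_raw = np.empty_like(counts)
    for j in range(len(cells)):
        others = np.delete(cpm, j, axis=1)
        e_raw[:, j] = stats.trim_mean(others, trim, axis=1)

    e_hat_all = e_raw
    params = None
    phi = 0.0
    for it in range(max(n_iter, 1)):
        params, phi = _fit_round(
            e_hat_all, detected, totals, counts, cells, lambda0
        )
        if it == max(n_iter, 1) - 1:
            break
        model = ErrorModel(params=params, lambda0=lambda0, phi=phi)
        e_hat_all = _loo_reference(counts, cells, model)
    return ErrorModel(params=params, lambda0=lambda0, phi=phi)


def _loo_reference(
    counts: np.ndarray,
    cells: list[str],
    model: "ErrorModel",
    grid_log2: np.ndarray | None = None,
) -> np.ndarray:
    """Leave-one-out grid MLE of per-gene expression under the mixture model.

    For each cell j, the reference expression of gene g is the grid point
    maximizing the summed mixture log-likelihood over all *other* cells.
    Computed in two passes (total minus own term) so memory stays at
    genes x grid.
    """
    if grid_log2 is None:
        # top of the range is a whole library (1e6 cpm): reference estimates
        # must not truncate even extreme genes or phi inherits the bias
        grid_log2 = np.linspace(-5.0, 20.0, 251)
    e = 2.0**grid_log2
    n_genes, n_cells = counts.shape
    total = np.zeros((n_genes, grid_log2.size))

    def cell_term(j: int) -> np.ndarray:
        x = counts[:, j]
        cell = cells[j]
        t = model.params.at[cell, "total_counts"]
        pd_e = model.p_drop(cell, e)
        log_pd = np.log(np.maximum(pd_e, 1e-300))
        log_1mpd = np.log(np.maximum(1.0 - pd_e, 1e-300))
        log_pois = stats.poisson.logpmf(x, model.lambda0)
        mu = e[None, :] * (t / 1e6)
        log_nb = _nb_log_pmf(x[:, None], mu, model.phi)
        return np.logaddexp(
            log_pd[None, :] + log_pois[:, None], log_1mpd[None, :] + log_nb
        )

    for j in range(n_cells):
        total += cell_term(j)
    e_hat = np.empty_like(counts)
    for j in range(n_cells):
        loo = total - cell_term(j)
        e_hat[:, j] = e[np.argmax(loo, axis=1)]
    return e_hat


def _nb_log_pmf(x: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB log pmf with mean mu, variance mu + phi mu^2 (broadcasting)."""
    if phi <= 0:
        return stats.poisson.logpmf(x, np.maximum(mu, 1e-300))
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-300)
    return (
        gammaln(x + r) - gammaln(r) - gammaln(x + 1)
        + r * (np.log(r) - np.log(r + mu))
        + x * (np.log(mu) - np.log(r + mu))
    )


def make_grid(lo: float = 0.0, hi: float = 15.0, n: int = 301) -> np.ndarray:
    """Default posterior grid over log2 expression (CPM), 301 points in [0,15]."""
    return np.linspace(lo, hi, n)


def _group_log_posterior(
    counts: np.ndarray,  # genes x cells (this group)
    cells: list[str],
    models: ErrorModel,
    grid: np.ndarray,
) -> np.ndarray:
    """Unnormalized log posterior (genes x grid) of group mean expression."""
    e = 2.0**grid
    log_post = np.zeros((counts.shape[0], grid.size))
    for j, cell in enumerate(cells):
        x = counts[:, j]
        t = models.params.at[cell, "total_counts"]
        pd_e = models.p_drop(cell, e)  # grid
        log_pd = np.log(np.maximum(pd_e, 1e-300))
        log_1mpd = np.log(np.maximum(1.0 - pd_e, 1e-300))
        log_pois = stats.poisson.logpmf(x, models.lambda0)  # genes
        mu = e[None, :] * (t / 1e6)  # 1 x grid
        log_nb = _nb_log_pmf(x[:, None], mu, models.phi)  # genes x grid
        log_post += np.logaddexp(
            log_pd[None, :] + log_pois[:, None], log_1mpd[None, :] + log_nb
        )
    return log_post


def de_dropout(
    cm: CountMatrix,
    models: ErrorModel,
    contrast: Contrast,
    grid: np.ndarray | None = None,
) -> DEResult:
    """Dropout-aware Bayesian differential expression for one contrast.

    Per gene and group, a posterior over the log2-CPM grid is formed with a
    uniform prior from the product of per-cell mixture likelihoods
    p_drop(e) Pois(x; lambda0) + (1 - p_drop(e)) NB(x; e/1e6 * L_c, phi).
    The log2 fold-change (A - B) posterior is the cross-correlation of the
    two group posteriors; log2fc is its mode, Z its mean/SD, p the
    two-sided normal tail of Z.  Genes undetected in every cell of both
    groups get Z = 0, p = 1 and an ``undetected`` flag.
    """
    if grid is None:
        grid = make_grid()
    cells_a, cells_b = contrast.resolve(cm.regions)
    missing = [
        c for c in cells_a + cells_b if c not in models.params.index
    ]
    if missing:
        raise ValueError(f"no error model for cells: {missing[:5]}")
    counts_a = cm.counts[cells_a].to_numpy()
    counts_b = cm.counts[cells_b].to_numpy()

    lp_a = _group_log_posterior(counts_a, cells_a, models, grid)
    lp_b = _group_log_posterior(counts_b, cells_b, models, grid)
    post_a = np.exp(lp_a - logsumexp(lp_a, axis=1, keepdims=True))
    post_b = np.exp(lp_b - logsumexp(lp_b, axis=1, keepdims=True))

    # fold-change distribution over delta = gA - gB on the shared grid
    step = grid[1] - grid[0]
    m = grid.size
    # correlate(post_a, post_b): full cross-correlation along the grid axis
    fc_post = signal.fftconvolve(post_a, post_b[:, ::-1], mode="full", axes=1)
    fc_post = np.clip(fc_post, 0.0, None)
    fc_post /= fc_post.sum(axis=1, keepdims=True)
    deltas = (np.arange(2 * m - 1) - (m - 1)) * step

    mean = fc_post @ deltas
    var = fc_post @ deltas**2 - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    # mode with ties resolved toward the smallest |delta|
    maxp = fc_post.max(axis=1, keepdims=True)
    tie = fc_post >= maxp * (1.0 - 1e-9)
    abs_d = np.where(tie, np.abs(deltas)[None, :], np.inf)
    mode = deltas[np.argmin(abs_d, axis=1)]

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    undetected = (counts_a.sum(axis=1) == 0) & (counts_b.sum(axis=1) == 0)
    z[undetected] = 0.0
    p[undetected] = 1.0
    mode[undetected] = 0.0

    table = pd.DataFrame({
        "log2fc": mode, "z": z, "p": p, "undetected": undetected,
    }, index=cm.gene_ids)
    _attach_corrected(table)
    return DEResult(table=table, method="dropout", contrast=contrast.name)


def de_bimod(em: ExpressionMatrix, contrast: Contrast) -> DEResult:
    """Two-part (detection + level) likelihood-ratio test per gene.

    Part 1 models the detection fraction as binomial; part 2 models the
    detected log-CPM values as normal with a shared variance.  The LRT
    statistic is referred to chi-square with df equal to the number of free
    parameters differing between the alternative and the null (2 when both
    parts are estimable, else 1).
    """
    cells_a, cells_b = contrast.resolve(_regions_of(em))
    va = em.values[cells_a].to_numpy()
    vb = em.values[cells_b].to_numpy()
    na, nb = va.shape[1], vb.shape[1]

    rows = np.arange(va.shape[0])
    log2fc = np.zeros(len(rows))
    lrt = np.zeros(len(rows))
    dfs = np.zeros(len(rows), dtype=int)
    flagged = np.zeros(len(rows), dtype=bool)

    def binom_ll(d, n, p):
        if p <= 0.0 or p >= 1.0:
            return 0.0 if (d == 0 or d == n) else -np.inf
        return d * np.log(p) + (n - d) * np.log1p(-p)

    for g in rows:
        ya = va[g][va[g] > 0]
        yb = vb[g][vb[g] > 0]
        da, db = len(ya), len(yb)
        if da + db == 0:
            lrt[g] = 0.0
            dfs[g] = 1
            flagged[g] = True
            continue
        # binomial part
        ll_alt = binom_ll(da, na, da / na) + binom_ll(db, nb, db / nb)
        ll_null = binom_ll(da + db, na + nb, (da + db) / (na + nb))
        stat = 2.0 * (ll_alt - ll_null)
        df = 1
        # normal part on detected values, MLE variances
        if da >= 1 and db >= 1 and da + db >= 3:
            y = np.concatenate([ya, yb])
            ss_alt = ((ya - ya.mean()) ** 2).sum() + ((yb - yb.mean()) ** 2).sum()
            ss_null = ((y - y.mean()) ** 2).sum()
            n_det = da + db
            if ss_alt <= 0.0:
                if ss_null > 0.0:
                    stat += 2.0 * 20.0  # separated point masses: saturate
                    flagged[g] = True
                df += 1
            else:
                stat += n_det * np.log(ss_null / ss_alt)
                df += 1
        log2fc[g] = (ya.mean() if da else 0.0) - (yb.mean() if db else 0.0)
        lrt[g] = max(stat, 0.0)
        dfs[g] = df

    p = stats.chi2.sf(lrt, dfs)
    p[lrt == 0.0] = 1.0
    z = np.sign(np.where(log2fc != 0, log2fc, 1.0)) * stats.norm.isf(
        np.clip(p / 2.0, 1e-300, 0.5)
    )
    z[p >= 1.0] = 0.0
    table = pd.DataFrame({
        "log2fc": log2fc, "z": z, "p": p, "lrt": lrt, "df": dfs,
        "undetected": flagged,
    }, index=em.gene_ids)
    _attach_corrected(table)
    return DEResult(table=table, method="bimod", contrast=contrast.name)


def de_ttest(em: ExpressionMatrix, contrast: Contrast) -> DEResult:
    """Student's equal-variance t-test on log-CPM per gene."""
    cells_a, cells_b = contrast.resolve(_regions_of(em))
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("t-test needs at least two cells per group")
    va = em.values[cells_a].to_numpy()
    vb = em.values[cells_b].to_numpy()
    t, p = stats.ttest_ind(va, vb, axis=1, equal_var=True)
    log2fc = va.mean(axis=1) - vb.mean(axis=1)
    # zero pooled variance: equal means -> p=1; unequal -> p -> 0
    zero_var = (va.var(axis=1) == 0) & (vb.var(axis=1) == 0)
    equal_means = np.isclose(log2fc, 0.0)
    p = np.where(zero_var & equal_means, 1.0, p)
    t = np.where(zero_var & equal_means, 0.0, t)
    flagged = zero_var & ~equal_means
    p = np.where(flagged, 1e-300, p)
    z = np.sign(np.where(log2fc != 0, log2fc, 1.0)) * stats.norm.isf(
        np.clip(p / 2.0, 1e-300, 0.5)
    )
    z = np.where(p >= 1.0, 0.0, z)
    table = pd.DataFrame({
        "log2fc": log2fc, "z": z, "p": p, "t": t, "undetected": flagged,
    }, index=em.gene_ids)
    _attach_corrected(table)
    return DEResult(table=table, method="ttest", contrast=contrast.name)


def _regions_of(em: ExpressionMatrix) -> pd.Series:
    if not hasattr(em, "regions") or em.regions is None:
        raise ValueError("expression matrix lacks cell region labels")
    return em.regions


def _attach_corrected(table: pd.DataFrame) -> None:
    """Add BH-adjusted p and the corresponding corrected Z (cZ) in place."""
    p_adj = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    sign = np.sign(table["z"].to_numpy())
    sign[sign == 0] = 1.0
    cz = sign * stats.norm.isf(np.clip(p_adj / 2.0, 1e-300, 0.5))
    cz[p_adj >= 1.0] = 0.0
    table["p_adj"] = p_adj
    table["cz"] = cz


def call_significant(
    results: dict[str, DEResult],
    z_cutoff: float = Z_CUTOFF_DEFAULT,
    use_corrected: bool = False,
) -> pd.DataFrame:
    """Flag genes with |Z| strictly greater than the cutoff in ANY contrast.

    Returns a gene table with per-contrast Z/p/cZ columns and a ``flagged``
    column.  The primary call uses uncorrected Z; corrected values are
    reported alongside.
    """
    if not results:
        raise ValueError("no results given")
    pieces = {}
    flags = None
    for name, res in results.items():
        col = "cz" if use_corrected else "z"
        zs = res.table[col]
        pieces[f"z_{name}"] = res.table["z"]
        pieces[f"p_{name}"] = res.table["p"]
        pieces[f"cz_{name}"] = res.table["cz"]
        f = zs.abs() > z_cutoff
        flags = f if flags is None else (flags | f)
    out = pd.DataFrame(pieces)
    out["flagged"] = flags
    return out


def benchmark_rankings(
    results_per_method: dict[str, dict[str, DEResult]],
    known_genes: list[str],
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Rank known regional genes under each method.

    For each method, genes are ranked by their best (minimum over contrasts)
    p-value, ties broken by |Z| descending then gene ID; the table reports
    each known gene's rank and whether its best p is below ``p_cutoff``.
    Unknown gene IDs are listed with a missing rank rather than failing.
    """
    records = []
    for method, contrasts in results_per_method.items():
        p_min = None
        z_best = None
        for res in contrasts.values():
            p = res.table["p"]
            z = res.table["z"].abs()
            if p_min is None:
                p_min, z_best = p.copy(), z.copy()
            else:
                better = p < p_min
                z_best = z.where(better | (p == p_min) & (z > z_best), z_best)
                p_min = p.where(better, p_min)
        order = pd.DataFrame({"p": p_min, "z_abs": z_best})
        order = order.sort_values(
            by=["p", "z_abs"], ascending=[True, False], kind="mergesort"
        )
        # stable mergesort + index tie-break via prior sort by gene ID
        order = order.loc[
            order.assign(gene=order.index)
            .sort_values(by=["p", "z_abs", "gene"], ascending=[True, False, True])
            .index
        ]
        rank = pd.Series(np.arange(1, len(order) + 1), index=order.index)
        for gene in known_genes:
            if gene in rank.index:
                records.append({
                    "method": method, "gene": gene, "rank": int(rank[gene]),
                    "p": float(p_min[gene]),
                    "significant": bool(p_min[gene] < p_cutoff),
                })
            else:
                records.append({
                    "method": method, "gene": gene, "rank": None,
                    "p": None, "significant": False,
                })
    return pd.DataFrame(records)
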