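"""Downstream quantification statistics.

Implements the statistics applied after the sequencing analysis: relative
qPCR quantification by the ddCt method with a three-gene housekeeping
normalization, normalized expression-domain lengths and length-normalized
cell counts, Fisher's exact test for RNAi synergy, one-way ANOVA with
Dunnett many-to-one comparisons, and the two prospective power calculations
(difference of proportions with Cohen's h; balanced one-way ANOVA with
Cohen's f).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# qPCR ddCt


@dataclass
class QPCRPlate:
    """Ct values indexed by (gene, sample, replicate).

    ``table`` has columns gene, sample, replicate, ct; ``housekeeping`` names
    the three normalization genes (present in every sample);
    ``sample_condition`` maps sample -> condition, with one condition named
    ``control``.
    """

    table: pd.DataFrame
    housekeeping: tuple[str, ...]
    sample_condition: dict[str, str]

    def __post_init__(self) -> None:
        required = {"gene", "sample", "replicate", "ct"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"plate table needs columns {sorted(required)}")
        reps = self.table.groupby(["gene", "sample"])["replicate"].count()
        if (reps < 2).any():
            gene, sample = reps.idxmin()
            logger.warning(
                "gene %s sample %s has %d replicate(s); averaging available",
                gene, sample, reps.min(),
            )


def ddct(plate: QPCRPlate) -> pd.DataFrame:
    """Relative quantification by the ddCt method.

    Technical replicates are averaged; dCt = mean Ct(gene, sample) minus the
    mean over the housekeeping genes of their replicate-averaged Ct in the
    same sample; ddCt subtracts the mean dCt over control samples; the log2
    fold change is -ddCt (one fewer cycle to threshold = twice the
    transcript).

    Returns a tidy frame with columns gene, sample, condition, dct, ddct,
    log2fc, excluding the housekeeping genes themselves.
    """
    mean_ct = (
        plate.table.groupby(["gene", "sample"])["ct"].mean().unstack("sample")
    )
    missing_hk = [g for g in plate.housekeeping if g not in mean_ct.index]
    if missing_hk:
        raise ValueError(f"housekeeping genes missing from plate: {missing_hk}")
    hk = mean_ct.loc[list(plate.housekeeping)]
    if hk.isna().any().any():
        sample = hk.columns[hk.isna().any(axis=0)][0]
        raise ValueError(f"housekeeping Ct missing in sample {sample!r}")
    dct = mean_ct - hk.mean(axis=0)

    conditions = pd.Series(plate.sample_condition)
    control_samples = conditions.index[conditions == "control"]
    if len(control_samples) == 0:
        raise ValueError("no control samples in plate")
    control_mean = dct[
        [s for s in control_samples if s in dct.columns]
    ].mean(axis=1)
    ddct_mat = dct.sub(control_mean, axis=0)

    targets = [g for g in mean_ct.index if g not in plate.housekeeping]
    out = (
        ddct_mat.loc[targets]
        .rename_axis(index="gene", columns="sample")
        .stack()
        .rename("ddct")
        .reset_index()
    )
    out["dct"] = out.apply(lambda r: dct.loc[r["gene"], r["sample"]], axis=1)
    out["condition"] = out["sample"].map(plate.sample_condition)
    out["log2fc"] = -out["ddct"]
    return out[["gene", "sample", "condition", "dct", "ddct", "log2fc"]]


# ---------------------------------------------------------------------------
# Measurement normalization


@dataclass
class DomainTable:
    """Per-animal measurements: condition, lengths (um), optional cell counts."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "condition" not in self.table.columns:
            raise ValueError("domain table needs a 'condition' column")


def normalize_measurements(
    dt: DomainTable,
    mode: Literal["domain_over_total", "count_over_reference"],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize per-animal measurements and summarize per condition.

    ``domain_over_total``: expression-domain length / total body length
    (dimensionless fraction).  ``count_over_reference``: cell count / the
    reference length (e.g. anterior tip to esophagus), per micrometre.
    Returns (per-animal table with a ``normalized`` column, per-condition
    mean +/- SD summary).
    """
    df = dt.table.copy()
    if mode == "domain_over_total":
        num, den = "domain_length_um", "total_length_um"
    elif mode == "count_over_reference":
        num, den = "cell_count", "reference_length_um"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for col in (num, den):
        if col not in df.columns:
            raise ValueError(f"column {col!r} required for mode {mode!r}")
    bad = df[df[den] <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive {den} for animal {bad.iloc[0].get('animal', bad.index[0])!r}"
        )
    if (df[num] < 0).any():
        bad = df[df[num] < 0].iloc[0]
        raise ValueError(f"negative {num} for animal {bad.get('animal', '?')!r}")
    df["normalized"] = df[num] / df[den]
    summary = (
        df.groupby("condition")["normalized"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
    )
    return df, summary


# ---------------------------------------------------------------------------
# Exact and ANOVA tests


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 contingency table.

    Two-sided by summing the probabilities of all tables with the observed
    margins whose hypergeometric probability does not exceed the observed
    table's (with a small relative tolerance for ties).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = arr.astype(int)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Standard one-way fixed-effects ANOVA; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    grand = np.concatenate(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = [a.mean() for a in arrays]
    if ss_within == 0.0:
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        logger.warning("zero within-group variance with unequal means; p -> 0")
        return float("inf"), 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def dunnett_many_to_one(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett-style many-to-one comparisons with Monte Carlo adjustment.

    Each treatment group is compared with the control by a pooled-variance t
    statistic; the family-wise adjusted p-value is the Monte Carlo
    probability that the maximum |t| across comparisons, under the joint
    null with the balanced many-to-one correlation structure, exceeds the
    observed |t_i|.  Seed-reproducible.

    Returns a DataFrame with one row per treatment group: t, p_unadjusted
    (two-sided pooled t), p_adjusted.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need control plus at least one treatment group")
    if len(arrays[control_index]) < 2:
        raise ValueError("control group needs at least two values")
    control = arrays[control_index]
    treatments = [a for i, a in enumerate(arrays) if i != control_index]
    names = [i for i in range(len(arrays)) if i != control_index]

    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    df_resid = n_total - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    s2 = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_resid

    t_obs, p_unadj, ns = [], [], []
    for a in treatments:
        se = np.sqrt(s2 * (1.0 / len(a) + 1.0 / len(control)))
        t = (a.mean() - control.mean()) / se if se > 0 else 0.0
        t_obs.append(t)
        p_unadj.append(2.0 * stats.t.sf(abs(t), df_resid) if se > 0 else 1.0)
        ns.append(len(a))

    # Null of (T_1..T_m): T_i = (Z_i/sqrt(n_i) - Z_0/sqrt(n_0)) / (S sqrt(1/n_i+1/n_0))
    rng = np.random.default_rng(seed)
    m = len(treatments)
    z0 = rng.standard_normal(n_mc) / np.sqrt(len(control))
    zi = rng.standard_normal((n_mc, m)) / np.sqrt(ns)
    s_null = np.sqrt(rng.chisquare(df_resid, n_mc) / df_resid)
    scale = np.sqrt(1.0 / np.asarray(ns) + 1.0 / len(control))
    t_null = (zi - z0[:, None]) / (s_null[:, None] * scale[None, :])
    max_abs = np.abs(t_null).max(axis=1)
    p_adj = [
        float((np.sum(max_abs >= abs(t)) + 1) / (n_mc + 1)) for t in t_obs
    ]
    return pd.DataFrame({
        "group": names,
        "t": t_obs,
        "p_unadjusted": p_unadj,
        "p_adjusted": np.maximum(p_adj, p_unadj),
    })


# ---------------------------------------------------------------------------
# Power calculations


@dataclass(frozen=True)
class PowerSpec:
    """Prospective sample-size specification.

    ``effect_size`` is Cohen's h for ``two_proportions`` (arcsine-transformed
    proportion difference) or Cohen's f for ``one_way_anova``; ``k`` is the
    number of ANOVA groups.
    """

    family: Literal["two_proportions", "one_way_anova"]
    effect_size: float
    alpha: float = 0.05
    power: float = 0.8
    k: int = field(default=2)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if self.k < 2:
            raise ValueError("k must be at least 2")


def power_two_proportions(spec: PowerSpec) -> float:
    """Minimum total sample size for a two-proportion test at Cohen's h.

    Per-group n = (z_{1-alpha/2} + z_{power})^2 / h^2; the returned value is
    the TOTAL across the two equal groups, reported to one decimal.
    """
    if spec.family != "two_proportions":
        raise ValueError("spec.family must be 'two_proportions'")
    z = stats.norm.isf(spec.alpha / 2.0) + stats.norm.isf(1.0 - spec.power)
    n_per_group = (z / spec.effect_size) ** 2
    return round(2.0 * n_per_group, 1)


def power_anova(spec: PowerSpec) -> float:
    """Minimum per-group n for a balanced one-way ANOVA at Cohen's f.

    Solves for the smallest real n >= 2 with noncentral-F power >= target:
    noncentrality lambda = k * n * f^2, df = (k - 1, k(n - 1)).  Reported to
    one decimal.
    """
    if spec.family != "one_way_anova":
        raise ValueError("spec.family must be 'one_way_anova'")
    k, f2 = spec.k, spec.effect_size**2

    def attained(n: float) -> float:
        df2 = k * (n - 1.0)
        crit = stats.f.isf(spec.alpha, k - 1, df2)
        return float(stats.ncf.sf(crit, k - 1, df2, k * n * f2))

    lo = 2.0
    if attained(lo) >= spec.power:
        return round(lo, 1)
    hi = 4.0
    while attained(hi) < spec.power:
        hi *= 2.0
        if hi > 1e7:
            raise ValueError("requested power unattainable")
    n = optimize.brentq(lambda n: attained(n) - spec.power, lo, hi, xtol=1e-4)
    return round(float(n), 1)
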