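"""Synthetic data with ground truth for the axial muscle single-cell pipeline.

Emulates the structure of a single-cell RNA-seq study of cells dissected from
10 ordered anterior-posterior (AP) body regions: a mixture of muscle,
neoblast, epidermal-lineage and other cells; lognormal library sizes;
expression dropout whose probability falls with true expression; negative
binomial counts; marker genes gating cell classes; and regionally expressed
muscle genes (mRGs) drawn from the spatial profile families observed along
the axis (tip-restricted, graded anterior/posterior, interior band,
rare-cell, shallow gradient, broad domain).

The generative model per gene g and cell c with true expression e (CPM):

    p_drop(e) = logistic(dropout_midpoint - dropout_slope * log(e + 1))
    count ~ Poisson(lambda0)                      with prob. p_drop(e)
            NB(mean = e / 1e6 * L_c, disp = phi)  otherwise

with L_c a lognormal library size and NB variance mean + phi * mean^2.
Ground truth (cell classes, gene labels, per-region true mean CPM) is
returned alongside the counts for benchmarking.

The module also simulates qPCR Ct plates for the ddCt estimator and
domain-length measurement tables for the expression-domain statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, write_counts
from .downstream_stats import DomainTable, QPCRPlate

logger = logging.getLogger(__name__)

CELL_CLASSES = ("muscle", "neoblast", "epidermal", "other")

PROFILE_FAMILIES = (
    "tip_restricted",
    "anterior_gradient",
    "posterior_gradient",
    "band",
    "rare_cell",
    "shallow",
    "broad",
)

#: mRG complement of the default configuration: 44 regional genes spread over
#: the profile families seen along the axis, with CPM amplitudes.
DEFAULT_MRG_PROFILES: tuple[tuple[str, int, float], ...] = (
    ("tip_restricted", 6, 200.0),
    ("anterior_gradient", 8, 150.0),
    ("posterior_gradient", 8, 150.0),
    ("band", 8, 150.0),
    ("rare_cell", 6, 400.0),
    ("shallow", 4, 150.0),
    ("broad", 4, 100.0),
)

#: Marker genes gating cell classes (marker -> (class, mean CPM in class)).
DEFAULT_MARKER_SPEC: dict[str, tuple[str, float]] = {
    "troponin": ("muscle", 200.0),
    "collagen": ("muscle", 150.0),
    "piwi_like": ("neoblast", 200.0),
    "prog_like": ("epidermal", 200.0),
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the axial count-matrix simulation.

    Defaults approximate the study design the pipeline targets: 10 regions,
    ~18 cells sorted per region (~180 cells), ~65% muscle, libraries of a few
    hundred thousand mapped reads, and on the order of 3,000 expressed
    transcripts per cell.
    """

    n_regions: int = 10
    cells_per_region: int = 18
    n_genes: int = 4000
    cell_class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "muscle": 0.65, "neoblast": 0.15, "epidermal": 0.14, "other": 0.06
        }
    )
    library_size_log_mean: float = 12.97  # ln scale; e^12.97 ~ 430,000 reads
    library_size_log_sd: float = 0.35
    dropout_midpoint: float = 2.0
    dropout_slope: float = 1.0
    background_rate: float = 0.1  # Poisson rate of the dropout component
    nb_dispersion: float = 0.4
    mrg_profiles: tuple[tuple[str, int, float], ...] = DEFAULT_MRG_PROFILES
    marker_spec: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_SPEC)
    )
    program_genes_per_class: int = 40  # class-specific (non-regional) programs
    program_fold: float = 8.0
    baseline_log_sd: float = 1.2  # lognormal spread of baseline gene CPM
    rare_cell_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "cells_per_region", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        tot = sum(self.cell_class_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(
                f"cell_class_proportions sum to {tot}, expected 1"
            )
        if set(self.cell_class_proportions) - set(CELL_CLASSES):
            raise ConfigurationError(
                f"unknown cell classes: "
                f"{set(self.cell_class_proportions) - set(CELL_CLASSES)}"
            )
        for fam, n, amp in self.mrg_profiles:
            if fam not in PROFILE_FAMILIES:
                raise ConfigurationError(f"unknown profile family {fam!r}")
            if n < 0 or amp <= 0:
                raise ConfigurationError("mrg_profiles need n >= 0, amplitude > 0")
        n_special = (
            sum(n for _, n, _ in self.mrg_profiles)
            + len(self.marker_spec)
            + self.program_genes_per_class * 3
        )
        if n_special >= self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for {n_special} "
                "mRG/marker/program genes"
            )

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    def to_flat(self) -> dict[str, str]:
        """Flatten to a round-trippable key-value mapping."""
        flat: dict[str, str] = {}
        for name in (
            "n_regions", "cells_per_region", "n_genes",
            "library_size_log_mean", "library_size_log_sd",
            "dropout_midpoint", "dropout_slope", "background_rate",
            "nb_dispersion", "program_genes_per_class", "program_fold",
            "baseline_log_sd", "rare_cell_fraction", "seed",
        ):
            flat[name] = repr(getattr(self, name))
        for cls, p in self.cell_class_proportions.items():
            flat[f"proportion.{cls}"] = repr(p)
        for i, (fam, n, amp) in enumerate(self.mrg_profiles):
            flat[f"mrg.{i}"] = f"{fam}:{n}:{amp!r}"
        for gene, (cls, cpm) in self.marker_spec.items():
            flat[f"marker.{gene}"] = f"{cls}:{cpm!r}"
        return flat

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "SimConfig":
        kw: dict = {}
        proportions: dict[str, float] = {}
        mrg: dict[int, tuple[str, int, float]] = {}
        markers: dict[str, tuple[str, float]] = {}
        ints = {"n_regions", "cells_per_region", "n_genes",
                "program_genes_per_class", "seed"}
        for key, val in flat.items():
            if key.startswith("proportion."):
                proportions[key.split(".", 1)[1]] = float(val)
            elif key.startswith("mrg."):
                fam, n, amp = val.split(":")
                mrg[int(key.split(".", 1)[1])] = (fam, int(n), float(amp))
            elif key.startswith("marker."):
                c, cpm = val.split(":")
                markers[key.split(".", 1)[1]] = (c, float(cpm))
            elif key in ints:
                kw[key] = int(val)
            else:
                kw[key] = float(val)
        if proportions:
            kw["cell_class_proportions"] = proportions
        if mrg:
            kw["mrg_profiles"] = tuple(mrg[i] for i in sorted(mrg))
        if markers:
            kw["marker_spec"] = markers
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_flat().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        flat = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            flat[key.strip()] = val.strip()
        return cls.from_flat(flat)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated count matrix.

    ``cell_class`` maps cell ID -> class; ``gene_label`` maps gene ID to
    ``mRG:<family>``, ``nonregional`` or ``marker``; ``profile_params`` holds
    each gene's true per-region mean CPM vector in muscle cells
    (gene x region DataFrame, columns 1..n_regions).
    """

    cell_class: pd.Series
    gene_label: pd.Series
    profile_params: pd.DataFrame

    @property
    def mrg_genes(self) -> pd.Index:
        return self.gene_label.index[
            self.gene_label.str.startswith("mRG:")
        ]

    def mrg_of_family(self, family: str) -> pd.Index:
        return self.gene_label.index[self.gene_label == f"mRG:{family}"]

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.cell_class.rename("cell_class").rename_axis("cell_id").to_csv(
            out_dir / "truth_cells.tsv", sep="\t"
        )
        self.gene_label.rename("gene_label").rename_axis("gene_id").to_csv(
            out_dir / "truth_genes.tsv", sep="\t"
        )
        self.profile_params.rename_axis("gene_id").to_csv(
            out_dir / "truth_profiles.tsv", sep="\t"
        )


def _region_profile(
    family: str, n_regions: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """True mean CPM over regions 1..n for one regional gene (muscle cells)."""
    prof = np.zeros(n_regions)
    if family == "tip_restricted":
        prof[0] = amplitude
    elif family == "anterior_gradient":
        rate = rng.uniform(0.3, 0.8)
        prof = amplitude * np.exp(-rate * np.arange(n_regions))
    elif family == "posterior_gradient":
        rate = rng.uniform(0.3, 0.8)
        prof = amplitude * np.exp(-rate * np.arange(n_regions))[::-1]
    elif family == "band":
        width = min(int(rng.integers(2, 5)), max(n_regions - 2, 1))
        lo = 1 if n_regions - width > 1 else 0  # interior when possible
        start = int(rng.integers(lo, max(n_regions - width, lo + 1)))
        prof[start:start + width] = amplitude
    elif family == "rare_cell":
        width = min(int(rng.integers(2, 5)), n_regions)
        start = int(rng.integers(0, n_regions - width + 1))
        prof[start:start + width] = amplitude
    elif family == "shallow":
        grad = np.linspace(1.0, 0.5, n_regions)
        if rng.random() < 0.5:
            grad = grad[::-1]
        prof = amplitude * grad
    elif family == "broad":
        width = int(rng.integers(max(8, n_regions - 2), n_regions))
        start = int(rng.integers(0, n_regions - width + 1))
        prof[start:start + width] = amplitude
    else:  # pragma: no cover - guarded by SimConfig validation
        raise ConfigurationError(f"unknown profile family {family!r}")
    return prof


def simulate_axis_counts(
    config: SimConfig,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a gene x cell count matrix over ordered axial regions.

    Returns the raw counts with per-cell region metadata, and the ground
    truth (cell classes, gene labels, true muscle region profiles).
    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n_reg, n_cells = config.n_regions, config.n_regions * config.cells_per_region
    n_genes = config.n_genes

    # --- gene roster ---------------------------------------------------
    marker_genes = list(config.marker_spec)
    mrg_genes: list[str] = []
    mrg_family: list[str] = []
    for fam, n, _amp in config.mrg_profiles:
        for i in range(n):
            mrg_genes.append(f"mrg_{fam}_{i}")
            mrg_family.append(fam)
    program_classes = ("muscle", "neoblast", "epidermal")
    program_genes = {
        cls: [f"prog_{cls}_{i}" for i in range(config.program_genes_per_class)]
        for cls in program_classes
    }
    n_named = (
        len(marker_genes) + len(mrg_genes)
        + sum(len(v) for v in program_genes.values())
    )
    baseline_genes = [f"gene_{i}" for i in range(n_genes - n_named)]
    gene_ids = (
        marker_genes + mrg_genes
        + [g for cls in program_classes for g in program_genes[cls]]
        + baseline_genes
    )
    gene_index = pd.Index(gene_ids, name="gene_id")
    gpos = {g: i for i, g in enumerate(gene_ids)}

    # --- true expression by (class, region), CPM scale ------------------
    # baseline: lognormal CPM shared by every class and region
    base_cpm = np.zeros(n_genes)
    n_base = len(baseline_genes) + sum(len(v) for v in program_genes.values())
    # center so that baseline genes sum near 1e6 before per-cell normalization
    mean_log = np.log(1e6 / n_base) - config.baseline_log_sd**2 / 2
    draws = rng.lognormal(mean_log, config.baseline_log_sd, size=n_base)
    k = 0
    for cls in program_classes:
        for g in program_genes[cls]:
            base_cpm[gpos[g]] = draws[k]
            k += 1
    for g in baseline_genes:
        base_cpm[gpos[g]] = draws[k]
        k += 1

    # expression[class] is genes x regions
    expr = {cls: np.tile(base_cpm[:, None], (1, n_reg)) for cls in CELL_CLASSES}
    for cls in program_classes:
        idx = [gpos[g] for g in program_genes[cls]]
        expr[cls][idx, :] *= config.program_fold
    for gene, (cls, cpm) in config.marker_spec.items():
        expr[cls][gpos[gene], :] = cpm
    profiles = np.zeros((len(mrg_genes), n_reg))
    for j, (g, fam) in enumerate(zip(mrg_genes, mrg_family)):
        amp = next(a for f, _n, a in config.mrg_profiles if f == fam)
        profiles[j] = _region_profile(fam, n_reg, amp, rng)
        expr["muscle"][gpos[g], :] = profiles[j]

    # --- cells ----------------------------------------------------------
    regions = np.repeat(np.arange(1, n_reg + 1), config.cells_per_region)
    classes = list(config.cell_class_proportions)
    probs = np.array([config.cell_class_proportions[c] for c in classes])
    cell_class = rng.choice(classes, size=n_cells, p=probs)
    lib_sizes = rng.lognormal(
        config.library_size_log_mean, config.library_size_log_sd, size=n_cells
    )
    cell_ids = [f"cell_{r:02d}_{i:03d}" for i, r in enumerate(regions)]

    # rare_cell genes: within their domain only a fraction of muscle cells express
    rare_rows = [j for j, fam in enumerate(mrg_family) if fam == "rare_cell"]
    rare_gpos = [gpos[mrg_genes[j]] for j in rare_rows]
    rare_express = rng.random((len(rare_rows), n_cells)) < config.rare_cell_fraction

    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for c in range(n_cells):
        e = expr[cell_class[c]][:, regions[c] - 1].copy()
        if cell_class[c] == "muscle" and rare_rows:
            on = rare_express[:, c]
            e[np.array(rare_gpos)[~on]] = 0.0
        e *= 1e6 / e.sum()  # true CPM sums to one million per cell
        p_drop = 1.0 / (1.0 + np.exp(
            -(config.dropout_midpoint - config.dropout_slope * np.log1p(e))
        ))
        dropped = rng.random(n_genes) < p_drop
        mu = e / 1e6 * lib_sizes[c]
        # NB with variance mu + phi mu^2  <=>  Gamma-Poisson mixture
        phi = config.nb_dispersion
        if phi > 0:
            lam = np.where(mu > 0, rng.gamma(1.0 / phi, phi * mu + 1e-300), 0.0)
        else:
            lam = mu
        nb_counts = rng.poisson(lam)
        bg_counts = rng.poisson(config.background_rate, size=n_genes)
        counts[:, c] = np.where(dropped, bg_counts, nb_counts)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_index, columns=cell_ids),
        pd.DataFrame({"region": regions}, index=pd.Index(cell_ids, name="cell_id")),
    )

    # --- truth ----------------------------------------------------------
    labels = pd.Series("nonregional", index=gene_index, name="gene_label")
    labels[marker_genes] = "marker"
    for g, fam in zip(mrg_genes, mrg_family):
        labels[g] = f"mRG:{fam}"
    # true mean CPM in muscle cells per region, on the normalized scale the
    # cells actually realize (rare-cell genes at their expectation over cells)
    muscle_true = expr["muscle"].copy()
    if rare_gpos:
        muscle_true[rare_gpos, :] *= config.rare_cell_fraction
    muscle_true = muscle_true * (1e6 / muscle_true.sum(axis=0, keepdims=True))
    profile_params = pd.DataFrame(
        muscle_true, index=gene_index, columns=np.arange(1, n_reg + 1),
    )
    truth = SyntheticTruth(
        cell_class=pd.Series(cell_class, index=cm.cell_ids, name="cell_class"),
        gene_label=labels,
        profile_params=profile_params,
    )
    return cm, truth


def write_simulation(
    cm: CountMatrix, truth: SyntheticTruth, config: SimConfig,
    out_dir: str | Path,
) -> None:
    """Write counts (MatrixMarket + TSVs), truth TSVs and the flat config."""
    out_dir = Path(out_dir)
    write_counts(cm, out_dir)
    truth.save(out_dir)
    config.save(out_dir / "sim_config.txt")


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr(
    n_genes: int,
    n_replicates: int,
    true_log2fc: Sequence[float],
    ct_noise_sd: float,
    seed: int,
    n_samples: int = 3,
) -> QPCRPlate:
    """Simulate a qPCR Ct table for target genes plus 3 housekeeping genes.

    Each condition (control / treatment) has ``n_samples`` biological samples
    with ``n_replicates`` technical replicates per gene.  Treatment target
    Ct values are shifted by -true_log2fc relative to control (one PCR cycle
    per doubling), so the ddCt estimator recovers ``true_log2fc`` in
    expectation; housekeeping genes are unshifted.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 technical replicates")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    if len(true_log2fc) != n_genes:
        raise ValueError("true_log2fc must have one value per gene")
    rng = np.random.default_rng(seed)
    targets = [f"target_{i}" for i in range(n_genes)]
    housekeeping = ["hk_1", "hk_2", "hk_3"]
    base_ct = {g: 22.0 + rng.uniform(-2, 2) for g in targets + housekeeping}

    rows = []
    sample_condition: dict[str, str] = {}
    for cond in ("control", "treatment"):
        for s in range(n_samples):
            sample = f"{cond}_{s + 1}"
            sample_condition[sample] = cond
            for g in housekeeping + targets:
                ct = base_ct[g]
                if cond == "treatment" and g in base_ct and g.startswith("target"):
                    shift = true_log2fc[targets.index(g)]
                    ct = ct - shift
                for rep in range(1, n_replicates + 1):
                    rows.append({
                        "gene": g, "sample": sample, "replicate": rep,
                        "ct": ct + rng.normal(0.0, ct_noise_sd),
                    })
    return QPCRPlate(
        table=pd.DataFrame(rows),
        housekeeping=tuple(housekeeping),
        sample_condition=sample_condition,
    )


# ---------------------------------------------------------------------------
# Expression-domain measurements


def simulate_domains(
    n_control: int,
    n_rnai: int,
    shift_fraction: float,
    noise_sd: float,
    seed: int,
    base_fraction: float = 0.4,
    mean_length_um: float = 2000.0,
    length_sd_um: float = 250.0,
) -> DomainTable:
    """Simulate per-animal body/domain length measurements.

    RNAi animals' normalized expression domain (domain / total length) is
    shifted by ``shift_fraction`` relative to controls; ``noise_sd`` is the
    per-animal SD of the normalized fraction.  Negative or degenerate draws
    are resampled (truncation) and logged.
    """
    if n_control < 1 or n_rnai < 0:
        raise ValueError("need at least one control animal")
    if not 0.0 <= shift_fraction <= 1.0:
        raise ValueError("shift_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    n_resampled = 0
    for cond, n, frac in (
        ("control", n_control, base_fraction),
        ("rnai", n_rnai, min(base_fraction + shift_fraction, 1.0)),
    ):
        for i in range(n):
            total = rng.normal(mean_length_um, length_sd_um)
            while total <= 0:
                n_resampled += 1
                total = rng.normal(mean_length_um, length_sd_um)
            f = frac + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            while not 0.0 < f <= 1.0:
                n_resampled += 1
                f = frac + rng.normal(0.0, noise_sd)
            rows.append({
                "animal": f"{cond}_{i + 1}", "condition": cond,
                "total_length_um": total, "domain_length_um": f * total,
            })
    if n_resampled:
        logger.info("resampled %d degenerate length draws", n_resampled)
    return DomainTable(table=pd.DataFrame(rows))
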