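# axialmrg

Identification of **muscle regionally expressed genes (mRGs)** — genes whose
expression within body-wall muscle is restricted to a domain of the
anterior–posterior (AP) body axis — from single-cell RNA-seq of cells
dissected from ordered axial regions (1 = head tip … 10 = tail tip), as in
planarian positional-information studies.

The package is aimed at computational biologists who have (or simulate) a
gene × cell count matrix with per-cell axial region labels and want a
tested, reproducible implementation of the full analysis:

1. **Preprocessing** — isotig collapse, rRNA/mitochondrial exclusion,
   library QC (discard cells with fewer than 1000 expressed (>2-read)
   transcripts), log₂(CPM + 1) normalization.
2. **Muscle-cell classification** — PCA on highly expressed
   (4 < mean log₂-CPM < 8), highly dispersed (var/mean > 1.2) genes with
   permutation significance, sign-oriented so a muscle marker (*troponin*)
   loads negatively; a cell is muscle iff PC1 < 0 **and** marker CPM > 4.
3. **Dropout-aware differential expression** over three axial contrasts
   (anterior 1–3 vs posterior 8–10; head 1 vs post-pharyngeal 7–9;
   pre-pharyngeal 2–4 vs tail 10).  Each cell gets an error model
   p_drop(e) = 1/(1+exp(θ₀+θ₁·log(e+1))): dropped transcripts yield
   background Poisson(λ₀) counts, detected ones negative binomial counts
   with mean e/10⁶·L_c and global dispersion φ.  Per gene and cell group a
   grid posterior over log₂ e gives a fold-change posterior by
   cross-correlation; Z = posterior mean/SD, and genes with |Z| > 2.58
   (tail p < 0.005) in **any** contrast are candidate mRGs.  A two-part
   "bimod" likelihood-ratio test and Student's t-test are provided for
   method comparison.
4. **Combination score** — with k contrasts, the minimum p-value of a null
   gene follows Beta(1, k), so genes are ranked by
   S_min = −ln(1 − (1 − p₍₁₎)ᵏ); classification of true regional genes by
   S_min is evaluated by ROC/AUC against validation labels.
5. **Region map** — per-region mean expression over muscle cells, row
   z-scores, complete-linkage Euclidean clustering of genes and regions
   (the region dendrogram should recapitulate the AP order).
6. **Downstream statistics** — ΔΔCt qPCR fold changes (3-gene housekeeping
   normalization, log₂FC = −ΔΔCt), normalized expression-domain lengths and
   cell counts, Fisher-exact RNAi synergy tests, one-way ANOVA with
   Monte-Carlo Dunnett comparisons, and prospective power calculations
   (Cohen's h for two proportions, Cohen's f with noncentral F for ANOVA).

A first-class **synthetic-data module** generates count matrices with known
ground truth — cell classes, marker genes, and mRGs drawn from the spatial
profile families seen along the axis (tip-restricted, graded, banded,
rare-cell, shallow, broad) — so every stage is benchmarked without external
data.  See `docs/methods.md` for the generative model and all defaults.

## Worked example

```python
from axialmrg.pipeline_cli import RunConfig, run_pipeline

out = run_pipeline(RunConfig(out_dir="demo_run", seed=7))
```

writes the full artifact set (QC report, PCA tables, per-contrast DE tables,
candidate table, ROC points, region profiles, Newick dendrograms, power
table) plus `manifest.json`, which for seed 7 records:

```
classify   variable_genes 19   muscle_cells 121
de         contrasts 3         phi 0.368
combine    flagged 174
roc        auc 0.995
regionmap  ap_order_concordance 0.988
```

Read: of 180 simulated cells, 121 pass the muscle gate; 174 of 4000 genes
exceed |Z| > 2.58 in at least one contrast; ranking all genes by S_min
separates the 44 planted regional genes from the rest with AUC 0.995; and
clustering regions by their expression profiles reproduces the anatomical
anterior→posterior order almost perfectly (|Spearman| 0.988 between leaf
order and axis position).

The same pipeline is exposed as a CLI:

```
axialmrg run --seed 7 --out-dir demo_run
axialmrg simulate --out-dir sim --seed 1
axialmrg qc sim --out-dir qc_out
axialmrg classify qc_out --out-dir cls
axialmrg de sim cls/cell_annotation.tsv --out-dir de_out
axialmrg combine de_out/*.tsv --out candidates.tsv
axialmrg stats power --family two_proportions -e 0.4
# -> total n (two equal groups) = 98.1
```

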