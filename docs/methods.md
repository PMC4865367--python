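# Methods

This note documents the models, defaults and design choices behind
`axialmrg`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis problem

Single cells are dissected from 10 ordered regions along the
anterior–posterior (AP) axis and sequenced.  The cell pool is a mixture of
body-wall muscle (the tissue of interest), neoblasts, epidermal-lineage
cells and others.  The goal is to find genes whose expression **within
muscle** is restricted to an axial domain (mRGs).  The pipeline therefore
(i) gates muscle cells, (ii) tests genes for regional differential
expression between groups of regions, (iii) combines the per-contrast
p-values into a single rank score, and (iv) summarizes the axial expression
map.

## Normalization and QC

Cells with fewer than 1000 expressed transcripts are discarded, where
"expressed" means strictly more than 2 reads; both thresholds are exposed
(`min_expressed`, `min_reads`).  Expression values are log₂(CPM + 1); the
pseudocount and log base are configurable.  rRNA/mitochondrial exclusion
(user-supplied ID list) and isotig collapse happen on raw counts *before*
CPM so that discarded reads never inflate the denominator.

## Muscle gating

Variable genes are those with 4 < mean log₂-CPM < 8 and dispersion > 1.2,
with dispersion defined as variance/mean of log-CPM across cells (the
conventional over-dispersion ratio; configurable).  PCA is fit on centered,
unit-scaled variable-gene values; loadings are extended to all genes by
projecting each gene's standardized profile onto the unit-norm component
scores.  Because an SVD's component signs are arbitrary, each component is
oriented so the designated marker gene (*troponin* by default) loads
negatively — muscle cells then sit at PC1 < 0.  Component significance uses
a permutation null (each gene's values permuted independently across cells;
p = (1 + #{null ≥ observed})/(n_perm + 1); 100 permutations by default).
The muscle call requires both PC1 < 0 and marker CPM > 4 (linear CPM scale).
Cells with an expressed-transcript count above the 99th percentile are
flagged as putative doublets but not removed.

## Dropout-aware differential expression

The error model treats each observed count as a two-component mixture:
with probability p_drop(e) the transcript dropped out and the count is
background Poisson(λ₀ = 0.1); otherwise it is negative binomial with mean
e/10⁶ · L_c (e = true CPM, L_c = the cell's total counts) and variance
μ + φμ².  Dropout probability is logistic in log-expression,
p_drop(e) = 1/(1 + exp(θ₀ + θ₁·log(e+1))) with θ₁ ≥ 0, so it decreases with
expression.

**Fitting.**  For each cell, a reference expression per gene is the
20%-trimmed mean of CPM over the *other* cells; (θ₀, θ₁) maximize the
Bernoulli likelihood of the detection indicator where the zero probability
includes *both* mixture components — modelling P(zero) as
p_drop·e^(−λ₀) + (1−p_drop)·NB(0; μ, φ) is essential, because at low
expression most zeros are NB sampling zeros and a plain logistic fit would
absorb them into the dropout curve.  φ is a single global method-of-moments
estimate over detected counts (restricted to entries with expected count
> 0.25, below which squared residuals carry no dispersion information).
Because the observed mean expression of a gene is itself depressed by
dropout, fitting iterates (3 rounds by default): after each round the
reference expression is re-estimated as the leave-one-out grid MLE under
the current mixture model (computed in two passes so memory stays at
genes × grid).  On simulated data with strong dropout (θ₀ = −2, θ₁ = 1.5)
this recovers both parameters within 25% relative error at 2,000 genes and
60 cells (see `test_dropout_model_parameter_recovery`).

**Testing.**  Per gene and cell group, a posterior over a log₂-expression
grid (301 points on [0, 15], uniform prior) is the normalized product of
per-cell mixture likelihoods.  The log₂ fold-change (group A − group B)
posterior is the discrete cross-correlation of the two group posteriors;
the reported fold change is its mode (ties resolved toward 0), Z is its
mean/SD, and p the two-sided normal tail of Z.  Genes undetected in every
cell of both groups are flagged with Z = 0, p = 1.  The primary
significance call is |Z| > 2.58 (tail p < 0.005) in any contrast, on
*uncorrected* Z; Benjamini–Hochberg-adjusted values (cZ) are reported
alongside.  Positive fold change / Z means enrichment in the first-named
(more anterior) group.

Two comparison methods share the interface: a two-part likelihood-ratio
test (binomial detection fraction + normal mean of detected log-CPM with
pooled variance, χ² with df = number of estimable parts) and Student's
equal-variance t-test with Z defined as the signed normal quantile of the
two-sided p.

## Combination score and ROC

With k independent contrasts and no regional expression, the minimum
p-value follows Beta(1, k); the rank score is
S_min = −ln(1 − (1 − p₍₁₎)ᵏ), computed via log1p/expm1 so small p do not
underflow.  Natural log is used (any base gives the same ranking).
Uncorrected per-contrast p-values enter S_min.  S_min is a *ranking*
statistic, not an adjusted p-value, and no combined p-value is reported.
ROC curves sweep distinct score values descending (ties share one step);
AUC is the trapezoid area and equals the normalized Mann–Whitney U.

## Region map

Per-region profiles are arithmetic means of log-CPM over the muscle cells
of each region.  Rows are z-scored with the sample (n−1) SD — matching the
common heatmap-scaling convention — and constant rows are zeroed and
flagged.  Genes and regions are clustered by complete-linkage agglomerative
clustering on Euclidean distance.  Leaves are arranged by optimal leaf
ordering (minimum sum of adjacent leaf distances): a dendrogram's branch
rotations are arbitrary, and without this step even noise-free, perfectly
graded profiles produce a scrambled leaf sequence, so leaf order would
carry no information about the axis.  Axial-order recovery is scored as the
absolute Spearman correlation between region leaf order and anatomical
order (absolute, because reversing a dendrogram is meaningless).

## Downstream statistics

* **ΔΔCt** — technical replicates averaged; ΔCt subtracts the mean of three
  housekeeping genes within the sample (removing sample-wide offsets);
  ΔΔCt subtracts the mean control ΔCt; log₂FC = −ΔΔCt (one fewer cycle to
  threshold = twice the transcript).
* **Measurement normalization** — expression-domain length / body length
  (dimensionless), or cell count / reference length (per µm).
* **Fisher exact** — two-sided by summing hypergeometric probabilities ≤
  the observed table's (1e-7 relative tie tolerance); delegated to
  `scipy.stats.fisher_exact` and cross-checked against an enumeration
  oracle in the tests.
* **ANOVA / Dunnett** — standard one-way F; many-to-one comparisons use
  pooled-variance t statistics with a family-wise adjustment obtained by
  Monte-Carlo sampling (default 10⁵ draws, seeded) of max|t| under the
  joint null with the balanced many-to-one correlation structure; verified
  against `scipy.stats.dunnett` in the tests.  Two-sided comparisons are
  assumed.
* **Power** — two proportions: per-group n = (z₁₋α/₂ + z_power)²/h²,
  reported as the **total** over two equal groups (98.1 for h = 0.4, 24.5
  for h = 0.8 at α = 0.05, power 0.8); the printed convention matches the
  closed form only as a two-group total, so that convention is documented
  rather than silently assumed.  Balanced ANOVA: smallest real n ≥ 2 with
  noncentral-F power ≥ target, λ = k·n·f², df = (k−1, k(n−1)), solved by
  bracketed root-finding to 1e-4 and reported to one decimal (5.3 for
  k = 4, 6.1 for k = 3 at f = 0.8).

## Synthetic data

`simulate_axis_counts` emulates the study design: 10 regions ×
18 cells/region (~180 cells), class proportions 65% muscle / 15% neoblast /
14% epidermal / 6% other, lognormal library sizes (ln-mean 12.97 ≈ 430k
reads, ln-SD 0.35), and 4,000 genes: 4 class markers (e.g. *troponin* at
200 CPM in muscle only), 40 class-program genes per class (8-fold elevated
in their class, giving the PCA its structure), 44 mRGs split across the
profile families (6 tip-restricted, 8 anterior-graded, 8 posterior-graded,
8 banded, 6 rare-cell, 4 shallow, 4 broad), and baseline genes with
lognormal CPM (ln-SD 1.2).  Each cell's true CPM vector is normalized to
10⁶, then counts are drawn from the same dropout + NB mixture the error
model assumes (dropout midpoint 2.0 and slope 1.0 on log(e+1); NB
dispersion 0.4; background Poisson 0.1).  The dropout midpoint was set so a
cell expresses ~3,400–3,500 (>2-read) transcripts, the order of magnitude
reported for such libraries; real per-gene dropout rates and library-size
distributions are not published for this design, so these two parameters
are order-of-magnitude choices, fixed once.  Rare-cell genes are expressed
in a random 20% of muscle cells within their domain.  Broad domains span
8–9 of 10 regions (a 10-region domain would be non-regional), so at least
one terminal region lies outside the domain and the axial contrasts can in
principle detect every planted gene.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, gene–gene correlation beyond the class programs, UMI chemistry, and
cell-to-cell capture-efficiency variation (s_c ≡ 1; library-size variation
enters only through L_c, keeping e identifiable).  Passing benchmarks on
this generator therefore demonstrate internal consistency and statistical
calibration of the method, not performance on real data with those
artifacts.

`simulate_qpcr` builds Ct plates (3 housekeeping genes, ≥2 technical
replicates, configurable biological samples per condition) in which one PCR
cycle equals one doubling, so ΔΔCt recovers the programmed log₂ fold change
in expectation.  `simulate_domains` draws per-animal body lengths
(N(2000, 250) µm, truncated positive) and normalized domain fractions
(control 0.4) with the RNAi condition shifted by a programmed fraction;
degenerate draws are resampled and logged.

## Numerical choices and degenerate inputs

Grid posteriors use 301 points on log₂ e ∈ [0, 15] (CPM 1…32768); the
reference-expression grid inside the error-model fit extends to 2²⁰ CPM so
extreme genes are not truncated (truncation there visibly biases φ).
Fold-change posterior ties are resolved toward zero.  Zero posterior SD,
zero pooled variance, all-zero genes, constant z-score rows, single-class
ROC labels, zero-total cells and empty variable-gene selections all raise
or flag explicitly rather than propagating NaNs.  All stochastic steps
(simulation, permutation tests, Monte-Carlo Dunnett) take explicit seeds;
the pipeline derives per-stage seeds from one master seed, and identical
configurations are byte-identical on rerun.

## Problem sizes

Defaults were chosen so the full synthetic pipeline (4,000 genes, 180
cells, three contrasts) completes in ~25 s on one CPU, and the complete
test suite — including 10-seed classification/concordance benchmarks and
the parameter-recovery and rare-cell power-ordering simulations — in a few
minutes.  Benchmarks that need many replicates (rare-cell AUC ordering,
parameter recovery) run at reduced size (1,000–2,000 genes, 60–120 cells)
with seeds fixed in the tests.

## Known limitations

* The dropout DE model is a fully specified, simplified analog of published
  Bayesian single-cell DE methods (grid posterior, uniform prior, global φ,
  no cross-fitting of cell pairs); its per-gene numbers are not expected to
  match any particular published implementation.
* The Z statistic is a posterior summary (mean/SD), not a frequentist test
  statistic; its null calibration is verified empirically (|Z| > 2.58 rate
  ≤ 2% on null genes) rather than guaranteed analytically.
* φ is global; strongly gene-specific overdispersion would be absorbed
  partly into dropout estimates.
* Muscle gating assumes one dominant marker; co-expression gates (e.g.
  *collagen*) can be emulated by rerunning with a different `marker_id`.
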