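# Methods

This note documents the models and procedures implemented in `naristat`,
the parameter choices that matter, and what the synthetic benchmarks do
and do not demonstrate about real data.

## The synthetic generator

All counts are negative binomial with a mean/dispersion parameterization,
variance = μ + μ²/θ, drawn as a gamma–Poisson mixture.  This is the
standard count model for RNA-seq; θ (default 10) sets biological
overdispersion on top of Poisson sampling (θ → ∞ recovers Poisson).
Identical configurations, including the seed, produce bit-identical
outputs; all draws come from one `numpy` PCG64 stream per dataset.

### Single-cell naris-occlusion design

Each simulated mOSN carries one true OR.  Default conditions:

| parameter | default | meaning |
|---|---|---|
| `n_or_genes` | 60 | OR repertoire size (`OrS0001`…) |
| `resistant_or_fraction` | 10/60 | ORs whose cells ignore occlusion |
| `cells_per_or_per_naris` | 40 | balanced open/closed design |
| `or_dominant_mean` / `or_leak_mean` | 50 / 0.1 | transcripts of the chosen vs non-chosen ORs |
| `n_activity_genes` | 5 | the activity program, named *S100a5*, *Dlg2*, *Pcp4l1*, *Kirrel2*, *Lrrc3b* |
| `activity_mean` | 2.0 | baseline activity-gene transcripts/cell |
| `sensor_mean` | 1.0 | baseline *Rhbdf2* (iRhom2) transcripts/cell |
| `occlusion_effect` | −1.0 | natural-log shift of activity genes in closed-naris cells |
| `sensor_effect` | +1.0 | natural-log shift of the sensor gene, opposite sign |
| `n_background_genes` | 500 | uninvolved transcriptome |
| `nb_mean_background`, `background_mean_sigma` | 1.5, 1.0 | lognormal spread of background baselines |
| `n_mito_genes`, `mito_mean` | 10, 5.0 | `mt-` genes feeding the regression covariate |

Closed-naris cells of responsive ORs have activity-gene means multiplied
by exp(occlusion_effect) and the sensor mean by exp(sensor_effect);
resistant ORs keep multipliers of exactly 1 (effect heterogeneity is not
simulated).  The anticorrelation between sensor and activity genes is
therefore condition-linked (opposite-sign mean shifts), not a cell-level
latent variable — the simplest structure the stratification stage must be
able to recover.

No occlusion effect size is an estimate of real tissue: the magnitudes
are free parameters chosen so that per-cell counts remain in a realistic
few-transcripts regime while the planted contrast is recoverable at the
default sample sizes.  Background baselines are spread lognormally
because mean-binned HVG selection is only meaningful when expression
spans a range — a homogeneous background would make every bin degenerate.

Two deliberate idealizations follow from the design.  First, the naris
design is exactly balanced per OR, so the OR population-shift statistic
is centered at zero for *all* ORs up to assignment noise; the benchmark
checks that resistant ORs show no shift, but a real deprivation-driven
abundance loss is not simulated.  Second, maturation trajectories,
doublets, ambient RNA and batch effects are all absent, so passing tests
demonstrate correctness of the statistics, not robustness to those
artifacts.

A companion odor-exposure dataset (odor vs solvent, 200 cells/group)
halves the sensor mean and doubles activity means in the odor group,
emulating acute activation.

### Bulk WT/KO design

Genes share the single-cell roster; baselines are log-uniform in
[5, 500] expected counts.  Exactly `bulk_n_up` (14) OR genes are
up-shifted and `bulk_n_down` (16) down-shifted by `bulk_logfc` (1.5 log₂)
in the KO genotype, across 12 replicates per genotype split over ages
5/8/10/30 weeks (3 per age per genotype).  Per-OR effects drift with age:
one gene-level Gaussian perturbation (sd `bulk_age_drift_sd`, log₂) is
shared by ages 5 and 8, an independent one applies at 30 weeks, and age
10 uses their midpoint — so fold changes correlate more strongly between
neighbouring ages.  The default sd of 0.5 keeps the pooled 12 v 12
contrast at essentially full strength; setting it to ~2 makes the drift
dominate the shared effect, which is the regime used to demonstrate the
adjacent-vs-distant age-correlation ordering.  A planted
"occlusion-responsive" program (30 background genes, +1 log₂ in KO) and a
size-matched untouched control set are recorded for gene-set benchmarks.

## Preprocessing

The chain is the standard scRNA-seq workflow: QC → depth normalization →
log1p → HVG selection → covariate regression → scaling → PCA.

- **QC** is a single pass on the original matrix (cells with ≥200
  detected genes, genes detected in ≥3 cells), not iterated to a fixed
  point; iteration changes almost nothing on realistic data and a single
  pass is order-independent and easy to reason about.
- **Normalization** scales each cell to 10⁴ counts before ln(1+x).
- **HVG selection** computes mean and dispersion (variance/mean) on
  back-transformed normalized counts, log-transforms both (log1p for the
  mean), bins genes into 20 equal-width mean bins and z-scores the log
  dispersion within each bin.  The default thresholds (mean in
  (0.0125, 3), normalized dispersion > 0.5) are defined on this log
  scale, the convention of the toolkit they originate from; a bin with a
  single gene or zero spread falls back to scaling by the bin mean, so a
  lone gene cannot select itself.  On defaults this retains the OR genes
  (hypervariable across cells by construction), the activity program and
  the sensor gene, plus the most variable background genes.
- **Regression** removes total counts and mitochondrial fraction per gene
  by OLS on centered covariates, returning residuals plus the fitted
  intercept; centering makes the intercept the mean prediction, so
  per-gene means are preserved exactly.  A constant covariate (e.g. no
  `mt-` genes) is dropped with a log note rather than producing a
  rank-deficient design.
- **Scaling** z-scores each gene with population sd (ddof 0), maps
  zero-variance genes to zero and clips at ±10.
- **PCA** takes the top 40 right singular vectors of the centered HVG
  matrix; explained variances are singular values squared over (n−1),
  matching a covariance eigendecomposition.  Sign is fixed by forcing the
  largest-magnitude loading of each component positive, which makes
  repeated runs bit-identical.  If 40 exceeds the matrix rank the number
  of components is reduced with a logged warning.  Euclidean distances
  downstream use all retained components.

Neighbour-graph clustering and 2-D embeddings are intentionally out of
scope: their layouts are not deterministic across library versions and no
statistic here depends on them.

## Occlusion statistics

Pair matching takes the full Cartesian product of confidently assigned
open × closed cells per OR, capped at 10⁴ pairs per OR by uniform
seeded subsampling (the product is O(n²); the cap bounds memory and the
subsample median is stable to within a few percent at ≥10³ pairs).
Per-pair gene fold changes are log₂((1+e꜀)/(1+eₒ)) on back-transformed
normalized expression — reported in log₂ because that is the figure
convention for fold changes.

Pairs within an OR reuse cells and are not independent, so group
comparisons (resistant vs responsive, KO⁺ vs KO⁻ vs na) aggregate to one
median per OR before the two-sided Mann–Whitney test; the pooled per-pair
table is still written for inspection.  Mann–Whitney is used for all
two-group expression comparisons in the package: it is exact at small n,
invariant to monotone transforms, and makes no normality assumption.

The population shift per OR is raw = log1p(n_closed) − log1p(n_open);
log1p keeps zero-count nares finite.  To compare across ORs of very
different abundance the raw shift is multiplied by the OR's share of all
assigned cells and rescaled by the number of ORs, so an OR of average
abundance keeps its raw value.  This weighting is one reasonable choice
among several; the unweighted statistic is available via `--no-weight`
and the chosen formula is stated in the output headers.

OR classes come from a bulk DE table: KO⁺ if FDR < 0.05 with positive
log fold change in the knockout, KO⁻ if negative, otherwise na.

## Stratification and gene sets

Five strata: stratum 0 is exactly the cells with zero raw sensor counts
("no detectable" expression); nonzero cells are cut at the quartiles of
the nonzero count distribution, with equal counts always sharing a
stratum (boundaries move to the next distinct count).  The split count is
exposed (`nonzero_bins`) because raw counts are small integers and the
effective number of distinct strata depends on the data.

Enrichment of the zero-sensor stratum tests each gene against all other
cells (two-sided Mann–Whitney on normalized expression), with BH
correction across genes and ranking by p then |log₂ fold change| of the
(1+mean) ratio.  Gene-set scores are unweighted means — per cell over
normalized expression, or per gene over bulk log fold changes — without
background-matched control bins; the bulk benchmark therefore compares
against an explicit size-matched control set.

## Bulk differential expression

Counts become log₂ CPM with a 0.5 prior count (prior added to counts and
twice the prior to library sizes, so zeros stay finite); each gene is
tested KO vs WT with a Welch two-sample t-test and BH-corrected within
the declared universe (all genes, or OR genes only — the latter matters
for per-age contrasts, where 3 v 3 samples have no power against a
genome-wide correction).  Library sizes always come from the full matrix;
the universe restricts only which genes are tested and corrected.

This stage deliberately does not reproduce TMM normalization or
negative-binomial GLMs: the benchmarks are parameter recovery on
synthetic data, where Welch-on-log-CPM is well calibrated (the global
null keeps the p < 0.05 fraction at ~0.05 across 20 datasets) and
recovers 1.5-log₂ effects at 12 v 12 with >90% sensitivity.  Genes with
zero variance in both groups receive p = 1.

Cross-age correlation is the Pearson matrix of per-age log fold changes
over the union (default; intersection available) of ORs significant at
any age.

## Numerical conventions and degenerate inputs

- Natural log for normalized expression; log₂ for all reported fold
  changes; conversions happen at the statistic, never by rescaling stored
  matrices.
- Benjamini–Hochberg is the exact step-up: adjᵢ = min over j ≥ i of
  p₍ⱼ₎·n/j on the ascending sort, clipped at 1, stable (mergesort) order.
- Readers reject malformed input (dimension mismatches, negative or
  non-integer counts, unknown metadata levels) instead of coercing.
- Empty designs are errors with named offenders: cells with zero totals,
  all-zero sensor genes, ORs with no cells in one naris (skipped and
  logged), groups with fewer than 2 ORs (p reported as NA).
- MatrixMarket files are 1-based genes × cells; all in-memory indexing is
  0-based cells × genes; the conversion lives only in the IO module.

## Benchmark problem sizes

The shipped tests and the acceptance script run the single-cell pipeline
at 60 ORs × 80 cells (4800 cells × 576 genes), deconvolution at 20 ORs ×
200 cells, bulk recovery at 576 genes × 24 samples, and the null
calibration over 20 × 200-gene datasets — sizes chosen so the full suite
completes in minutes on one core while keeping every planted contrast
comfortably detectable.

## Known limitations

- The generator's effects are homogeneous within gene class; there is no
  per-cell latent activity state, so recovery results bound what the
  statistics can do under ideal, not realistic, noise.
- The population-shift statistic is exercised only under a balanced
  design (see above).
- HVG selection follows one specific dispersion-normalization convention;
  other flavors (e.g. variance-stabilized selection) would retain
  somewhat different gene sets.
- The simplified DE stage is not a substitute for count-model DE when the
  goal is analyzing a real bulk experiment with few replicates.
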