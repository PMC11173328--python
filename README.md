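# naristat

Statistics for activity-dependent gene regulation in olfactory sensory
neurons (OSNs), from single-cell and bulk RNA-seq.

Each mature OSN (mOSN) expresses a single olfactory receptor (OR) out of a
repertoire of ~1200 mouse OR genes, and odor stimulation sculpts both the
OSN transcriptome and the abundance of OR-defined OSN populations.  A
classic experimental probe is unilateral naris occlusion: comparing mOSNs
from the open (stimulated) and closed (deprived) nostril reveals an
activity program (*S100a5*, *Dlg2*, *Pcp4l1*, *Kirrel2*, *Lrrc3b*) that is
suppressed by deprivation, a sensor gene (iRhom2 / *Rhbdf2*) that moves in
the opposite direction, and OR subsets that differ in how strongly their
host OSNs respond.  `naristat` packages the analyses used to quantify this
regulation, for computational biologists who want a tested, reproducible
implementation that runs end to end on fully ground-truthed synthetic data.

## What it computes

- **OR deconvolution** — per mOSN, the dominant OR on raw counts
  (argmax over OR genes; lexicographic tie-break, confidence flags).
- **Preprocessing** — QC (≥200 genes/cell, ≥3 cells/gene), depth
  normalization to 10⁴ + log1p, mean-binned highly-variable-gene
  selection, regression of total counts and mitochondrial fraction,
  z-scaling, and PCA (40 components, deterministic sign convention).
- **Naris-occlusion pair statistics** — for each OR, all open×closed cell
  pairs; per pair the Euclidean distance in PC space
  d(o,c) = √Σₖ(xₒₖ−x꜀ₖ)² (a readout of overall transcriptomic change) and
  per-gene log₂((1+e꜀)/(1+eₒ)) fold changes on normalized expression; a
  per-OR population shift log1p(n꜀) − log1p(nₒ), weighted by the OR's
  share of assigned cells; Mann–Whitney comparisons of per-OR medians
  between OR classes (e.g. knockout-enriched KO⁺ vs depleted KO⁻).
- **Sensor stratification** — five strata by raw sensor-gene counts
  (stratum 0 = no detectable transcripts, quartiles of the nonzero cells),
  Mann–Whitney enrichment ranking of the zero-sensor stratum with
  Benjamini–Hochberg correction, and odor-vs-solvent exposure tests.
- **Gene-set scoring** — unweighted mean scores per cell (normalized
  expression) or per gene (bulk log fold change), with rank-based group
  tests.
- **Simplified bulk differential expression** — log₂-CPM (prior count
  0.5), per-gene Welch t of knockout vs wild type, BH-FDR within a
  declared gene universe (all genes or ORs only), per-age contrasts and
  cross-age Pearson correlation of OR fold changes.
- **Synthetic data** — a negative-binomial (mean/dispersion) generator
  producing naris-occlusion single-cell data, odor-exposure data and bulk
  WT/KO designs with complete ground truth, so every stage above is
  testable without downloading anything.

## Worked example

```python
import naristat as ns

cfg = ns.SimConfig(seed=1)                  # 60 ORs, 10 resistant
cm, meta, truth = ns.generate_sc_dataset(cfg)
prep = ns.run_preprocess(cm)

or_genes = [g for g in cm.gene_ids if str(g).startswith("OrS")]
assignments = ns.assign_or(cm, or_genes)
print(ns.assignment_accuracy(assignments, truth.cells))

pairs = ns.match_pairs(assignments, meta, seed=1)
pairs = ns.pairwise_euclidean(prep.embedding, pairs)
pairs = ns.pairwise_gene_logfc(prep.norm, pairs, ["S100a5"])
summary = ns.per_or_summary(pairs, truth.or_classes)
tests = ns.compare_groups(summary["median_euclid_dist"], summary["or_class"])
```

This prints an OR assignment accuracy of `1.0000` (4800 cells, 576 genes,
107 HVGs, 40 PCs), and the per-OR medians split by planted class:

```
            median_euclid_dist  median_logfc_S100a5
or_class
resistant                7.683               -0.016
responsive               7.929               -1.430
distance Mann-Whitney p = 3.99e-06
```

Responsive ORs sit further from their deprived counterparts in PC space
and lose *S100a5* expression (−1.43 log₂ per pair), while the planted
occlusion-resistant ORs barely move — the statistic the pair machinery is
designed to expose.

The same pipeline is available from the shell:

```sh
naristat simulate --config config.yml --out sim/
naristat preprocess --matrix sim/matrix.mtx --genes sim/genes.tsv \
    --cells sim/cells.tsv --out prep/
naristat assign-or --matrix sim/matrix.mtx --genes sim/genes.tsv \
    --cells sim/cells.tsv --out assign/
naristat occlusion --assignments assign/or_assignment.tsv --meta sim/meta.tsv \
    --pca prep/pca_coords.tsv --norm prep/norm.tsv --gene S100a5 --out occl/
```

Outputs are plain TSV tables plus a `run.log` recording configuration,
seed, library versions and row counts; identical inputs reproduce every
table byte for byte.

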