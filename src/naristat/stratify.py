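"""Sensor-gene stratification, enrichment ranking, odor-exposure tests and
gene-set scoring.

Cells are split into five strata by raw counts of a sensor gene (iRhom2 /
Rhbdf2 by default): stratum 0 holds cells with zero transcripts and the
nonzero cells are cut at quantile boundaries into four further strata,
with equal counts always landing in the same stratum.  Genes enriched in
the zero-sensor stratum are ranked by two-sided Mann-Whitney tests with
Benjamini-Hochberg correction; the top ranks are expected to recover the
known OSN activity program.  Gene-set scores are unweighted means, either
per cell on normalized expression or per gene on bulk log fold changes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .bulk import bh_fdr
from .io import CountMatrix, GeneSet
from .preprocess import NormMatrix

logger = logging.getLogger(__name__)


def stratify_by_gene(
    counts: CountMatrix, gene: str = "Rhbdf2", nonzero_bins: int = 4
) -> pd.DataFrame:
    """Ordinal strata 0..nonzero_bins from raw counts of one gene.

    Stratum 0 is exactly the zero-count cells.  Nonzero cells are split at
    raw-count quantile boundaries; because assignment is by count value,
    ties always share a stratum (boundaries effectively move to the next
    distinct count).  Degenerate distributions collapse to fewer strata
    with a logged warning.
    """
    if nonzero_bins < 1:
        raise ValueError("nonzero_bins must be >= 1")
    col = counts.gene_index([gene])[0]
    vec = np.asarray(counts.counts[:, [col]].todense()).ravel()
    if vec.sum() == 0:
        raise ValueError(f"gene not detected: {gene!r} has zero counts in all cells")
    nonzero = vec[vec > 0]
    qs = np.linspace(0, 1, nonzero_bins + 1)[1:-1]
    edges = np.unique(np.quantile(nonzero, qs)) if qs.size else np.array([])
    if len(np.unique(nonzero)) == 1:
        logger.warning(
            "all nonzero counts of %s are equal; single nonzero stratum", gene
        )
    strata = np.zeros(len(vec), dtype=int)
    pos = vec > 0
    # stratum = 1 + number of quantile boundaries strictly below the count
    strata[pos] = 1 + np.searchsorted(edges, vec[pos], side="left")
    return pd.DataFrame({"cell_id": counts.cell_ids, "stratum": strata})


def rank_enriched_genes(
    norm: NormMatrix, strata: pd.DataFrame, reference_stratum: int = 0
) -> pd.DataFrame:
    """Genes enriched in one stratum versus all other cells.

    Per gene: two-sided Mann-Whitney U of the reference-stratum cells
    against the rest on normalized expression, log2 fold change of
    (1 + mean) back-transformed expression, BH-FDR across genes, and rank
    by ascending p then descending absolute fold change.
    """
    order = strata.set_index("cell_id").loc[list(norm.cell_ids), "stratum"].to_numpy()
    ref = order == reference_stratum
    if ref.sum() < 3:
        raise ValueError(
            f"reference stratum {reference_stratum} has {int(ref.sum())} cells (< 3)"
        )
    if (~ref).sum() < 1:
        raise ValueError("no cells outside the reference stratum")
    a = norm.values[ref]
    b = norm.values[~ref]
    _u, p = stats.mannwhitneyu(a, b, alternative="two-sided", axis=0)
    p = np.asarray(p, dtype=float)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    e_ref = np.expm1(a).mean(axis=0)
    e_rest = np.expm1(b).mean(axis=0)
    logfc = np.log2((1.0 + e_ref) / (1.0 + e_rest))
    out = pd.DataFrame(
        {"gene": norm.gene_ids, "logfc": logfc, "p": p, "fdr": bh_fdr(p)}
    )
    out = out.sort_values(
        ["p", "logfc"], key=lambda s: s if s.name == "p" else -s.abs()
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def exposure_response_test(
    norm: NormMatrix, condition: pd.Series, gene: str
) -> dict:
    """Odor vs solvent comparison of one gene's normalized expression.

    Returns group medians and the two-sided Mann-Whitney p-value.
    """
    condition = pd.Series(np.asarray(condition, dtype=object))
    bad = set(condition.unique()) - {"odor", "solvent"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    col = norm.gene_index([gene])[0]
    vec = norm.values[:, col]
    odor = vec[condition.to_numpy() == "odor"]
    solvent = vec[condition.to_numpy() == "solvent"]
    if len(odor) == 0 or len(solvent) == 0:
        raise ValueError("both condition groups must be nonempty")
    _u, p = stats.mannwhitneyu(odor, solvent, alternative="two-sided")
    return {
        "gene": gene,
        "median_odor": float(np.median(odor)),
        "median_solvent": float(np.median(solvent)),
        "p_value": float(p),
    }


def score_cells(norm: NormMatrix, gene_set: GeneSet) -> pd.Series:
    """Per-cell score: mean normalized expression over the set's genes.

    Genes missing from the matrix are logged and ignored; an empty
    intersection is an error.
    """
    present = [g for g in sorted(gene_set.gene_ids) if g in set(norm.gene_ids)]
    missing = sorted(gene_set.gene_ids - set(present))
    if missing:
        logger.info("gene set %s: %d genes absent from data", gene_set.name, len(missing))
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the data")
    cols = norm.gene_index(present)
    return pd.Series(
        norm.values[:, cols].mean(axis=1), index=norm.cell_ids, name=gene_set.name
    )


def score_logfc(de: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-gene bulk log fold changes restricted to the set's genes."""
    table = de.set_index("gene")["logfc"]
    present = [g for g in sorted(gene_set.gene_ids) if g in table.index]
    missing = sorted(gene_set.gene_ids - set(present))
    if missing:
        logger.info("gene set %s: %d genes absent from DE table", gene_set.name, len(missing))
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the DE table")
    return table.loc[present].rename(gene_set.name)


def compare_score_groups(scores: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney between per-cell score groups."""
    groups = pd.Series(np.asarray(groups, dtype=object), index=scores.index)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    a = scores[groups == labels[0]].to_numpy()
    b = scores[groups == labels[1]].to_numpy()
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return pd.DataFrame(
        [
            {
                "group_a": labels[0],
                "group_b": labels[1],
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "u_stat": float(u),
                "p_value": float(p),
            }
        ]
    )


def compare_logfc_sets(de: pd.DataFrame, set_a: GeneSet, set_b: GeneSet) -> dict:
    """Are one set's bulk fold changes shifted relative to another's?"""
    a = score_logfc(de, set_a).to_numpy()
    b = score_logfc(de, set_b).to_numpy()
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "set_a": set_a.name,
        "set_b": set_b.name,
        "n_a": len(a),
        "n_b": len(b),
        "mean_logfc_a": float(a.mean()),
        "mean_logfc_b": float(b.mean()),
        "u_stat": float(u),
        "p_value": float(p),
    }


def score_gene_set(data, gene_set: GeneSet, grouping=None):
    """Dispatch: per-cell scores for a NormMatrix, per-gene fold changes
    for a DE table.  With ``grouping`` a group comparison is returned
    alongside the scores."""
    if isinstance(data, NormMatrix):
        scores = score_cells(data, gene_set)
        if grouping is not None:
            return scores, compare_score_groups(scores, grouping)
        return scores
    if isinstance(data, pd.DataFrame) and {"gene", "logfc"} <= set(data.columns):
        scores = score_logfc(data, gene_set)
        if grouping is not None:
            if not isinstance(grouping, GeneSet):
                raise TypeError("grouping for a DE table must be a background GeneSet")
            return scores, compare_logfc_sets(data, gene_set, grouping)
        return scores
    raise TypeError("data must be a NormMatrix or a DE table with gene/logfc columns")
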