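"""OR-matched open/closed-naris statistics.

For every OR with confidently assigned cells in both nares, all open x
closed cell pairs are formed (optionally capped by uniform subsampling).
Each pair yields a Euclidean distance in PC space -- a readout of overall
transcriptomic change under odor deprivation -- and per-gene log2 fold
changes on back-transformed normalized expression.  A per-OR population
shift statistic, log1p(n_closed) - log1p(n_open) weighted by the OR's
share of all assigned cells, summarizes abundance changes of the OR
repertoire.  ORs are classified KO+/KO-/na from a bulk differential
expression table, and per-OR summary values are compared between classes
with two-sided Mann-Whitney tests.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormMatrix, PCAEmbedding

logger = logging.getLogger(__name__)


def match_pairs(
    assignments: pd.DataFrame,
    meta: pd.DataFrame,
    max_pairs_per_or: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cartesian product of open x closed cells per OR.

    ``assignments`` must already be confident-filtered (rows with
    ``confident`` False are dropped here for safety).  ORs with zero cells
    in either naris are skipped and logged.  If an OR's product exceeds
    ``max_pairs_per_or``, a uniform subsample of that size is drawn with
    the given seed.  Returns columns or_id, open_cell, closed_cell.
    """
    rng = np.random.default_rng(seed)
    if "confident" in assignments.columns:
        assignments = assignments.loc[assignments["confident"]]
    merged = assignments.merge(meta[["cell_id", "naris"]], on="cell_id", how="inner")
    rows = []
    for or_id in sorted(merged["assigned_or"].unique()):
        sub = merged.loc[merged["assigned_or"] == or_id]
        open_cells = np.sort(sub.loc[sub["naris"] == "open", "cell_id"].to_numpy())
        closed_cells = np.sort(sub.loc[sub["naris"] == "closed", "cell_id"].to_numpy())
        n_o, n_c = len(open_cells), len(closed_cells)
        if n_o == 0 or n_c == 0:
            logger.info(
                "skipping OR %s: %d open, %d closed cells", or_id, n_o, n_c
            )
            continue
        total = n_o * n_c
        if total > max_pairs_per_or:
            idx = np.sort(rng.choice(total, size=max_pairs_per_or, replace=False))
        else:
            idx = np.arange(total)
        rows.append(
            pd.DataFrame(
                {
                    "or_id": or_id,
                    "open_cell": open_cells[idx // n_c],
                    "closed_cell": closed_cells[idx % n_c],
                }
            )
        )
    if not rows:
        raise ValueError("no matchable ORs: every OR lacks cells in one naris")
    return pd.concat(rows, ignore_index=True)


def pairwise_euclidean(embedding: PCAEmbedding, pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach the PC-space Euclidean distance to each pair."""
    open_rows = embedding.rows_for(pairs["open_cell"])
    closed_rows = embedding.rows_for(pairs["closed_cell"])
    diff = embedding.coordinates[open_rows] - embedding.coordinates[closed_rows]
    out = pairs.copy()
    out["euclid_dist"] = np.sqrt((diff**2).sum(axis=1))
    return out


def pairwise_gene_logfc(
    norm: NormMatrix, pairs: pd.DataFrame, genes
) -> pd.DataFrame:
    """Per-pair log2 fold change of each gene, closed over open.

    Expression is back-transformed to normalized counts (exp(value) - 1)
    and compared as log2((1 + e_closed) / (1 + e_open)).
    """
    genes = list(genes)
    cols = norm.gene_index(genes)
    lookup = {c: i for i, c in enumerate(norm.cell_ids)}
    missing = [
        c
        for c in itertools.chain(pairs["open_cell"], pairs["closed_cell"])
        if c not in lookup
    ]
    if missing:
        raise KeyError(f"cells absent from normalized matrix: {sorted(set(missing))[:5]}")
    open_rows = np.array([lookup[c] for c in pairs["open_cell"]])
    closed_rows = np.array([lookup[c] for c in pairs["closed_cell"]])
    out = pairs.copy()
    for gene, col in zip(genes, cols):
        e_open = np.expm1(norm.values[open_rows, col])
        e_closed = np.expm1(norm.values[closed_rows, col])
        out[f"logfc_{gene}"] = np.log2((1.0 + e_closed) / (1.0 + e_open))
    return out


def or_population_shift(
    assignments: pd.DataFrame, meta: pd.DataFrame, weighted: bool = True
) -> pd.DataFrame:
    """Normalized log1p shift of per-OR cell counts between nares.

    raw_shift = log1p(n_closed) - log1p(n_open); weight is the OR's share
    of all assigned cells (weights sum to 1); normalized_shift rescales
    raw_shift by weight times the number of ORs so an OR of average
    abundance keeps its raw shift.  With ``weighted=False`` the
    normalized_shift column equals raw_shift.
    """
    if "confident" in assignments.columns:
        assignments = assignments.loc[assignments["confident"]]
    if assignments.empty:
        raise ValueError("empty assignment table")
    merged = assignments.merge(meta[["cell_id", "naris"]], on="cell_id", how="inner")
    table = (
        merged.groupby("assigned_or")["naris"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["open", "closed"], fill_value=0)
        .rename_axis(index="or_id")
        .reset_index()
        .rename(columns={"open": "n_open", "closed": "n_closed"})
    )
    table["raw_shift"] = np.log1p(table["n_closed"]) - np.log1p(table["n_open"])
    total = (table["n_open"] + table["n_closed"]).sum()
    table["weight"] = (table["n_open"] + table["n_closed"]) / total
    n_or = len(table)
    if weighted:
        table["normalized_shift"] = table["raw_shift"] * table["weight"] * n_or
    else:
        table["normalized_shift"] = table["raw_shift"]
    return table[["or_id", "n_open", "n_closed", "raw_shift", "weight", "normalized_shift"]]


def classify_or_sets(
    de: pd.DataFrame, or_genes=None, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """KO+ / KO- / na OR classes from a differential expression table.

    ``de`` needs columns gene, logfc, fdr.  KO_plus: fdr < threshold and
    logfc > 0 (enriched in the knockout); KO_minus: fdr < threshold and
    logfc < 0; otherwise na.
    """
    table = de.copy()
    if or_genes is not None:
        or_genes = set(or_genes)
        missing = or_genes - set(table["gene"])
        if missing:
            raise KeyError(f"OR genes absent from DE table: {sorted(missing)[:5]}")
        table = table.loc[table["gene"].isin(or_genes)]
    sig = table["fdr"] < fdr_threshold
    cls = np.where(
        sig & (table["logfc"] > 0),
        "KO_plus",
        np.where(sig & (table["logfc"] < 0), "KO_minus", "na"),
    )
    return pd.DataFrame(
        {
            "or_id": table["gene"].to_numpy(),
            "or_class": cls,
            "source_logfc": table["logfc"].to_numpy(),
            "source_fdr": table["fdr"].to_numpy(),
        }
    )


def per_or_summary(
    pair_records: pd.DataFrame, classes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Median and IQR of pair statistics aggregated per OR.

    Pairs within an OR share cells and are not independent, so group-level
    testing uses one median value per OR rather than pooled pairs.
    """
    value_cols = [
        c for c in pair_records.columns if c == "euclid_dist" or c.startswith("logfc_")
    ]
    agg = pair_records.groupby("or_id")[value_cols].median().add_prefix("median_")
    q1 = pair_records.groupby("or_id")["euclid_dist"].quantile(0.25)
    q3 = pair_records.groupby("or_id")["euclid_dist"].quantile(0.75)
    agg["iqr_euclid_dist"] = q3 - q1
    agg["n_pairs"] = pair_records.groupby("or_id").size()
    agg = agg.reset_index()
    if classes is not None:
        agg = agg.merge(classes[["or_id", "or_class"]], on="or_id", how="left")
        agg["or_class"] = agg["or_class"].fillna("na")
    return agg


def compare_groups(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney U between every pair of groups.

    ``values`` holds one number per OR (e.g. the per-OR median distance),
    ``groups`` the class labels.  Groups with fewer than 2 members get
    p = NA with a logged warning.  Returns per-pair medians, IQRs, U and p.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups, dtype=object))
    labels = sorted(groups.dropna().unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 nonempty groups")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        va = values[groups == a].to_numpy()
        vb = values[groups == b].to_numpy()
        entry = {
            "group_a": a,
            "group_b": b,
            "n_a": len(va),
            "n_b": len(vb),
            "median_a": float(np.median(va)) if len(va) else np.nan,
            "median_b": float(np.median(vb)) if len(vb) else np.nan,
            "iqr_a": float(np.subtract(*np.percentile(va, [75, 25]))) if len(va) else np.nan,
            "iqr_b": float(np.subtract(*np.percentile(vb, [75, 25]))) if len(vb) else np.nan,
        }
        if len(va) < 2 or len(vb) < 2:
            logger.warning(
                "group %s vs %s: fewer than 2 ORs in a group, p set to NA", a, b
            )
            entry["u_stat"] = np.nan
            entry["p_value"] = np.nan
        else:
            u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            entry["u_stat"] = float(u)
            entry["p_value"] = float(p)
        rows.append(entry)
    return pd.DataFrame(rows)
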