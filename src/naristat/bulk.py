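"""Simplified bulk differential expression over genotype.

Counts become log2 counts-per-million with a 0.5 prior count, each gene is
tested KO vs WT with a Welch two-sample t-test, and p-values receive
Benjamini-Hochberg correction within the declared gene universe (all
genes, or olfactory receptors only).  This deliberately replaces the
negative-binomial GLM machinery of dedicated bulk DE packages: the goal
here is recovery of planted effects in simulation, not numeric agreement
with any particular fitted model.  Per-age contrasts and the pairwise
Pearson correlation of OR fold changes across ages round out the stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BulkCounts


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    All inputs must lie in (0, 1].  adj_(i) = min_{j >= i} p_(j) * n / j
    over the ascending sort, clipped at 1; the output is monotone in rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    stepped = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def log2_cpm(counts: np.ndarray, prior_count: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a prior count to handle zeros."""
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    if np.any(libsize <= 0):
        raise ValueError("samples with zero library size")
    return np.log2((counts + prior_count) / (libsize + 2.0 * prior_count)[None, :] * 1e6)


def de_test(
    bulk: BulkCounts,
    design: pd.DataFrame,
    age=None,
    gene_universe=None,
    contrast_label: str | None = None,
) -> pd.DataFrame:
    """Welch t-test of KO vs WT on log2-CPM, BH-corrected.

    ``age`` restricts to one age's samples; ``gene_universe`` restricts
    the tested genes (and hence the FDR correction) to a subset, e.g. OR
    genes only.  logfc is the KO minus WT difference of group means
    (log2).  Genes with zero variance in both groups get p = 1.
    """
    design = design.copy()
    design["age"] = design["age"].astype(int)
    if age is not None:
        design = design.loc[design["age"] == int(age)]
    sample_pos = {s: i for i, s in enumerate(bulk.sample_ids)}
    missing = [s for s in design["sample_id"] if s not in sample_pos]
    if missing:
        raise KeyError(f"design samples absent from counts: {missing[:5]}")
    ko = [sample_pos[s] for s in design.loc[design["genotype"] == "KO", "sample_id"]]
    wt = [sample_pos[s] for s in design.loc[design["genotype"] == "WT", "sample_id"]]
    if len(ko) < 2 or len(wt) < 2:
        raise ValueError(
            f"need >= 2 samples per genotype, got KO={len(ko)} WT={len(wt)}"
        )

    genes = bulk.gene_ids
    # library sizes always come from the full matrix; the universe only
    # restricts which genes are tested and corrected
    expr = log2_cpm(bulk.counts)
    if gene_universe is not None:
        universe = set(gene_universe)
        mask = np.array([g in universe for g in genes])
        if not mask.any():
            raise ValueError("gene universe shares no genes with the counts")
        genes = genes[mask]
        expr = expr[mask]
    a = expr[:, ko]
    b = expr[:, wt]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    p[~np.isfinite(p)] = 1.0  # zero variance in both groups
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    label = contrast_label or ("KO_vs_WT" if age is None else f"KO_vs_WT_age{age}")
    return pd.DataFrame(
        {
            "gene": genes,
            "contrast": label,
            "logfc": logfc,
            "p": p,
            "fdr": bh_fdr(p),
            "mean_expr": expr.mean(axis=1),
        }
    )


def logfc_age_correlation(
    de_by_age: dict, fdr_threshold: float = 0.05, universe: str = "union"
) -> pd.DataFrame:
    """Pairwise Pearson correlation of fold changes across ages.

    ``de_by_age`` maps age to a DE table.  The gene universe is the union
    (default) or intersection of genes significant (fdr < threshold) in
    the per-age tables; it must contain at least 3 genes.  Returns a
    symmetric age x age matrix with unit diagonal.
    """
    ages = sorted(de_by_age)
    sig_sets = []
    for age in ages:
        de = de_by_age[age]
        sig_sets.append(set(de.loc[de["fdr"] < fdr_threshold, "gene"]))
    if universe == "union":
        genes = set().union(*sig_sets)
    elif universe == "intersection":
        genes = set.intersection(*sig_sets) if sig_sets else set()
    else:
        raise ValueError(f"universe must be 'union' or 'intersection', got {universe!r}")
    shared = set.intersection(*(set(de_by_age[a]["gene"]) for a in ages))
    genes = sorted(genes & shared)
    if len(genes) < 3:
        raise ValueError(
            f"gene universe has {len(genes)} genes (< 3); cannot correlate"
        )
    mat = np.column_stack(
        [de_by_age[a].set_index("gene").loc[genes, "logfc"].to_numpy() for a in ages]
    )
    corr = np.corrcoef(mat, rowvar=False)
    return pd.DataFrame(corr, index=ages, columns=ages)


def de_recovery(de: pd.DataFrame, truth: pd.DataFrame, fdr_threshold: float = 0.05):
    """Sensitivity and empirical FDR of DE calls against planted truth.

    ``truth`` needs gene_id and de_direction (up/down/none) columns; a
    call counts as recovered when significant with the planted sign.
    """
    merged = de.merge(
        truth[["gene_id", "de_direction"]], left_on="gene", right_on="gene_id"
    )
    called = merged["fdr"] < fdr_threshold
    sign = np.where(merged["logfc"] > 0, "up", "down")
    true_pos = called & (merged["de_direction"] == sign)
    false_pos = called & (merged["de_direction"] == "none")
    n_planted = int((merged["de_direction"] != "none").sum())
    n_called = int(called.sum())
    sensitivity = float(true_pos.sum() / n_planted) if n_planted else np.nan
    empirical_fdr = float(false_pos.sum() / n_called) if n_called else 0.0
    return {
        "sensitivity": sensitivity,
        "empirical_fdr": empirical_fdr,
        "n_called": n_called,
        "n_planted": n_planted,
    }
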