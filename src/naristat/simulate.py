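"""Synthetic single-cell and bulk count datasets with ground truth.

The single-cell generator emulates a naris-occlusion mOSN experiment: every
mature olfactory sensory neuron (mOSN) is dominated by one olfactory
receptor (OR) gene, a small activity program (S100a5-like genes) is
suppressed in closed-naris cells, an iRhom2-like sensor gene (Rhbdf2) moves
in the opposite direction, and a designated "resistant" OR subset ignores
occlusion entirely.  The bulk generator emulates a WT vs knockout olfactory
epithelium design (3 replicates per age per genotype, ages 5/8/10/30 weeks)
with a planted set of up- and downregulated OR genes and an optional
occlusion-responsive gene set.

Counts are negative binomial with a mean/dispersion parameterization
(variance = mu + mu**2 / dispersion), the standard scRNA-seq count model,
drawn via the equivalent gamma-Poisson mixture.  Identical configurations
(including seed) produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from math import log

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSet

ACTIVITY_GENES = ("S100a5", "Dlg2", "Pcp4l1", "Kirrel2", "Lrrc3b")
SENSOR_GENE = "Rhbdf2"
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6",
    "mt-Co3", "mt-Nd3", "mt-Nd4", "mt-Nd5", "mt-Cytb",
)


class ConfigError(ValueError):
    """Invalid simulation configuration; names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Means are expected transcripts per gene per cell on the raw count
    scale.  ``occlusion_effect`` and ``sensor_effect`` are natural-log
    shifts applied to closed-naris cells of responsive ORs (activity genes
    and the sensor gene respectively); the paper-scale phenotype has the
    activity program suppressed (negative) and the sensor induced
    (positive) by odor deprivation.  ``bulk_logfc`` and ``geneset_logfc``
    are log2 shifts applied in the KO genotype.
    """

    seed: int = 0
    # gene roster
    n_or_genes: int = 60
    n_activity_genes: int = 5
    n_background_genes: int = 500
    n_mito_genes: int = 10
    # single-cell design
    cells_per_or_per_naris: int = 40
    nb_mean_background: float = 1.5
    background_mean_sigma: float = 1.0  # lognormal spread across background genes
    nb_dispersion: float = 10.0
    or_dominant_mean: float = 50.0
    or_leak_mean: float = 0.1
    activity_mean: float = 2.0
    sensor_mean: float = 1.0
    mito_mean: float = 5.0
    occlusion_effect: float = -1.0
    sensor_effect: float = 1.0
    resistant_or_fraction: float = 10 / 60
    # odor-exposure companion design (acetophenone vs solvent)
    exposure_cells_per_group: int = 200
    exposure_sensor_effect: float = -log(2.0)  # sensor halved by odor
    exposure_activity_effect: float = log(2.0)
    # bulk design
    bulk_n_up: int = 14
    bulk_n_down: int = 16
    bulk_logfc: float = 1.5
    bulk_reps_per_group: int = 12
    bulk_ages: tuple = (5, 8, 10, 30)
    bulk_age_drift_sd: float = 0.5
    bulk_base_mean_low: float = 5.0
    bulk_base_mean_high: float = 500.0
    n_geneset_genes: int = 30
    geneset_logfc: float = 1.0

    def validate(self) -> None:
        counts = [
            "n_or_genes", "n_activity_genes", "n_background_genes",
            "n_mito_genes", "cells_per_or_per_naris", "exposure_cells_per_group",
            "bulk_n_up", "bulk_n_down", "bulk_reps_per_group", "n_geneset_genes",
        ]
        for name in counts:
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {value!r}")
        if self.n_or_genes < 1:
            raise ConfigError("n_or_genes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"nb_dispersion must be > 0, got {self.nb_dispersion!r}")
        nonneg = [
            "nb_mean_background", "or_dominant_mean", "or_leak_mean",
            "activity_mean", "sensor_mean", "mito_mean", "background_mean_sigma",
            "bulk_base_mean_low", "bulk_base_mean_high",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not 0.0 <= self.resistant_or_fraction <= 1.0:
            raise ConfigError(
                f"resistant_or_fraction must be in [0, 1], got {self.resistant_or_fraction!r}"
            )
        if self.bulk_n_up + self.bulk_n_down > self.n_or_genes:
            raise ConfigError(
                f"bulk_n_up + bulk_n_down = {self.bulk_n_up + self.bulk_n_down} "
                f"exceeds n_or_genes = {self.n_or_genes}"
            )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bulk_ages"] = list(self.bulk_ages)
        return d


@dataclass
class GroundTruth:
    """Generative labels for the single-cell dataset.

    ``cells`` has one row per cell: the true OR, naris, and the realized
    occlusion multipliers applied to activity and sensor means (exactly 1
    for every cell of a resistant OR).  ``or_classes`` labels each OR
    resistant or responsive; ``gene_roles`` labels each gene
    OR / activity / sensor / background.
    """

    cells: pd.DataFrame
    or_classes: pd.DataFrame
    gene_roles: pd.DataFrame


@dataclass
class BulkGroundTruth:
    """Planted bulk effects: per-gene direction, per-age log2 fold changes,
    and the planted occlusion-responsive gene set plus its size-matched
    background control set."""

    genes: pd.DataFrame
    geneset_up: GeneSet | None
    geneset_background: GeneSet | None


def _gene_roster(config: SimConfig):
    or_genes = [f"OrS{i + 1:04d}" for i in range(config.n_or_genes)]
    n_act = config.n_activity_genes
    activity = list(ACTIVITY_GENES[:n_act])
    activity += [f"Act{i + 1:04d}" for i in range(len(activity), n_act)]
    mito = list(MITO_GENES[: config.n_mito_genes])
    mito += [f"mt-X{i + 1:02d}" for i in range(len(mito), config.n_mito_genes)]
    background = [f"Gene{i + 1:04d}" for i in range(config.n_background_genes)]
    genes = or_genes + activity + [SENSOR_GENE] + mito + background
    roles = (
        ["OR"] * len(or_genes)
        + ["activity"] * len(activity)
        + ["sensor"]
        + ["background"] * (len(mito) + len(background))
    )
    return genes, roles, or_genes, activity, mito, background


def _background_means(config: SimConfig, rng, n: int) -> np.ndarray:
    """Lognormal spread of baseline expression across background genes,
    emulating the wide expression range of a real transcriptome."""
    if n == 0:
        return np.zeros(0)
    if config.background_mean_sigma == 0 or config.nb_mean_background == 0:
        return np.full(n, config.nb_mean_background, dtype=float)
    return config.nb_mean_background * rng.lognormal(
        mean=0.0, sigma=config.background_mean_sigma, size=n
    )


def _draw_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, theta) via gamma-Poisson; exact zeros where mu == 0."""
    lam = np.zeros_like(mu)
    pos = mu > 0
    if np.any(pos):
        lam[pos] = rng.gamma(shape=dispersion, scale=mu[pos] / dispersion)
    return rng.poisson(lam).astype(np.int64)


def generate_sc_dataset(config: SimConfig):
    """Simulate the naris-occlusion single-cell dataset.

    Returns ``(CountMatrix, meta, GroundTruth)``.  Each OR contributes
    ``cells_per_or_per_naris`` cells per naris (balanced by construction).
    Closed-naris cells of responsive ORs have activity-gene means
    multiplied by exp(occlusion_effect) and the sensor-gene mean by
    exp(sensor_effect); resistant ORs keep multiplier exactly 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, roles, or_genes, activity, mito, background = _gene_roster(config)
    n_genes = len(genes)

    # gene-level baselines are drawn before any cells so that the roster is
    # identical across designs sharing a seed
    bg_means = _background_means(config, rng, len(background))
    n_resistant = int(round(config.resistant_or_fraction * config.n_or_genes))
    resistant_idx = rng.choice(config.n_or_genes, size=n_resistant, replace=False)
    resistant = np.zeros(config.n_or_genes, dtype=bool)
    resistant[resistant_idx] = True

    n_per = config.cells_per_or_per_naris
    n_cells = config.n_or_genes * 2 * n_per

    true_or = np.repeat(np.arange(config.n_or_genes), 2 * n_per)
    naris = np.tile(np.repeat(["open", "closed"], n_per), config.n_or_genes)
    cell_ids = np.array([f"C{i + 1:06d}" for i in range(n_cells)], dtype=object)

    closed = naris == "closed"
    responsive_cell = ~resistant[true_or]
    act_mult = np.where(closed & responsive_cell, np.exp(config.occlusion_effect), 1.0)
    sens_mult = np.where(closed & responsive_cell, np.exp(config.sensor_effect), 1.0)

    mu = np.empty((n_cells, n_genes), dtype=float)
    n_or = config.n_or_genes
    mu[:, :n_or] = config.or_leak_mean
    mu[np.arange(n_cells), true_or] = config.or_dominant_mean
    a0 = n_or
    a1 = n_or + len(activity)
    mu[:, a0:a1] = config.activity_mean * act_mult[:, None]
    mu[:, a1] = config.sensor_mean * sens_mult
    m0 = a1 + 1
    m1 = m0 + len(mito)
    mu[:, m0:m1] = config.mito_mean
    mu[:, m1:] = bg_means[None, :]

    counts = sp.csr_matrix(_draw_counts(rng, mu, config.nb_dispersion))
    cm = CountMatrix(cell_ids, np.array(genes, dtype=object), counts)

    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "naris": naris,
            "condition": "NA",
            "sample": np.where(closed, "occl_closed", "occl_open"),
            "genotype": "WT",
        }
    )
    truth_cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "true_or": np.array(or_genes, dtype=object)[true_or],
            "naris": naris,
            "activity_multiplier": act_mult,
            "sensor_multiplier": sens_mult,
        }
    )
    or_classes = pd.DataFrame(
        {
            "or_id": or_genes,
            "or_class": np.where(resistant, "resistant", "responsive"),
        }
    )
    gene_roles = pd.DataFrame({"gene_id": genes, "role": roles})
    return cm, meta, GroundTruth(truth_cells, or_classes, gene_roles)


def generate_exposure_dataset(config: SimConfig):
    """Simulate an odorant-exposure (odor vs solvent) mOSN dataset.

    Odor-exposed cells have the sensor-gene mean multiplied by
    exp(exposure_sensor_effect) (halved by default) and activity genes by
    exp(exposure_activity_effect); solvent cells are baseline.  OR choice
    is uniform across the roster.  Returns ``(CountMatrix, meta, truth)``
    where truth records per-cell condition multipliers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    genes, roles, or_genes, activity, mito, background = _gene_roster(config)
    n_genes = len(genes)
    bg_means = _background_means(config, rng, len(background))

    n_per = config.exposure_cells_per_group
    n_cells = 2 * n_per
    condition = np.repeat(["solvent", "odor"], n_per)
    cell_ids = np.array([f"E{i + 1:06d}" for i in range(n_cells)], dtype=object)
    true_or = rng.integers(0, config.n_or_genes, size=n_cells)

    odor = condition == "odor"
    sens_mult = np.where(odor, np.exp(config.exposure_sensor_effect), 1.0)
    act_mult = np.where(odor, np.exp(config.exposure_activity_effect), 1.0)

    mu = np.empty((n_cells, n_genes), dtype=float)
    n_or = config.n_or_genes
    mu[:, :n_or] = config.or_leak_mean
    mu[np.arange(n_cells), true_or] = config.or_dominant_mean
    a0, a1 = n_or, n_or + len(activity)
    mu[:, a0:a1] = config.activity_mean * act_mult[:, None]
    mu[:, a1] = config.sensor_mean * sens_mult
    m0 = a1 + 1
    mu[:, m0:m0 + len(mito)] = config.mito_mean
    mu[:, m0 + len(mito):] = bg_means[None, :]

    counts = sp.csr_matrix(_draw_counts(rng, mu, config.nb_dispersion))
    cm = CountMatrix(cell_ids, np.array(genes, dtype=object), counts)
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "naris": "NA",
            "condition": condition,
            "sample": np.where(odor, "exposure_odor", "exposure_solvent"),
            "genotype": "WT",
        }
    )
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "true_or": np.array(or_genes, dtype=object)[true_or],
            "condition": condition,
            "activity_multiplier": act_mult,
            "sensor_multiplier": sens_mult,
        }
    )
    return cm, meta, truth


def generate_bulk_dataset(config: SimConfig):
    """Simulate the bulk WT vs KO olfactory epithelium experiment.

    Exactly ``bulk_n_up`` OR genes are up-shifted and ``bulk_n_down``
    down-shifted by ``bulk_logfc`` (log2) in the KO genotype, and
    ``n_geneset_genes`` background genes are up-shifted by
    ``geneset_logfc`` (the planted occlusion-responsive program).  Per-OR
    effects drift with age: ages 5 and 8 weeks share one gene-level
    perturbation, 30 weeks draws an independent one, and 10 weeks is their
    midpoint, so fold changes correlate more strongly between neighbouring
    ages.  Returns ``(BulkCounts, design, BulkGroundTruth)``.
    """
    config.validate()
    if config.bulk_reps_per_group < 2:
        raise ConfigError(
            f"bulk_reps_per_group must be >= 2, got {config.bulk_reps_per_group}"
        )
    rng = np.random.default_rng(config.seed + 2_000_003)
    genes, roles, or_genes, activity, mito, background = _gene_roster(config)
    n_genes = len(genes)

    base = np.exp(
        rng.uniform(
            np.log(max(config.bulk_base_mean_low, 1e-3)),
            np.log(max(config.bulk_base_mean_high, 1e-3)),
            size=n_genes,
        )
    )

    n_de = config.bulk_n_up + config.bulk_n_down
    de_or = rng.choice(config.n_or_genes, size=n_de, replace=False)
    up_idx = de_or[: config.bulk_n_up]
    down_idx = de_or[config.bulk_n_up:]

    sign = np.zeros(n_genes)
    sign[up_idx] = 1.0
    sign[down_idx] = -1.0

    # planted occlusion-responsive set + size-matched null control, both
    # drawn from the non-mitochondrial background genes
    bg_offset = config.n_or_genes + config.n_activity_genes + 1 + config.n_mito_genes
    n_bg = config.n_background_genes
    n_set = min(config.n_geneset_genes, n_bg // 2)
    set_pick = rng.choice(n_bg, size=2 * n_set, replace=False)
    geneset_idx = bg_offset + set_pick[:n_set]
    control_idx = bg_offset + set_pick[n_set:]

    # age drift: delta_a shared by 5 and 8 weeks, delta_b at 30 weeks
    delta_a = np.zeros(n_genes)
    delta_b = np.zeros(n_genes)
    if config.bulk_age_drift_sd > 0 and n_de:
        delta_a[de_or] = rng.normal(0.0, config.bulk_age_drift_sd, size=n_de)
        delta_b[de_or] = rng.normal(0.0, config.bulk_age_drift_sd, size=n_de)

    ages = list(config.bulk_ages)
    effect_by_age = {}
    for age in ages:
        if config.bulk_age_drift_sd > 0:
            if age <= 8:
                drift = delta_a
            elif age >= 30:
                drift = delta_b
            else:
                drift = 0.5 * (delta_a + delta_b)
        else:
            drift = 0.0
        eff = sign * config.bulk_logfc + np.where(sign != 0, drift, 0.0)
        eff = eff + np.where(
            np.isin(np.arange(n_genes), geneset_idx), config.geneset_logfc, 0.0
        )
        effect_by_age[age] = eff

    reps = config.bulk_reps_per_group
    per_age = [reps // len(ages)] * len(ages)
    for i in range(reps - sum(per_age)):
        per_age[i] += 1

    sample_ids, genotypes, sample_ages = [], [], []
    mu_cols = []
    for age, n_rep in zip(ages, per_age):
        for genotype in ("WT", "KO"):
            for r in range(n_rep):
                sample_ids.append(f"{genotype}_{age}w_r{r + 1}")
                genotypes.append(genotype)
                sample_ages.append(age)
                eff = effect_by_age[age] if genotype == "KO" else 0.0
                mu_cols.append(base * np.power(2.0, eff))
    mu = np.column_stack(mu_cols) if mu_cols else np.zeros((n_genes, 0))
    counts = _draw_counts(rng, mu, config.nb_dispersion)

    bulk = BulkCounts(
        gene_ids=np.array(genes, dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        counts=counts,
    )
    design = pd.DataFrame(
        {"sample_id": sample_ids, "genotype": genotypes, "age": sample_ages}
    )

    direction = np.where(sign > 0, "up", np.where(sign < 0, "down", "none"))
    truth_genes = pd.DataFrame(
        {
            "gene_id": genes,
            "role": roles,
            "de_direction": direction,
            "true_log2fc": sign * config.bulk_logfc
            + np.where(np.isin(np.arange(n_genes), geneset_idx), config.geneset_logfc, 0.0),
        }
    )
    for age in ages:
        truth_genes[f"log2fc_age{age}"] = effect_by_age[age]
    gene_arr = np.array(genes, dtype=object)
    truth = BulkGroundTruth(
        genes=truth_genes,
        geneset_up=(
            GeneSet("planted_occlusion_up", frozenset(gene_arr[geneset_idx]))
            if n_set
            else None
        ),
        geneset_background=(
            GeneSet("planted_background", frozenset(gene_arr[control_idx]))
            if n_set
            else None
        ),
    )
    return bulk, design, truth


@dataclass
class BulkCounts:
    """Gene x sample nonnegative integer counts."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ConfigError(
                f"bulk counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ConfigError("bulk counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "gene_id", self.gene_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BulkCounts":
        genes = df["gene_id"].to_numpy(dtype=object)
        samples = np.array([c for c in df.columns if c != "gene_id"], dtype=object)
        return cls(genes, samples, df[list(samples)].to_numpy())
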