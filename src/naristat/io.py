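"""Readers and writers for on-disk formats.

Count matrices travel as MatrixMarket coordinate files (1-based, integer
field) with single-column ``genes.tsv`` / ``cells.tsv`` sidecars, the
CellRanger-style layout (rows = genes, columns = cells).  All in-memory
indexing is 0-based and cell-major; the 1-based conversion is confined to
this module.  Metadata and result tables are TSV with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mminfo, mmread, mmwrite

logger = logging.getLogger(__name__)

NARIS_LEVELS = ("open", "closed", "NA")
CONDITION_LEVELS = ("odor", "solvent", "NA")
GENOTYPE_LEVELS = ("WT", "KO", "NA")

META_COLUMNS = ["cell_id", "naris", "condition", "sample", "genotype"]


class FormatError(ValueError):
    """Malformed on-disk input; readers reject rather than coerce."""


@dataclass
class CountMatrix:
    """Sparse nonnegative integer cell x gene counts with stable IDs."""

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sp.csr_matrix  # cells x genes

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell IDs")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene IDs")
        data = self.counts.data
        if data.size:
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise FormatError("non-integer count entries")
                self.counts = self.counts.astype(np.int64)
                data = self.counts.data
            if data.min() < 0:
                raise FormatError("negative count entries")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def gene_index(self, genes) -> np.ndarray:
        """0-based column indices for ``genes``; raises on missing IDs."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        cm = self.counts
        cells = self.cell_ids
        genes = self.gene_ids
        if cell_mask is not None:
            cm = cm[cell_mask]
            cells = cells[cell_mask]
        if gene_mask is not None:
            cm = cm[:, gene_mask]
            genes = genes[gene_mask]
        return CountMatrix(cells, genes, cm.tocsr())


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene IDs; membership is exact string match."""

    name: str
    gene_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.gene_ids:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids


def _read_id_column(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] != 1:
        raise FormatError(f"{path}: expected a single ID column, got {df.shape[1]}")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    if any(i == "" for i in ids):
        raise FormatError(f"{path}: blank ID entries")
    return ids


def read_counts(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a genes x cells MatrixMarket file plus ID sidecars.

    The MTX header must declare coordinate integer format; dimensions must
    match the sidecar lengths exactly.
    """
    matrix_path = Path(matrix_path)
    rows, cols, _entries, fmt, fld, _sym = mminfo(matrix_path)
    if fmt != "coordinate":
        raise FormatError(f"{matrix_path}: MTX format is {fmt!r}, need coordinate")
    if fld != "integer":
        raise FormatError(f"{matrix_path}: MTX field is {fld!r}, need integer")
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    if rows != len(genes):
        raise FormatError(
            f"{matrix_path}: {rows} rows but {genes_path} lists {len(genes)} genes"
        )
    if cols != len(cells):
        raise FormatError(
            f"{matrix_path}: {cols} columns but {cells_path} lists {len(cells)} cells"
        )
    coo = mmread(matrix_path).tocoo()
    if coo.data.size and coo.data.min() < 0:
        bad = int(np.argmin(coo.data))
        raise FormatError(
            f"{matrix_path}: negative entry {coo.data[bad]} at "
            f"(row {coo.row[bad] + 1}, col {coo.col[bad] + 1})"
        )
    counts = coo.T.tocsr().astype(np.int64)
    return CountMatrix(cells, genes, counts)


def write_counts(cm: CountMatrix, matrix_path, genes_path, cells_path) -> None:
    """Write genes x cells MTX (1-based coordinate integer) + ID sidecars."""
    mat = cm.counts.T.tocoo().astype(np.int64)
    mmwrite(str(matrix_path), mat, field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    pd.DataFrame({"cell_id": cm.cell_ids}).to_csv(cells_path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    validate_meta(meta)
    return meta[META_COLUMNS]


def write_meta(meta: pd.DataFrame, path) -> None:
    validate_meta(meta)
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_meta(meta: pd.DataFrame, cm: CountMatrix | None = None) -> None:
    """Check enum levels and, when a matrix is given, ID agreement."""
    for col, levels in (
        ("naris", NARIS_LEVELS),
        ("condition", CONDITION_LEVELS),
        ("genotype", GENOTYPE_LEVELS),
    ):
        bad = set(meta[col].astype(str)) - set(levels)
        if bad:
            raise FormatError(f"metadata column {col!r} has invalid levels {sorted(bad)}")
    if meta["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id rows in metadata")
    if cm is not None:
        meta_ids = set(meta["cell_id"])
        mat_ids = set(cm.cell_ids)
        if meta_ids != mat_ids:
            only_meta = sorted(meta_ids - mat_ids)[:5]
            only_mat = sorted(mat_ids - meta_ids)[:5]
            raise FormatError(
                f"metadata/matrix cell ID mismatch (meta-only {only_meta}, "
                f"matrix-only {only_mat})"
            )


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One gene ID per line; blank lines ignored; must be nonempty."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return GeneSet(name or path.stem, frozenset(ids))


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.gene_ids)) + "\n")


def write_table(df: pd.DataFrame, path, log=None) -> None:
    """Write a result table as TSV with header and deterministic columns."""
    df.to_csv(path, sep="\t", index=False)
    if log is not None:
        log.table(Path(path).name, len(df))


class RunLog:
    """One run = one plain-text log file; no timestamps, no hidden state."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(self.path, "a")

    def write(self, msg: str) -> None:
        self._fh.write(msg.rstrip("\n") + "\n")
        self._fh.flush()

    def table(self, name: str, n_rows: int) -> None:
        self.write(f"wrote {name}: {n_rows} rows")

    def versions(self) -> None:
        import scipy

        from . import __version__

        self.write(
            f"versions: naristat={__version__} numpy={np.__version__} "
            f"scipy={scipy.__version__} pandas={pd.__version__}"
        )

    def config(self, mapping: dict) -> None:
        for key in sorted(mapping):
            self.write(f"config: {key} = {mapping[key]!r}")

    def close(self) -> None:
        self._fh.close()
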