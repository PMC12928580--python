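"""Annotated single-cell cohorts and auxiliary resources.

The pipeline's entry point is an :class:`AnnotatedCohort`: a gene x cell
log-normalized expression matrix, per-cell metadata (patient of origin and
cell type), and a patient x driver-gene binary annotation matrix.  Auxiliary
resources are a ligand-receptor pair table and an undirected intracellular
gene-interaction network, both consumed by the lite communication-network
backend and by intrinsic-extrinsic path expansion.

All on-disk formats are plain TSV (dense expression, metadata, annotations)
or MatrixMarket ``.mtx`` with ``genes.tsv``/``cells.tsv`` sidecars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
import scipy.io
import scipy.sparse

from .errors import InputFormatError, ValidationError

__all__ = [
    "AnnotatedCohort",
    "LigandReceptorTable",
    "IntracellularNetwork",
    "read_cohort",
    "write_cohort",
    "filter_low_expressed",
    "lognormalize",
    "read_lr_table",
    "read_intracellular_network",
]


@dataclass
class AnnotatedCohort:
    """A validated multi-patient single-cell cohort.

    Parameters
    ----------
    expr
        Gene x cell matrix of non-negative (log-normalized) expression.
    cell_meta
        Indexed by cell ID with columns ``patient_id`` and ``cell_type``.
    driver_annot
        Patient x driver-gene matrix with entries in {0, 1}; 1 means the
        driver event is present in that patient's tumor.
    cell_types
        Declared finite vocabulary of cell-type labels.  Defaults to the
        labels observed in ``cell_meta``.
    retention
        Optional gene x cell-type boolean mask recording which genes passed
        the per-type low-expression filter (see :func:`filter_low_expressed`).
    """

    expr: pd.DataFrame
    cell_meta: pd.DataFrame
    driver_annot: pd.DataFrame
    cell_types: tuple[str, ...] = ()
    retention: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.cell_types:
            self.cell_types = tuple(sorted(self.cell_meta["cell_type"].unique()))
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValidationError("duplicate gene symbols in expression matrix")
        if self.expr.columns.has_duplicates:
            raise ValidationError("duplicate cell IDs in expression matrix")
        if (self.expr.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative entries")
        if not self.expr.columns.equals(self.cell_meta.index):
            missing = set(self.expr.columns) ^ set(self.cell_meta.index)
            raise ValidationError(
                f"cell IDs of expression matrix and cell metadata differ: {sorted(missing)[:5]}"
            )
        unknown = set(self.cell_meta["cell_type"]) - set(self.cell_types)
        if unknown:
            raise ValidationError(f"cell types outside declared vocabulary: {sorted(unknown)}")
        missing_patients = set(self.cell_meta["patient_id"]) - set(self.driver_annot.index)
        if missing_patients:
            raise ValidationError(
                f"patients in cell metadata absent from driver annotations: {sorted(missing_patients)}"
            )
        vals = self.driver_annot.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("driver annotations must be binary (0/1)")

    # ------------------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def cells(self) -> pd.Index:
        return self.expr.columns

    @property
    def patients(self) -> pd.Index:
        return self.driver_annot.index

    def cells_of(self, patient: str | None = None, cell_type: str | None = None) -> pd.Index:
        """Cell IDs restricted to a patient and/or cell type."""
        mask = pd.Series(True, index=self.cell_meta.index)
        if patient is not None:
            mask &= self.cell_meta["patient_id"] == patient
        if cell_type is not None:
            mask &= self.cell_meta["cell_type"] == cell_type
        return self.cell_meta.index[mask]

    def is_retained(self, gene: str, cell_type: str) -> bool:
        """Whether a gene passed the low-expression filter for a cell type.

        Before :func:`filter_low_expressed` has been applied every gene is
        considered retained.
        """
        if self.retention is None:
            return gene in self.expr.index
        if gene not in self.retention.index:
            return False
        return bool(self.retention.at[gene, cell_type])


@dataclass(frozen=True)
class LigandReceptorTable:
    """Curated (ligand, receptor) gene-symbol pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValidationError("empty gene symbol in ligand-receptor table")
            if (lig, rec) in seen:
                raise ValidationError(f"duplicate ligand-receptor row: {lig}\t{rec}")
            seen.add((lig, rec))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class IntracellularNetwork:
    """Undirected gene-gene interaction network within a single cell."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"intracellular network contains self-loops: {loops[:3]}")

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))


# ----------------------------------------------------------------------
# readers / writers


def _read_expr(expr_path: Path) -> pd.DataFrame:
    if expr_path.suffix == ".mtx":
        mat = scipy.sparse.csr_matrix(scipy.io.mmread(expr_path))
        genes = pd.read_csv(expr_path.parent / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(expr_path.parent / "cells.tsv", sep="\t", header=None)[0]
        if mat.shape != (len(genes), len(cells)):
            raise InputFormatError(
                f"{expr_path}: matrix is {mat.shape} but sidecars declare "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        return pd.DataFrame(mat.toarray(), index=genes.str.strip(), columns=cells.str.strip())
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str).str.strip()
    expr.columns = expr.columns.astype(str).str.strip()
    return expr


def read_cohort(
    expr_path: str | Path,
    cell_meta_path: str | Path,
    driver_path: str | Path,
    protein_coding_path: str | Path | None = None,
    cell_types: Sequence[str] | None = None,
) -> AnnotatedCohort:
    """Load an annotated cohort from disk.

    ``protein_coding_path``, when given, is a one-symbol-per-line list; the
    expression matrix is restricted to symbols on that list (unlisted genes
    are dropped, list entries absent from the matrix are ignored).
    """
    expr_path, cell_meta_path, driver_path = Path(expr_path), Path(cell_meta_path), Path(driver_path)
    expr = _read_expr(expr_path)
    meta = pd.read_csv(cell_meta_path, sep="\t", dtype=str)
    required = {"cell_id", "patient_id", "cell_type"}
    if not required <= set(meta.columns):
        raise InputFormatError(f"{cell_meta_path}: missing columns {sorted(required - set(meta.columns))}")
    meta = meta.set_index("cell_id")
    if len(meta) != expr.shape[1]:
        raise InputFormatError(
            f"{cell_meta_path}: {len(meta)} rows but expression matrix has {expr.shape[1]} cells"
        )
    meta = meta.loc[expr.columns]
    drivers = pd.read_csv(driver_path, sep="\t", index_col=0)
    if protein_coding_path is not None:
        coding = {
            line.strip()
            for line in Path(protein_coding_path).read_text().splitlines()
            if line.strip()
        }
        expr = expr.loc[[g for g in expr.index if g in coding]]
    return AnnotatedCohort(
        expr=expr,
        cell_meta=meta,
        driver_annot=drivers,
        cell_types=tuple(cell_types) if cell_types else (),
    )


def write_cohort(cohort: AnnotatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as dense TSVs; inverse of :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": out / "expression.tsv",
        "cell_meta": out / "cell_meta.tsv",
        "drivers": out / "drivers.tsv",
    }
    cohort.expr.to_csv(paths["expr"], sep="\t")
    cohort.cell_meta.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        paths["cell_meta"], sep="\t", index=False
    )
    cohort.driver_annot.to_csv(paths["drivers"], sep="\t")
    return paths


# ----------------------------------------------------------------------
# preprocessing


def lognormalize(raw_counts: pd.DataFrame, scale: float = 10_000.0) -> pd.DataFrame:
    """Library-size normalize to ``scale`` counts per cell, then log1p.

    value = ln(1 + count / colsum * scale), computed per cell (column).
    Cells with zero total counts yield an all-zero column and a warning.
    """
    counts = raw_counts.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValidationError("raw counts contain negative values")
    colsum = counts.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) have zero total counts; their columns are left all-zero",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, colsum)
    normed = np.log1p(counts / safe * scale)
    normed[:, zero] = 0.0
    return pd.DataFrame(normed, index=raw_counts.index, columns=raw_counts.columns)


def filter_low_expressed(cohort: AnnotatedCohort, min_frac: float = 0.05) -> AnnotatedCohort:
    """Record the per-(gene, cell type) low-expression retention mask.

    A gene is retained for a cell type iff the fraction of that type's cells
    with expression > 0 is at least ``min_frac``.  Different cell types may
    therefore keep different gene sets; the expression matrix itself is left
    untouched and the mask is stored on the returned cohort.
    """
    masks = {}
    for ct in cohort.cell_types:
        cells = cohort.cells_of(cell_type=ct)
        if len(cells) == 0:
            raise ValidationError(f"cell type {ct!r} has zero cells; cannot apply expression filter")
        frac = (cohort.expr[cells] > 0).sum(axis=1) / len(cells)
        masks[ct] = frac >= min_frac
    retention = pd.DataFrame(masks, index=cohort.genes)
    return replace(cohort, retention=retention)


# ----------------------------------------------------------------------
# auxiliary resources


def read_lr_table(path: str | Path) -> LigandReceptorTable:
    """Read a 2-column TSV (ligand, receptor); a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise InputFormatError(f"{path}: expected 2 columns (ligand, receptor)")
    if df.iloc[0, 0].lower() in {"ligand", "l"}:
        df = df.iloc[1:]
    pairs = tuple((str(l).strip(), str(r).strip()) for l, r in zip(df[0], df[1]))
    if not pairs:
        raise InputFormatError(f"{path}: empty ligand-receptor table")
    return LigandReceptorTable(pairs)


def read_intracellular_network(path: str | Path) -> IntracellularNetwork:
    """Read a 2-column TSV edge list of undirected gene-gene interactions."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise InputFormatError(f"{path}: expected 2 columns (geneA, geneB)")
    g = nx.Graph()
    for a, b in zip(df[0], df[1]):
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            raise ValidationError(f"{path}: self-loop on {a}")
        g.add_edge(a, b)
    return IntracellularNetwork(g)


def intracellular_from_pairs(pairs: Iterable[tuple[str, str]]) -> IntracellularNetwork:
    """Build an :class:`IntracellularNetwork` from in-memory gene pairs."""
    g = nx.Graph()
    g.add_edges_from(pairs)
    return IntracellularNetwork(g)
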