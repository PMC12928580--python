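"""Downstream evaluation: immune scores and signature-based survival analysis.

Two bulk-level immune activity proxies are provided:

* MHC-I score — arithmetic mean expression of the nine-gene antigen
  presentation core set (HLA-A/B/C, TAP1/2, NLRC5, PSMB8/9, B2M);
* CYT score — geometric mean of the cytolytic effectors GZMA and PRF1,
  with a small pseudocount.

For survival analysis against a CCC signature, per-gene expression in the
single-cell cohort defines Hi/Lo cell subtypes by a median split; bulk
patients are stratified by the median split of the Hi-subtype abundance per
signature gene (supplied externally by a deconvolution tool, or by the
built-in non-negative least squares fallback), every high/low combination
across the signature's genes forms a group, and survival differences across
groups are assessed with a multi-group log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import ParameterError, ValidationError
from .io import AnnotatedCohort

__all__ = [
    "MHC1_CORE",
    "BulkCohort",
    "SignatureStratification",
    "mhc1_score",
    "cyt_score",
    "subtype_split",
    "stratify_bulk",
    "logrank_groups",
    "km_curves",
    "nnls_deconvolve",
]

MHC1_CORE = (
    "HLA-A", "HLA-B", "HLA-C", "TAP1", "TAP2", "NLRC5", "PSMB9", "PSMB8", "B2M",
)


@dataclass
class BulkCohort:
    """Bulk expression (genes x samples) with per-sample clinical follow-up."""

    expr: pd.DataFrame
    clinical: pd.DataFrame  # index sample, columns: time, event

    def __post_init__(self) -> None:
        missing = set(self.clinical.index) - set(self.expr.columns)
        if missing:
            raise ValidationError(f"clinical samples absent from expression: {sorted(missing)}")
        if (self.clinical["time"] <= 0).any():
            raise ValidationError("survival times must be positive")
        if not np.isin(self.clinical["event"], (0, 1)).all():
            raise ValidationError("event indicator must be 0/1")


@dataclass
class SignatureStratification:
    """Combinatorial high/low patient grouping for one CCC signature.

    ``states`` is a samples x genes boolean frame (True = high abundance of
    the gene's Hi subtype); ``labels`` collapses each row into a group label
    like ``GENE1^hi|GENE2^lo``.  Groups partition the cohort.
    """

    states: pd.DataFrame
    labels: pd.Series

    @property
    def groups(self) -> dict[str, list[str]]:
        return {g: list(idx) for g, idx in self.labels.groupby(self.labels).groups.items()}


# ----------------------------------------------------------------------
# immune scores


def mhc1_score(bulk_expr: pd.DataFrame, core_set: tuple[str, ...] = MHC1_CORE) -> pd.Series:
    """Per-sample arithmetic mean of the available MHC-I core genes."""
    present = [g for g in core_set if g in bulk_expr.index]
    missing = [g for g in core_set if g not in bulk_expr.index]
    if not present:
        raise ValidationError("no MHC-I core genes found in the expression matrix")
    if missing:
        warnings.warn(f"MHC-I core genes missing and dropped: {missing}", stacklevel=2)
    return bulk_expr.loc[present].mean(axis=0).rename("mhc1_score")


def cyt_score(
    bulk_expr: pd.DataFrame,
    effectors: tuple[str, str] = ("GZMA", "PRF1"),
    pseudocount: float = 0.01,
) -> pd.Series:
    """Per-sample geometric mean of the two cytolytic effector genes."""
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    missing = [g for g in effectors if g not in bulk_expr.index]
    if missing:
        raise ValidationError(f"cytolytic effectors missing: {missing}")
    vals = bulk_expr.loc[list(effectors)]
    if (vals.to_numpy() < 0).any():
        raise ValidationError("negative expression values in cytolytic effectors")
    return pd.Series(
        np.sqrt((vals.iloc[0] + pseudocount) * (vals.iloc[1] + pseudocount)),
        index=bulk_expr.columns,
        name="cyt_score",
    )


# ----------------------------------------------------------------------
# signature-based stratification


def subtype_split(
    cohort: AnnotatedCohort, gene: str, cell_type: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-split one cell type into Hi/Lo subtypes by a gene's expression.

    Cells strictly above the median are ``Hi``; cells at or below the median
    (including ties at the median) are ``Lo``.  Returns the per-cell labels
    and the mean-expression profiles of both subtypes, usable as
    deconvolution signature columns.
    """
    if not cohort.is_retained(gene, cell_type):
        raise ValidationError(f"gene {gene!r} not retained for cell type {cell_type!r}")
    cells = cohort.cells_of(cell_type=cell_type)
    vals = cohort.expr.loc[gene, cells]
    if vals.nunique() <= 1:
        raise ValidationError(
            f"{gene!r} is constant across {cell_type!r} cells; the median split is "
            "degenerate — choose a variable gene or a different cell type"
        )
    labels = pd.Series(
        np.where(vals > vals.median(), "Hi", "Lo"), index=cells, name=f"{gene}@{cell_type}"
    )
    profiles = pd.DataFrame(
        {
            "Hi": cohort.expr[cells[labels == "Hi"]].mean(axis=1),
            "Lo": cohort.expr[cells[labels == "Lo"]].mean(axis=1),
        }
    )
    return labels, profiles


def stratify_bulk(bulk: BulkCohort, abundance: pd.DataFrame) -> SignatureStratification:
    """Combinatorial median-split stratification by Hi-subtype abundances.

    ``abundance`` is samples x signature-genes: per patient, the estimated
    abundance of the gene's Hi-expressing cell subtype.  Patients strictly
    above the per-gene median are "high" for that gene (ties at the median
    go to low); the group label concatenates the per-gene states, giving at
    most 2^k non-empty groups for k genes.
    """
    missing = set(bulk.clinical.index) - set(abundance.index)
    if missing:
        raise ValidationError(f"abundance rows missing for samples: {sorted(missing)}")
    ab = abundance.loc[bulk.clinical.index]
    states = ab.gt(ab.median(axis=0), axis=1)
    labels = pd.Series(
        [
            "|".join(f"{g}^{'hi' if row[g] else 'lo'}" for g in states.columns)
            for _, row in states.iterrows()
        ],
        index=states.index,
        name="group",
    )
    return SignatureStratification(states=states, labels=labels)


def logrank_groups(
    strat: SignatureStratification | pd.Series, clinical: pd.DataFrame
) -> tuple[float, int, float]:
    """Multi-group log-rank test across the stratification groups.

    Returns ``(chi-square statistic, degrees of freedom, p)``.  Empty groups
    are dropped with a warning; fewer than two remaining groups is an error.
    """
    labels = strat.labels if isinstance(strat, SignatureStratification) else strat
    labels = labels.loc[clinical.index]
    sizes = labels.value_counts()
    empty = [g for g, n in sizes.items() if n == 0]
    if empty:
        warnings.warn(f"dropping empty groups: {empty}", stacklevel=2)
    if sizes.gt(0).sum() < 2:
        raise ValidationError("log-rank test requires at least two non-empty groups")
    if clinical["event"].sum() == 0:
        raise ValidationError("no events observed; log-rank test undefined")
    res = multivariate_logrank_test(
        clinical["time"], labels, clinical["event"]
    )
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


def km_curves(
    strat: SignatureStratification | pd.Series, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Kaplan-Meier survival curves per group as a tidy table for export."""
    labels = strat.labels if isinstance(strat, SignatureStratification) else strat
    labels = labels.loc[clinical.index]
    frames = []
    for group in sorted(labels.unique()):
        idx = labels.index[labels == group]
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.loc[idx, "time"], clinical.loc[idx, "event"], label=group)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "group", group)
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# deconvolution fallback


def nnls_deconvolve(bulk_expr: pd.DataFrame, signature_matrix: pd.DataFrame) -> pd.DataFrame:
    """Estimate subtype abundances per bulk sample by non-negative least squares.

    ``signature_matrix`` is genes x subtypes (mean expression profiles).
    Coefficients are constrained non-negative and normalized to sum to one
    per sample.  This is a transparent baseline for when no dedicated
    deconvolution output is available.
    """
    genes = [g for g in signature_matrix.index if g in bulk_expr.index]
    if len(genes) < signature_matrix.shape[1]:
        raise ValidationError("fewer informative genes than subtypes")
    S = signature_matrix.loc[genes].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValidationError("signature matrix is rank-deficient")
    out = {}
    for sample in bulk_expr.columns:
        y = bulk_expr.loc[genes, sample].to_numpy(dtype=float)
        coef, _ = scipy.optimize.nnls(S, y)
        total = coef.sum()
        out[sample] = coef / total if total > 0 else coef
    return pd.DataFrame(out, index=signature_matrix.columns).T
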