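"""Driver-gene calling from inferred copy-number profiles.

Consumes per-patient gene x cell CNV matrices produced by an external
CNV-inference tool (one matrix for tumor cells, one for reference diploid
cells).  For each curated candidate driver gene the tumor-cell CNV value
distribution is compared with the reference distribution by a two-sample
two-sided Kolmogorov-Smirnov test; p values are Benjamini-Hochberg adjusted
(per patient by default) and genes with adjusted p below ``alpha`` are
called as that patient's drivers.  The resulting binary patient x driver
matrix feeds the cohort's driver annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError

__all__ = ["CNVProfile", "ks_driver_call", "read_cnv_matrix"]


@dataclass
class CNVProfile:
    """Per-patient inferred CNV matrices plus the candidate driver list.

    ``tumor`` and ``reference`` map patient IDs to gene x cell CNV value
    matrices; both compartments must exist for every patient and hold at
    least two cells each.
    """

    tumor: Mapping[str, pd.DataFrame]
    reference: Mapping[str, pd.DataFrame]
    candidate_drivers: Sequence[str]

    def __post_init__(self) -> None:
        if set(self.tumor) != set(self.reference):
            raise ValidationError("tumor and reference compartments cover different patients")
        for patient in self.tumor:
            for name, mat in (("tumor", self.tumor[patient]), ("reference", self.reference[patient])):
                if mat.shape[1] < 2:
                    raise ValidationError(
                        f"patient {patient!r}: {name} compartment has <2 cells"
                    )
        if not self.candidate_drivers:
            raise ValidationError("empty candidate driver list")


def read_cnv_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells CNV value TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)


def ks_driver_call(
    profile: CNVProfile,
    alpha: float = 0.01,
    family: str = "per_patient",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call per-patient drivers by the two-sample KS test on CNV profiles.

    Returns ``(calls, p_adj)``: both patient x candidate-gene frames, the
    first binary (1 = called driver), the second holding BH-adjusted p
    values (NaN for genes missing from a patient's matrices, which are
    skipped with a warning).  ``family='per_patient'`` adjusts across the
    candidate genes within each patient; ``'global'`` adjusts across all
    patient-gene pairs.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    if family not in ("per_patient", "global"):
        raise ParameterError(f"unknown family {family!r}")
    patients = sorted(profile.tumor)
    genes = list(profile.candidate_drivers)
    raw = pd.DataFrame(np.nan, index=patients, columns=genes)
    for patient in patients:
        tum, ref = profile.tumor[patient], profile.reference[patient]
        for gene in genes:
            if gene not in tum.index or gene not in ref.index:
                warnings.warn(
                    f"candidate {gene!r} missing from patient {patient!r} CNV matrices; skipped",
                    stacklevel=2,
                )
                continue
            stat = scipy.stats.ks_2samp(
                tum.loc[gene].to_numpy(), ref.loc[gene].to_numpy(), alternative="two-sided"
            )
            raw.at[patient, gene] = stat.pvalue
    p_adj = pd.DataFrame(np.nan, index=patients, columns=genes)
    if family == "global":
        flat = raw.to_numpy().ravel()
        mask = ~np.isnan(flat)
        if mask.any():
            adj = np.full(flat.shape, np.nan)
            adj[mask] = multipletests(flat[mask], method="fdr_bh")[1]
            p_adj.iloc[:, :] = adj.reshape(raw.shape)
    else:
        for patient in patients:
            row = raw.loc[patient].to_numpy()
            mask = ~np.isnan(row)
            if mask.any():
                adj = np.full(row.shape, np.nan)
                adj[mask] = multipletests(row[mask], method="fdr_bh")[1]
                p_adj.loc[patient] = adj
    calls = ((p_adj < alpha).fillna(False)).astype(int)
    return calls, p_adj
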