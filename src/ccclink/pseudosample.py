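"""Bootstrap pseudo-samples.

Single-cell cohorts are small (tens of patients), which starves a
per-sample association test of power.  The pipeline therefore up-samples
each patient into bootstrap pseudo-samples: for every focal cell type it
draws 50% of that patient's cells with replacement, repeated five times per
patient, yielding ``repeats`` pseudo-samples per eligible patient.  Patients
with fewer than ``min_cells`` cells in any focal type are "undersized"; a
policy flag optionally includes each of them once, unresampled, as its own
pseudo-sample (replicate index 0).

Reproducibility: one global seed plus a per-(patient, replicate) stream
derived by hashing the patient ID, so adding or removing patients does not
perturb other patients' draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import AnnotatedCohort

__all__ = ["PseudoSample", "eligible_patients", "generate_pseudosamples", "write_manifest"]


@dataclass(frozen=True)
class PseudoSample:
    """One bootstrap replicate of a patient's focal-cell-type compartment.

    ``cells_by_type`` maps each focal cell type to the multiset (tuple, with
    repeats) of selected cell IDs.  ``replicate_index`` 0 is reserved for
    undersized patients included directly with all of their cells.
    """

    sample_id: str
    source_patient: str
    replicate_index: int
    cells_by_type: dict[str, tuple[str, ...]]
    driver_vector: pd.Series

    def n_cells(self, cell_type: str) -> int:
        return len(self.cells_by_type[cell_type])


def _patient_stream(seed: int, patient: str, replicate: int) -> np.random.Generator:
    # stable 32-bit digest of the patient ID keeps streams independent of
    # cohort composition and of Python's randomized str hash
    digest = int.from_bytes(hashlib.blake2b(patient.encode(), digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence([seed, digest, replicate]))


def eligible_patients(
    cohort: AnnotatedCohort,
    focal_types: Sequence[str],
    min_cells: int = 20,
) -> tuple[list[str], list[str]]:
    """Split patients into (eligible, undersized) under the cell-count rule.

    A patient is eligible iff it has at least ``min_cells`` cells in *every*
    focal cell type.
    """
    unknown = set(focal_types) - set(cohort.cell_types)
    if unknown:
        raise ValidationError(f"focal cell types not in vocabulary: {sorted(unknown)}")
    eligible, undersized = [], []
    for patient in cohort.patients:
        counts = [len(cohort.cells_of(patient=patient, cell_type=t)) for t in focal_types]
        (eligible if all(c >= min_cells for c in counts) else undersized).append(patient)
    return eligible, undersized


def generate_pseudosamples(
    cohort: AnnotatedCohort,
    focal_types: Sequence[str],
    min_cells: int = 20,
    frac: float = 0.5,
    repeats: int = 5,
    include_undersized: bool = False,
    seed: int = 0,
) -> list[PseudoSample]:
    """Draw bootstrap pseudo-samples for every eligible patient.

    Each eligible patient yields ``repeats`` pseudo-samples; each draws
    round(frac * n_t) cells with replacement per focal type t (round half to
    even).  With ``include_undersized``, every undersized patient contributes
    exactly one unresampled pseudo-sample holding all of its focal cells.

    The total count is ``len(eligible) * repeats`` plus, when enabled, the
    number of undersized patients.
    """
    if repeats < 1:
        raise ParameterError(f"repeats must be >= 1, got {repeats}")
    if not (0 < frac <= 1):
        raise ParameterError(f"frac must be in (0, 1], got {frac}")
    eligible, undersized = eligible_patients(cohort, focal_types, min_cells)
    types = list(focal_types)
    out: list[PseudoSample] = []
    for patient in eligible:
        for rep in range(1, repeats + 1):
            rng = _patient_stream(seed, patient, rep)
            cells_by_type = {}
            for t in types:
                pool = list(cohort.cells_of(patient=patient, cell_type=t))
                k = round(frac * len(pool))
                cells_by_type[t] = tuple(rng.choice(pool, size=k, replace=True))
            out.append(
                PseudoSample(
                    sample_id=f"{patient}#r{rep}",
                    source_patient=patient,
                    replicate_index=rep,
                    cells_by_type=cells_by_type,
                    driver_vector=cohort.driver_annot.loc[patient],
                )
            )
    if include_undersized:
        for patient in undersized:
            cells_by_type = {
                t: tuple(cohort.cells_of(patient=patient, cell_type=t)) for t in types
            }
            out.append(
                PseudoSample(
                    sample_id=f"{patient}#r0",
                    source_patient=patient,
                    replicate_index=0,
                    cells_by_type=cells_by_type,
                    driver_vector=cohort.driver_annot.loc[patient],
                )
            )
    return out


def write_manifest(samples: Sequence[PseudoSample], path: str | Path) -> pd.DataFrame:
    """Write a manifest TSV: sample_id, source patient, replicate, cell counts."""
    types = sorted({t for s in samples for t in s.cells_by_type})
    rows = [
        {
            "sample_id": s.sample_id,
            "source_patient": s.source_patient,
            "replicate_index": s.replicate_index,
            **{f"n_{t}": s.n_cells(t) for t in types},
        }
        for s in samples
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
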