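"""End-to-end convenience wrapper: cohort -> ranked CCC signatures."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .association import AssociationResult, associate_all
from .io import AnnotatedCohort, IntracellularNetwork, LigandReceptorTable
from .mining import FrequentSubnetwork, encode_occurrence, gspan_mine
from .network import LiteBackend, MCTCNetwork, NetworkBackend
from .pseudosample import PseudoSample, generate_pseudosamples

__all__ = ["PipelineResult", "run_pipeline"]

# default support threshold as a fraction of the pseudo-sample count; kept
# below typical driver prevalence so patterns carried mostly by
# driver-positive samples still clear the mining threshold
DEFAULT_SUPPORT_FRAC = 0.15


@dataclass
class PipelineResult:
    pseudosamples: list[PseudoSample]
    networks: list[MCTCNetwork]
    patterns: list[FrequentSubnetwork]
    occurrence: pd.DataFrame
    drivers: pd.DataFrame
    results: list[AssociationResult]

    def signatures(self) -> list[AssociationResult]:
        """Significant driver-associated results, rank order per driver."""
        return sorted(
            (r for r in self.results if r.significant),
            key=lambda r: (r.driver, r.rank),
        )


def run_pipeline(
    cohort: AnnotatedCohort,
    lr_table: LigandReceptorTable | None,
    intra: IntracellularNetwork | None,
    focal_types: Sequence[str],
    backend: NetworkBackend | None = None,
    min_cells: int = 20,
    frac: float = 0.5,
    repeats: int = 5,
    include_undersized: bool = False,
    seed: int = 0,
    expr_frac_threshold: float = 0.1,
    hop_radius: int = 1,
    min_support: int | None = None,
    max_edges: int = 5,
    alpha: float = 0.05,
) -> PipelineResult:
    """Pseudo-sample, build networks, mine, and test in one call.

    When ``backend`` is None the lite co-expression backend is used, which
    requires ``lr_table`` and ``intra``.  ``min_support`` defaults to
    ``max(2, ceil(0.15 * n_pseudosamples))``.
    """
    samples = generate_pseudosamples(
        cohort,
        focal_types,
        min_cells=min_cells,
        frac=frac,
        repeats=repeats,
        include_undersized=include_undersized,
        seed=seed,
    )
    if backend is None:
        if lr_table is None or intra is None:
            raise ValueError("lite backend requires a ligand-receptor table and intracellular network")
        backend = LiteBackend(
            cohort, lr_table, intra, focal_types, expr_frac_threshold, hop_radius
        )
    networks = backend.networks(samples)
    if min_support is None:
        min_support = max(2, math.ceil(DEFAULT_SUPPORT_FRAC * len(networks)))
    patterns = gspan_mine(networks, min_support=min_support, max_edges=max_edges)
    occurrence = encode_occurrence(patterns, networks)
    drivers = pd.DataFrame(
        [s.driver_vector for s in samples],
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    ).astype(int)
    results = associate_all(occurrence, drivers, alpha=alpha)
    return PipelineResult(samples, networks, patterns, occurrence, drivers, results)
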