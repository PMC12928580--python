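"""Shared fixtures: tiny hand-built cohorts and random network factories."""

from __future__ import annotations

import random
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ccclink.io import AnnotatedCohort
from ccclink.network import MCTCNetwork


def build_cohort(
    cell_counts: dict[str, dict[str, int]],
    drivers: dict[str, dict[str, int]] | None = None,
    genes: list[str] | None = None,
    expr_fn=None,
    seed: int = 0,
) -> AnnotatedCohort:
    """Cohort with prescribed per-(patient, cell type) cell counts.

    ``cell_counts[patient][cell_type] = n``.  Expression defaults to
    uniform positive values; ``expr_fn(gene, patient, cell_type, rng)``
    overrides per-cell values when given.
    """
    genes = genes or ["G1", "G2"]
    rng = np.random.default_rng(seed)
    cols, meta = [], []
    vals = []
    for patient, per_type in cell_counts.items():
        for ctype, n in per_type.items():
            for k in range(n):
                cid = f"{patient}_{ctype}_{k}"
                cols.append(cid)
                meta.append({"cell_id": cid, "patient_id": patient, "cell_type": ctype})
                if expr_fn is None:
                    vals.append(rng.uniform(0.5, 2.0, size=len(genes)))
                else:
                    vals.append([expr_fn(g, patient, ctype, rng) for g in genes])
    expr = pd.DataFrame(np.array(vals).T, index=genes, columns=cols)
    patients = list(cell_counts)
    if drivers is None:
        drivers = {p: {"DRV": 0} for p in patients}
    driver_annot = pd.DataFrame(drivers).T.loc[patients]
    meta_df = pd.DataFrame(meta).set_index("cell_id")
    return AnnotatedCohort(expr=expr, cell_meta=meta_df, driver_annot=driver_annot)


def random_network(
    sid: str,
    rng: random.Random,
    genes=("G1", "G2", "G3", "G4"),
    types=("TC", "Mac", "CTL"),
    max_edges: int = 10,
) -> MCTCNetwork:
    """A random small labeled MCTC network (used against brute-force oracles)."""
    net = MCTCNetwork(sid)
    nodes = [(g, t) for g in genes for t in types]
    n_edges = rng.randint(2, max_edges)
    tries = 0
    while net.n_edges() < n_edges and tries < 200:
        tries += 1
        a, b = rng.sample(nodes, 2)
        net.add_edge(a, b)
    return net


@pytest.fixture
def toy_cohort() -> AnnotatedCohort:
    """3 patients, 3 cell types, deterministic positive expression."""
    return build_cohort(
        {
            "P1": {"TC": 4, "Mac": 3, "CTL": 3},
            "P2": {"TC": 3, "Mac": 4, "CTL": 3},
            "P3": {"TC": 3, "Mac": 3, "CTL": 4},
        },
        drivers={"P1": {"DRV": 1}, "P2": {"DRV": 0}, "P3": {"DRV": 1}},
        genes=["L", "R", "X"],
    )
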