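"""Synthetic cohorts with planted driver-communication associations.

Two generators share one seed protocol (a master seed; per-sample streams):

* :func:`simulate_network_cohort` draws per-sample communication networks
  directly — the primary test path for mining and association, bypassing
  any network-inference backend.  Each sample's driver status is
  Bernoulli(prevalence); each planted motif (a small labeled subgraph,
  typically a ligand-receptor edge) is inserted with probability
  ``p_driver_pos`` in driver-positive samples and ``p_driver_neg``
  otherwise; background edges over a separate gene label space are added at
  a configured density.  A motif is genuinely driver-associated iff its two
  conditional probabilities differ.

* :func:`simulate_expression_cohort` draws negative-binomial counts for a
  multi-patient cohort with three cell types and up-shifts the planted
  ligand/receptor genes in the designated cell types of motif-carrying
  patients, so the lite co-expression backend recovers the motif edges —
  the integration path exercising the pipeline end to end.

Defaults represent the study conditions used throughout the test-suite
simulations: 60 samples, driver prevalence 0.4, planted co-occurrence
probabilities 0.9 (driver+) vs 0.1 (driver-).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    AnnotatedCohort,
    IntracellularNetwork,
    LigandReceptorTable,
    filter_low_expressed,
    intracellular_from_pairs,
    lognormalize,
)
from .mining import FrequentSubnetwork
from .network import INTER, MCTCNetwork, Node

__all__ = [
    "PlantedMotif",
    "SimConfig",
    "default_motifs",
    "simulate_network_cohort",
    "simulate_expression_cohort",
    "ExpressionSim",
    "pattern_matches_motif",
]


@dataclass(frozen=True)
class PlantedMotif:
    """A labeled subgraph planted with driver-conditional probabilities."""

    name: str
    edges: tuple[tuple[Node, Node], ...]
    p_driver_pos: float = 0.9
    p_driver_neg: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.p_driver_pos, self.p_driver_neg):
            if not (0 <= p <= 1):
                raise ValidationError(f"motif {self.name}: probability {p} outside [0, 1]")

    @property
    def associated(self) -> bool:
        return self.p_driver_pos != self.p_driver_neg

    @property
    def genes(self) -> set[str]:
        return {n[0] for e in self.edges for n in e}

    def label_edges(self) -> frozenset[tuple[str, str, str]]:
        """Edges as sorted (label, kind, label) triples for exact matching."""
        out = set()
        for a, b in self.edges:
            la, lb = sorted((f"{a[0]}@{a[1]}", f"{b[0]}@{b[1]}"))
            kind = "intracellular" if a[1] == b[1] else "intercellular"
            out.add((la, kind, lb))
        return frozenset(out)


def default_motifs() -> tuple[PlantedMotif, ...]:
    """Two driver-associated ligand-receptor motifs and one null motif."""
    return (
        PlantedMotif("assoc_TC_Mac", ((("LIG1", "TC"), ("REC1", "Mac")),), 0.9, 0.1),
        PlantedMotif("assoc_Mac_CTL", ((("LIG2", "Mac"), ("REC2", "CTL")),), 0.9, 0.1),
        PlantedMotif("null_TC_CTL", ((("LIG3", "TC"), ("REC3", "CTL")),), 0.3, 0.3),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for both simulation paths."""

    n_samples: int = 60
    cell_types: tuple[str, ...] = ("TC", "Mac", "CTL")
    driver: str = "DRV1"
    prevalence: float = 0.4
    motifs: tuple[PlantedMotif, ...] = field(default_factory=default_motifs)
    n_background_genes: int = 20
    background_density: float = 0.004
    # expression-path parameters
    n_patients: int = 12
    cells_per_type: int = 40
    nb_mean_background: float = 2.0
    nb_mean_on: float = 8.0
    nb_mean_off: float = 0.02
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValidationError("prevalence must be in (0, 1)")
        bg = {f"BG{k}" for k in range(self.n_background_genes)}
        clash = bg & {g for m in self.motifs for g in m.genes}
        if clash:
            raise ValidationError(f"motif genes collide with background label space: {clash}")


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, sample_index]))


# ----------------------------------------------------------------------
# network-level simulation


def simulate_network_cohort(
    cfg: SimConfig, seed: int | None = None
) -> tuple[list[MCTCNetwork], pd.DataFrame, pd.DataFrame]:
    """Draw per-sample networks with planted driver-motif co-occurrence.

    Returns ``(networks, drivers, truth)``: one network per sample, the
    samples x 1 binary driver matrix, and the truth table recording each
    motif's conditional presence probabilities and whether it is genuinely
    driver-associated.
    """
    seed = cfg.seed if seed is None else seed
    bg_nodes = [
        (f"BG{k}", ct) for k in range(cfg.n_background_genes) for ct in cfg.cell_types
    ]
    n_possible = len(bg_nodes) * (len(bg_nodes) - 1) // 2
    networks, driver_col = [], []
    for i in range(cfg.n_samples):
        rng = _sample_rng(seed, i)
        has_driver = bool(rng.random() < cfg.prevalence)
        driver_col.append(int(has_driver))
        net = MCTCNetwork(f"S{i:03d}")
        for motif in cfg.motifs:
            p = motif.p_driver_pos if has_driver else motif.p_driver_neg
            if rng.random() < p:
                for a, b in motif.edges:
                    net.add_edge(a, b)
        n_bg = rng.binomial(n_possible, cfg.background_density)
        chosen = rng.choice(n_possible, size=n_bg, replace=False)
        for eid in chosen:
            a, b = _decode_edge(int(eid), len(bg_nodes))
            net.add_edge(bg_nodes[a], bg_nodes[b])
        networks.append(net)
    drivers = pd.DataFrame(
        {cfg.driver: driver_col}, index=pd.Index([n.sample_id for n in networks], name="sample_id")
    )
    truth = pd.DataFrame(
        [
            {
                "motif": m.name,
                "p_driver_pos": m.p_driver_pos,
                "p_driver_neg": m.p_driver_neg,
                "associated": m.associated,
            }
            for m in cfg.motifs
        ]
    )
    return networks, drivers, truth


def _decode_edge(eid: int, n: int) -> tuple[int, int]:
    """Map a flat index in [0, n*(n-1)/2) to an unordered node pair."""
    a = 0
    remaining = eid
    row = n - 1
    while remaining >= row:
        remaining -= row
        a += 1
        row -= 1
    return a, a + 1 + remaining


def pattern_matches_motif(pattern: FrequentSubnetwork, motif: PlantedMotif) -> bool:
    """Exact match between a mined pattern and a planted motif.

    Planted motifs carry unique node labels, so equality of the sorted
    labeled edge sets is equivalent to label-preserving isomorphism.
    """
    pat_edges = set()
    for i, j, kind in pattern.edge_list:
        la, lb = sorted((pattern.node_labels[i], pattern.node_labels[j]))
        pat_edges.add((la, kind, lb))
    return frozenset(pat_edges) == motif.label_edges()


# ----------------------------------------------------------------------
# expression-level simulation


@dataclass
class ExpressionSim:
    """An expression-path simulation bundle ready for the full pipeline."""

    cohort: AnnotatedCohort
    lr_table: LigandReceptorTable
    intra: IntracellularNetwork
    truth: pd.DataFrame
    carriers: pd.DataFrame  # patients x motifs, 1 = motif planted in that patient


def simulate_expression_cohort(cfg: SimConfig, seed: int | None = None) -> ExpressionSim:
    """Draw a count-level cohort whose planted motifs the lite backend recovers.

    Counts are negative binomial per (gene, cell type).  Planted ligand and
    receptor genes are expressed at ``nb_mean_on`` in their designated cell
    type of motif-carrying patients and ``nb_mean_off`` otherwise; the
    intercellular motifs in the ligand-receptor table used by the motifs are
    also present in the returned table.  The returned cohort is already
    log-normalized and carries the low-expression retention mask.
    """
    seed = cfg.seed if seed is None else seed
    motif_genes = {g for m in cfg.motifs for g in m.genes}
    genes = sorted({g for m in cfg.motifs for g in m.genes}) + [
        f"BG{k}" for k in range(cfg.n_background_genes)
    ]
    r = cfg.nb_dispersion

    def nb(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
        return rng.negative_binomial(r, r / (r + mean), size=size)

    patients = [f"P{k:02d}" for k in range(cfg.n_patients)]
    columns, meta_rows = [], []
    blocks = []
    driver_col, carrier_rows = [], []
    for pi, patient in enumerate(patients):
        rng = _sample_rng(seed, pi)
        has_driver = bool(rng.random() < cfg.prevalence)
        driver_col.append(int(has_driver))
        carried = {}
        for m in cfg.motifs:
            p = m.p_driver_pos if has_driver else m.p_driver_neg
            carried[m.name] = int(rng.random() < p)
        carrier_rows.append(carried)
        on_nodes = {
            n
            for m in cfg.motifs
            if carried[m.name]
            for e in m.edges
            for n in e
        }
        for ct in cfg.cell_types:
            ncells = cfg.cells_per_type
            block = np.empty((len(genes), ncells), dtype=np.int64)
            for gi, gene in enumerate(genes):
                if (gene, ct) in on_nodes:
                    mean = cfg.nb_mean_on
                elif gene in motif_genes:
                    # planted genes are silent outside their designated
                    # (cell type, carrier) context
                    mean = cfg.nb_mean_off
                else:
                    mean = cfg.nb_mean_background
                block[gi] = nb(rng, mean, ncells)
            blocks.append(block)
            for ci in range(ncells):
                cell_id = f"{patient}_{ct}_{ci:03d}"
                columns.append(cell_id)
                meta_rows.append({"cell_id": cell_id, "patient_id": patient, "cell_type": ct})
    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    cohort = AnnotatedCohort(
        expr=lognormalize(counts),
        cell_meta=pd.DataFrame(meta_rows).set_index("cell_id"),
        driver_annot=pd.DataFrame({cfg.driver: driver_col}, index=pd.Index(patients)),
        cell_types=cfg.cell_types,
    )
    cohort = filter_low_expressed(cohort)
    lr_pairs = []
    for m in cfg.motifs:
        for a, b in m.edges:
            if a[1] != b[1] and (a[0], b[0]) not in lr_pairs:
                lr_pairs.append((a[0], b[0]))
    lr_table = LigandReceptorTable(tuple(lr_pairs))
    # a small intracellular scaffold over background genes and motif genes
    intra_pairs = [(f"BG{k}", f"BG{k + 1}") for k in range(cfg.n_background_genes - 1)]
    if lr_pairs:
        intra_pairs.append(("BG0", lr_pairs[0][0]))
    intra = intracellular_from_pairs(intra_pairs)
    truth = pd.DataFrame(
        [
            {
                "motif": m.name,
                "p_driver_pos": m.p_driver_pos,
                "p_driver_neg": m.p_driver_neg,
                "associated": m.associated,
            }
            for m in cfg.motifs
        ]
    )
    carriers = pd.DataFrame(carrier_rows, index=pd.Index(patients, name="patient_id"))
    return ExpressionSim(cohort, lr_table, intra, truth, carriers)
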