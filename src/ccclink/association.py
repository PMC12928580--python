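"""Driver–subnetwork association testing.

Each frequent subnetwork's occurrence column (extrinsic factor) is tested
against each driver gene's per-sample status column (intrinsic factor) with
a one-sided Fisher's exact test.  The alternative is "greater" on the
co-occurrence cell: the question is whether a communication pattern appears
*together with* a driver event, not whether the two are mutually exclusive.
P values are Benjamini-Hochberg adjusted within each driver's family of
patterns, and patterns with adjusted p below ``alpha`` are labeled CCC
signatures and ranked by significance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .mining import FrequentSubnetwork

__all__ = ["AssociationResult", "fisher_one_sided", "associate_all", "results_table"]


@dataclass(frozen=True)
class AssociationResult:
    """Fisher statistics for one (driver, pattern) pair.

    The 2x2 table counts pseudo-samples: a = driver+ & pattern+,
    b = driver+ & pattern-, c = driver- & pattern+, d = driver- & pattern-.
    ``rank`` is assigned only among significant signatures of the driver.
    """

    driver: str
    pattern_id: int
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    p_adj: float
    rank: int | None = None

    @property
    def significant(self) -> bool:
        return self.rank is not None


def _check_binary(vec: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def fisher_one_sided(
    pattern_col: Sequence[int], driver_col: Sequence[int]
) -> tuple[tuple[int, int, int, int], float, float]:
    """One-sided (greater) Fisher's exact test for co-occurrence.

    Returns ``((a, b, c, d), odds_ratio, p)`` where p is the hypergeometric
    upper-tail probability P(X >= a) given the table margins, and the odds
    ratio is ad/bc (infinity when bc = 0 with a > 0, NaN for the degenerate
    all-zero diagonal).
    """
    pat = _check_binary(np.asarray(pattern_col), "pattern column")
    drv = _check_binary(np.asarray(driver_col), "driver column")
    if pat.shape != drv.shape:
        raise ValidationError("pattern and driver columns differ in length")
    a = int(np.sum(drv & pat))
    b = int(np.sum(drv & ~pat))
    c = int(np.sum(~drv & pat))
    d = int(np.sum(~drv & ~pat))
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return (a, b, c, d), odds, float(p)


def associate_all(
    F: pd.DataFrame,
    drivers: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "per_driver",
) -> list[AssociationResult]:
    """Test every (driver, pattern) pair and rank significant signatures.

    ``F`` is the binary occurrence matrix (samples x patterns); ``drivers``
    holds the per-sample driver status columns on the same index.  Drivers
    present in no sample or in all samples carry no contrast and are skipped
    with a warning.  ``family`` controls the multiple-testing family:
    ``per_driver`` (default) adjusts across the patterns tested against one
    driver; ``global`` adjusts across all driver-pattern pairs at once.

    Significant results (p_adj < alpha) receive ranks 1..k per driver in
    descending order of significance; ties are broken by higher odds ratio,
    then larger co-occurrence count, then pattern_id.
    """
    if family not in ("per_driver", "global"):
        raise ParameterError(f"unknown family {family!r}")
    if not F.index.equals(drivers.index):
        raise ValidationError("occurrence matrix and driver matrix have different sample indices")
    if F.shape[1] == 0:
        return []
    results: list[AssociationResult] = []
    tested: list[AssociationResult] = []
    for driver in drivers.columns:
        col = drivers[driver].to_numpy()
        prev = int(col.sum())
        if prev == 0 or prev == len(col):
            warnings.warn(
                f"driver {driver!r} present in {prev}/{len(col)} samples; "
                "no contrast, skipped",
                stacklevel=2,
            )
            continue
        for pid in F.columns:
            (a, b, c, d), odds, p = fisher_one_sided(F[pid].to_numpy(), col)
            tested.append(
                AssociationResult(driver=driver, pattern_id=pid, a=a, b=b, c=c, d=d,
                                  odds_ratio=odds, p=p, p_adj=math.nan)
            )
    if not tested:
        return []

    def adjust(group: list[AssociationResult]) -> list[AssociationResult]:
        padj = multipletests([r.p for r in group], method="fdr_bh")[1]
        return [
            AssociationResult(r.driver, r.pattern_id, r.a, r.b, r.c, r.d,
                              r.odds_ratio, r.p, float(q))
            for r, q in zip(group, padj)
        ]

    if family == "global":
        adjusted = adjust(tested)
    else:
        adjusted = []
        for driver in dict.fromkeys(r.driver for r in tested):
            adjusted.extend(adjust([r for r in tested if r.driver == driver]))

    for driver in dict.fromkeys(r.driver for r in adjusted):
        group = [r for r in adjusted if r.driver == driver]
        sig = [r for r in group if r.p_adj < alpha]
        # descending significance; deterministic tie-breaks
        sig.sort(
            key=lambda r: (
                r.p_adj,
                r.p,
                -(r.odds_ratio if math.isfinite(r.odds_ratio) else math.inf),
                -r.a,
                r.pattern_id,
            )
        )
        ranks = {(r.driver, r.pattern_id): k + 1 for k, r in enumerate(sig)}
        for r in group:
            results.append(
                AssociationResult(r.driver, r.pattern_id, r.a, r.b, r.c, r.d,
                                  r.odds_ratio, r.p, r.p_adj,
                                  rank=ranks.get((r.driver, r.pattern_id)))
            )
    return results


def results_table(
    results: Sequence[AssociationResult],
    patterns: Mapping[int, FrequentSubnetwork] | Sequence[FrequentSubnetwork] | None = None,
) -> pd.DataFrame:
    """Tidy results table, optionally annotated with pattern signatures."""
    if patterns is not None and not isinstance(patterns, Mapping):
        patterns = {p.pattern_id: p for p in patterns}
    rows = []
    for r in results:
        row = {
            "driver": r.driver,
            "pattern_id": r.pattern_id,
            "a": r.a,
            "b": r.b,
            "c": r.c,
            "d": r.d,
            "odds_ratio": r.odds_ratio,
            "p": r.p,
            "p_adj": r.p_adj,
            "rank": r.rank,
        }
        if patterns is not None and r.pattern_id in patterns:
            row["signature"] = patterns[r.pattern_id].signature()
        rows.append(row)
    return pd.DataFrame(rows)
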