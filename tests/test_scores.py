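"""Immune scores, median-split stratification, log-rank, NNLS fallback."""

import numpy as np
import pandas as pd
import pytest

from ccclink.errors import ValidationError
from ccclink.io import filter_low_expressed
from ccclink.scores import (
    MHC1_CORE,
    BulkCohort,
    cyt_score,
    km_curves,
    logrank_groups,
    mhc1_score,
    nnls_deconvolve,
    stratify_bulk,
    subtype_split,
)
from conftest import build_cohort
from oracles import logrank_two_group


def bulk_frame(data: dict, genes) -> pd.DataFrame:
    return pd.DataFrame(data, index=genes)


class TestMHC1:
    def test_constant_input_gives_constant(self):
        expr = bulk_frame({"s1": [3.0] * 9, "s2": [3.0] * 9}, list(MHC1_CORE))
        assert mhc1_score(expr).tolist() == pytest.approx([3.0, 3.0])

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        expr = bulk_frame({"s1": rng.uniform(0, 5, 9)}, list(MHC1_CORE))
        shuffled = expr.sample(frac=1, random_state=1)
        assert mhc1_score(expr)["s1"] == pytest.approx(mhc1_score(shuffled)["s1"])

    def test_mean_against_direct_sum(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 10, 9)
        expr = bulk_frame({"s1": vals}, list(MHC1_CORE))
        assert mhc1_score(expr)["s1"] == pytest.approx(vals.sum() / 9)

    def test_missing_genes_warn_and_drop(self):
        expr = bulk_frame({"s1": [2.0, 4.0]}, ["HLA-A", "HLA-B"])
        with pytest.warns(UserWarning, match="TAP1"):
            score = mhc1_score(expr)
        assert score["s1"] == pytest.approx(3.0)

    def test_no_core_genes_rejected(self):
        expr = bulk_frame({"s1": [1.0]}, ["OTHER"])
        with pytest.raises(ValidationError):
            mhc1_score(expr)


class TestCYT:
    def test_closed_form(self):
        expr = bulk_frame({"s1": [4.0, 9.0]}, ["GZMA", "PRF1"])
        assert cyt_score(expr, pseudocount=0.0)["s1"] == pytest.approx(6.0)

    def test_idempotent_on_equal_values(self):
        expr = bulk_frame({"s1": [5.5, 5.5]}, ["GZMA", "PRF1"])
        assert cyt_score(expr, pseudocount=0.0)["s1"] == pytest.approx(5.5)

    def test_am_gm_inequality(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.uniform(0, 20, size=(2, 50)), index=["GZMA", "PRF1"])
        geo = cyt_score(expr, pseudocount=0.0)
        am = expr.mean(axis=0)
        assert (geo <= am + 1e-12).all()

    def test_negative_expression_rejected(self):
        expr = bulk_frame({"s1": [-1.0, 2.0]}, ["GZMA", "PRF1"])
        with pytest.raises(ValidationError):
            cyt_score(expr)

    def test_missing_effector_rejected(self):
        expr = bulk_frame({"s1": [1.0]}, ["GZMA"])
        with pytest.raises(ValidationError):
            cyt_score(expr)


class TestSubtypeSplit:
    def _cohort(self, values):
        vals = iter(values)
        cohort = build_cohort(
            {"P1": {"CTL": len(values)}},
            drivers={"P1": {"DRV": 0}},
            genes=["PDCD1", "OTHER"],
            expr_fn=lambda g, p, t, rng: next(vals) if g == "PDCD1" else 1.0,
        )
        return filter_low_expressed(cohort)

    def test_median_split(self):
        cohort = self._cohort([1.0, 2.0, 3.0, 4.0])
        labels, profiles = subtype_split(cohort, "PDCD1", "CTL")
        assert labels.tolist() == ["Lo", "Lo", "Hi", "Hi"]
        assert set(profiles.columns) == {"Hi", "Lo"}
        assert profiles.at["PDCD1", "Hi"] > profiles.at["PDCD1", "Lo"]

    def test_ties_at_median_go_low(self):
        cohort = self._cohort([1.0, 2.0, 2.0, 4.0])
        labels, _ = subtype_split(cohort, "PDCD1", "CTL")
        assert labels.tolist() == ["Lo", "Lo", "Lo", "Hi"]

    def test_split_size_imbalance_bounded_by_ties(self):
        values = [1.0, 2.0, 2.0, 2.0, 3.0, 4.0]
        cohort = self._cohort(values)
        labels, _ = subtype_split(cohort, "PDCD1", "CTL")
        n_ties = values.count(2.0)
        assert abs((labels == "Hi").sum() - (labels == "Lo").sum()) <= n_ties

    def test_constant_gene_rejected(self):
        cohort = self._cohort([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValidationError, match="median split"):
            subtype_split(cohort, "PDCD1", "CTL")


@pytest.fixture
def bulk():
    rng = np.random.default_rng(11)
    samples = [f"b{i}" for i in range(8)]
    expr = pd.DataFrame(rng.uniform(1, 5, size=(3, 8)), index=["g1", "g2", "g3"], columns=samples)
    clinical = pd.DataFrame(
        {"time": rng.uniform(1, 100, 8), "event": rng.integers(0, 2, 8)}, index=samples
    )
    clinical.iloc[0, 1] = 1  # ensure at least one event
    return BulkCohort(expr=expr, clinical=clinical)


class TestStratifyBulk:
    def test_single_gene_median_split(self, bulk):
        ab = pd.DataFrame({"GENE": [0.1, 0.2, 0.3, 0.4]}, index=bulk.clinical.index[:4])
        small = BulkCohort(expr=bulk.expr.iloc[:, :4], clinical=bulk.clinical.iloc[:4])
        strat = stratify_bulk(small, ab)
        groups = strat.groups
        assert sorted(groups) == ["GENE^hi", "GENE^lo"]
        assert set(groups["GENE^hi"]) == set(ab.index[2:])

    def test_two_genes_at_most_four_groups_partition(self, bulk):
        rng = np.random.default_rng(0)
        ab = pd.DataFrame(
            rng.uniform(size=(8, 2)), index=bulk.clinical.index, columns=["gA", "gB"]
        )
        strat = stratify_bulk(bulk, ab)
        groups = strat.groups
        assert len(groups) <= 4
        assert sum(len(v) for v in groups.values()) == 8
        all_members = [s for v in groups.values() for s in v]
        assert len(set(all_members)) == 8  # partition: no overlaps

    def test_missing_sample_rejected(self, bulk):
        ab = pd.DataFrame({"g": [0.1]}, index=[bulk.clinical.index[0]])
        with pytest.raises(ValidationError):
            stratify_bulk(bulk, ab)


class TestLogrank:
    def test_identical_groups_null(self):
        time = [5, 10, 15, 20, 5, 10, 15, 20]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        clinical = pd.DataFrame({"time": time, "event": event}, index=[f"s{i}" for i in range(8)])
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=clinical.index)
        stat, df, p = logrank_groups(labels, clinical)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_toy_table_matches_hand_oracle(self):
        # group A: events at t=1,2; group B: censored at t=3,4
        clinical = pd.DataFrame(
            {"time": [1, 2, 3, 4], "event": [1, 1, 0, 0]}, index=["a1", "a2", "b1", "b2"]
        )
        labels = pd.Series(["A", "A", "B", "B"], index=clinical.index)
        stat, _, _ = logrank_groups(labels, clinical)
        expected = logrank_two_group(clinical["time"], clinical["event"], labels)
        assert stat == pytest.approx(expected)

    def test_random_two_groups_match_oracle(self):
        rng = np.random.default_rng(3)
        time = rng.uniform(1, 50, 30).round(1)
        event = rng.integers(0, 2, 30)
        event[0] = 1
        clinical = pd.DataFrame({"time": time, "event": event}, index=[f"s{i}" for i in range(30)])
        labels = pd.Series(rng.choice(["A", "B"], 30), index=clinical.index)
        stat, _, _ = logrank_groups(labels, clinical)
        assert stat == pytest.approx(logrank_two_group(time, event, labels), rel=1e-8)

    def test_single_group_rejected(self):
        clinical = pd.DataFrame({"time": [1, 2], "event": [1, 1]}, index=["s1", "s2"])
        labels = pd.Series(["A", "A"], index=clinical.index)
        with pytest.raises(ValidationError):
            logrank_groups(labels, clinical)

    def test_km_curves_export(self):
        clinical = pd.DataFrame(
            {"time": [1, 2, 3, 4], "event": [1, 1, 1, 0]}, index=["a", "b", "c", "d"]
        )
        labels = pd.Series(["A", "A", "B", "B"], index=clinical.index)
        curves = km_curves(labels, clinical)
        assert set(curves["group"]) == {"A", "B"}
        assert ((curves["survival"] >= 0) & (curves["survival"] <= 1)).all()


class TestNNLS:
    def _signature(self):
        rng = np.random.default_rng(5)
        return pd.DataFrame(
            rng.uniform(1, 10, size=(12, 2)), index=[f"g{i}" for i in range(12)],
            columns=["Hi", "Lo"],
        )

    def test_exact_5050_mixture(self):
        S = self._signature()
        bulk = pd.DataFrame({"s1": 0.5 * S["Hi"] + 0.5 * S["Lo"]})
        ab = nnls_deconvolve(bulk, S)
        assert ab.loc["s1"].tolist() == pytest.approx([0.5, 0.5], abs=1e-8)

    def test_pure_column(self):
        S = self._signature()
        bulk = pd.DataFrame({"s1": S["Hi"]})
        ab = nnls_deconvolve(bulk, S)
        assert ab.loc["s1"].tolist() == pytest.approx([1.0, 0.0], abs=1e-8)

    def test_noisy_recovery_degrades_gracefully(self):
        S = self._signature()
        rng = np.random.default_rng(9)
        true = np.array([0.7, 0.3])
        clean = S.to_numpy() @ true
        for noise, tol in ((0.01, 0.02), (0.3, 0.25)):
            bulk = pd.DataFrame(
                {"s1": clean + rng.normal(0, noise, size=len(clean))}, index=S.index
            )
            bulk[bulk < 0] = 0
            ab = nnls_deconvolve(bulk, S)
            assert ab.loc["s1"].to_numpy() == pytest.approx(true, abs=tol)

    def test_rank_deficient_rejected(self):
        S = self._signature()
        S["Lo"] = 2 * S["Hi"]
        bulk = pd.DataFrame({"s1": S["Hi"]})
        with pytest.raises(ValidationError):
            nnls_deconvolve(bulk, S)
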