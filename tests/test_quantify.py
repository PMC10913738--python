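"""TPM, filters, within-taxon normalization, activities and contributions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wamecfix as w
from wamecfix.io import ValidationError
from .conftest import make_catalog, make_samples


def brute_force_tpm(counts: pd.DataFrame, lengths: dict) -> pd.DataFrame:
    """Independent per-gene loop implementation of TPM."""
    out = counts.astype(float).copy()
    for lib in counts.columns:
        rates = {}
        for g in counts.index:
            rates[g] = counts.loc[g, lib] / (lengths[g] / 1000.0)
        total = sum(rates.values())
        for g in counts.index:
            out.loc[g, lib] = rates[g] / total * 1e6
    return out


class TestTpm:
    def test_hand_oracle_two_genes(self):
        cat = make_catalog([{"id": "a", "length": 1000}, {"id": "b", "length": 2000}])
        counts = pd.DataFrame({"L0": [10, 40]}, index=["a", "b"])
        tpm = w.compute_tpm(counts, cat)
        # rates {10, 20}, total 30
        assert tpm.loc["a", "L0"] == pytest.approx(1e6 / 3, rel=1e-12)
        assert tpm.loc["b", "L0"] == pytest.approx(2e6 / 3, rel=1e-12)

    def test_single_expressed_unigene_gets_the_million(self):
        cat = make_catalog([{"id": "a"}, {"id": "b"}])
        counts = pd.DataFrame({"L0": [7, 0]}, index=["a", "b"])
        tpm = w.compute_tpm(counts, cat)
        assert tpm.loc["a", "L0"] == pytest.approx(1e6)
        assert tpm.loc["b", "L0"] == 0.0

    def test_depth_invariance(self, rng):
        cat = make_catalog([{"id": f"g{i}", "length": 200 + 100 * i} for i in range(6)])
        counts = pd.DataFrame(
            {"L0": rng.integers(1, 100, 6)}, index=cat.ids
        )
        t1 = w.compute_tpm(counts, cat)
        t2 = w.compute_tpm(counts * 2, cat)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_library_named(self):
        cat = make_catalog([{"id": "a"}])
        counts = pd.DataFrame({"good": [1], "void": [0]}, index=["a"])
        with pytest.raises(ValidationError, match="void"):
            w.compute_tpm(counts, cat)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(5):
            n, m = 50, 8
            cat = make_catalog(
                [{"id": f"g{i}", "length": int(rng.integers(200, 5000))} for i in range(n)]
            )
            counts = pd.DataFrame(
                rng.integers(0, 500, (n, m)),
                index=cat.ids,
                columns=[f"L{j}" for j in range(m)],
            )
            counts.iloc[0] += 1  # no all-zero library
            expected = brute_force_tpm(counts, dict(cat.frame["length_bp"]))
            got = w.compute_tpm(counts, cat)
            assert np.allclose(got, expected, rtol=1e-9)


class TestLowExpressionFilter:
    def _tpm(self, rows: dict) -> pd.DataFrame:
        return pd.DataFrame(rows).T

    def test_below_everywhere_removed_one_spike_retained(self):
        tpm = self._tpm({"dim": [0.05, 0.05], "spiky": [0.05, 0.2], "hot": [5.0, 5.0]})
        kept, n = w.filter_low_expression(tpm, 0.1)
        assert n == 1
        assert list(kept.index) == ["spiky", "hot"]

    def test_exact_exclusion_count(self):
        tpm = self._tpm(
            {
                "a": [0.01, 0.02],
                "b": [0.09, 0.099],
                "c": [0.1, 0.0],
                "d": [1.0, 1.0],
                "e": [0.0, 50.0],
            }
        )
        _kept, n = w.filter_low_expression(tpm, 0.1)
        assert n == 2

    def test_boundary_inclusive(self):
        tpm = self._tpm({"edge": [0.1, 0.0]})
        kept, n = w.filter_low_expression(tpm, 0.1)
        assert n == 0 and "edge" in kept.index

    def test_no_renormalization_deficit_equals_removed_mass(self, rng):
        cat = make_catalog([{"id": f"g{i}"} for i in range(20)])
        counts = pd.DataFrame(
            rng.integers(0, 40, (20, 3)), index=cat.ids, columns=["a", "b", "c"]
        )
        counts.iloc[0] += 10_000_000  # force most genes below threshold
        tpm = w.compute_tpm(counts, cat)
        kept, _n = w.filter_low_expression(tpm, 0.1)
        removed_mass = tpm.loc[~tpm.index.isin(kept.index)].sum(axis=0)
        assert np.allclose(kept.sum(axis=0) + removed_mass, 1e6, rtol=1e-9)


class TestTaxonNormalize:
    def test_two_members_rescaled(self):
        cat = make_catalog(
            [
                {"id": "a", "supergroup": "Haptophyta"},
                {"id": "b", "supergroup": "Haptophyta"},
                {"id": "c", "supergroup": "Dinophyta"},
            ]
        )
        tpm = pd.DataFrame({"L0": [3.0, 7.0, 90.0]}, index=["a", "b", "c"])
        norm = w.taxon_normalize(tpm, cat, ("supergroup", "Haptophyta"))
        assert norm.loc["a", "L0"] == pytest.approx(3e5)
        assert norm.loc["b", "L0"] == pytest.approx(7e5)
        assert "c" not in norm.index

    def test_absent_library_is_nan_not_zero(self):
        cat = make_catalog([{"id": "a", "supergroup": "Haptophyta"}, {"id": "c"}])
        tpm = pd.DataFrame({"L0": [0.0, 5.0], "L1": [2.0, 5.0]}, index=["a", "c"])
        norm = w.taxon_normalize(tpm, cat, ("supergroup", "Haptophyta"))
        assert np.isnan(norm.loc["a", "L0"])
        assert norm.loc["a", "L1"] == pytest.approx(1e6)

    def test_unmatched_selector_raises(self):
        cat = make_catalog([{"id": "a"}])
        tpm = pd.DataFrame({"L0": [1.0]}, index=["a"])
        with pytest.raises(ValidationError, match="matches no unigene"):
            w.taxon_normalize(tpm, cat, ("supergroup", "Nope"))


class TestActivities:
    def _fixture(self):
        cat = make_catalog(
            [
                {"id": "r1", "supergroup": "Bacillariophyta", "order": "Bacillariales",
                 "kos": ["K01601"]},
                {"id": "r2", "supergroup": "Bacillariophyta", "order": "Bacillariales",
                 "kos": ["K01602"]},
                {"id": "r3", "supergroup": "Cyanobacteria", "order": "Synechococcales",
                 "kos": ["K01601", "K01602"]},  # both markers: counted once
                {"id": "bg", "supergroup": "Bacillariophyta", "order": "Bacillariales"},
            ]
        )
        tpm = pd.DataFrame(
            {"L0": [2.5, 1.5, 6.0, 100.0], "L1": [1.0, 0.0, 3.0, 50.0]},
            index=cat.ids,
        )
        return cat, tpm

    def test_ccf_sums_marker_tpm_per_lineage(self, pathways):
        cat, tpm = self._fixture()
        act = w.ccf_activity(tpm, cat, pathways, rank="supergroup")
        assert act.values.loc["Bacillariophyta", "L0"] == pytest.approx(4.0)
        assert act.values.loc["Cyanobacteria", "L0"] == pytest.approx(6.0)

    def test_partition_additivity(self, pathways):
        cat, tpm = self._fixture()
        for rank in ("supergroup", "order", "domain"):
            act = w.ccf_activity(tpm, cat, pathways, rank=rank)
            total = act.values.sum(axis=0)
            assert total["L0"] == pytest.approx(10.0)
            assert total["L1"] == pytest.approx(4.0)

    def test_invalid_rank(self, pathways):
        cat, tpm = self._fixture()
        with pytest.raises(ValidationError, match="rank"):
            w.ccf_activity(tpm, cat, pathways, rank="family")

    def test_ncf_mean_per_defined_gene(self, pathways):
        union = pathways.ncf_union
        picked = union[:4]
        cat = make_catalog(
            [{"id": f"n{i}", "supergroup": "Proteobacteria", "order": "SAR11",
              "kos": [k]} for i, k in enumerate(picked)]
        )
        tpm = pd.DataFrame({"L0": [5.0, 5.0, 5.0, 5.0]}, index=cat.ids)
        act = w.ncf_activity(tpm, cat, pathways, rank="order")
        assert act.values.loc["SAR11", "L0"] == pytest.approx(20.0 / len(union))

    def test_ncf_linearity(self, pathways):
        union = pathways.ncf_union
        cat = make_catalog(
            [{"id": "n0", "order": "SAR11", "kos": [union[0]]}]
        )
        tpm = pd.DataFrame({"L0": [3.0]}, index=["n0"])
        a1 = w.ncf_activity(tpm, cat, pathways, rank="order").values.iloc[0, 0]
        a2 = w.ncf_activity(tpm * 2, cat, pathways, rank="order").values.iloc[0, 0]
        assert a2 == pytest.approx(2 * a1)

    def test_ncf_detected_denominator_variant(self, pathways):
        union = pathways.ncf_union
        cat = make_catalog(
            [{"id": f"n{i}", "order": "SAR11", "kos": [k]} for i, k in enumerate(union[:4])]
        )
        tpm = pd.DataFrame({"L0": [5.0, 5.0, 5.0, 5.0]}, index=cat.ids)
        act = w.ncf_activity(tpm, cat, pathways, rank="order", denominator="detected")
        assert act.values.loc["SAR11", "L0"] == pytest.approx(5.0)


class TestCompleteness:
    def _support(self, n_expressed: int) -> pd.DataFrame:
        return pd.DataFrame({"L0": [n_expressed], "L1": [1]}, index=["OrderX"])

    @pytest.mark.parametrize("n,kept", [(14, False), (15, True), (16, True)])
    def test_threshold_boundary(self, n, kept):
        retained, report = w.completeness_filter(self._support(n), min_genes=15)
        assert ("OrderX" in retained) is kept
        assert report.loc["OrderX", "max_genes_expressed"] == n

    def test_min_one_keeps_anything_expressed(self):
        retained, _ = w.completeness_filter(self._support(1), min_genes=1)
        assert retained == ["OrderX"]

    def test_support_counts_distinct_kos(self, pathways):
        union = pathways.ncf_union
        # two unigenes carrying the same KO count once; expression in a single
        # library only counts there
        cat = make_catalog(
            [
                {"id": "a", "order": "Ord", "kos": [union[0]]},
                {"id": "b", "order": "Ord", "kos": [union[0]]},
                {"id": "c", "order": "Ord", "kos": [union[1]]},
            ]
        )
        tpm = pd.DataFrame({"L0": [1.0, 2.0, 1.0], "L1": [1.0, 0.0, 0.0]}, index=cat.ids)
        support = w.pathway_gene_support(tpm, cat, union, rank="order")
        assert support.loc["Ord", "L0"] == 2
        assert support.loc["Ord", "L1"] == 1


class TestContribution:
    def test_arithmetic(self, pathways):
        act = w.ActivityTable(
            pd.DataFrame({"c1": [6.0, 3.0, 1.0]}, index=["x", "y", "z"]),
            pathway="ccf", statistic="rubisco_tpm_sum", rank="order",
        )
        contrib = w.relative_contribution(act)
        assert list(contrib.values["c1"]) == pytest.approx([60.0, 30.0, 10.0])

    def test_single_lineage_is_100(self, pathways):
        act = w.ActivityTable(
            pd.DataFrame({"c1": [0.42]}, index=["only"]),
            pathway="ccf", statistic="rubisco_tpm_sum", rank="order",
        )
        assert w.relative_contribution(act).values.iloc[0, 0] == pytest.approx(100.0)

    def test_zero_pool_is_nan(self):
        act = w.ActivityTable(
            pd.DataFrame({"c1": [0.0, 0.0]}, index=["x", "y"]),
            pathway="ccf", statistic="rubisco_tpm_sum", rank="order",
        )
        assert w.relative_contribution(act).values["c1"].isna().all()

    @given(
        vals=st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=2, max_size=8,
        ).filter(lambda v: sum(v) > 1e-6)
    )
    @settings(max_examples=100, deadline=None)
    def test_columns_sum_to_100(self, vals):
        act = w.ActivityTable(
            pd.DataFrame({"c": vals}),
            pathway="ccf", statistic="rubisco_tpm_sum", rank="order",
        )
        contrib = w.relative_contribution(act)
        assert contrib.values["c"].sum() == pytest.approx(100.0, abs=1e-9)


class TestReplicateAggregation:
    def test_mean_within_condition(self):
        samples = make_samples(4)  # 2 stations x 2 replicates, small only
        vals = pd.DataFrame(
            {"L00": [1.0], "L01": [3.0], "L02": [10.0], "L03": [20.0]}, index=["x"]
        )
        act = w.ActivityTable(vals, pathway="ccf", statistic="rubisco_tpm_sum", rank="order")
        agg = w.aggregate_replicates(act, samples)
        assert agg.by_condition
        assert agg.values.loc["x", "st0_SUR"] == pytest.approx(2.0)
        assert agg.values.loc["x", "st1_SUR"] == pytest.approx(15.0)
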