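"""Weighted multi-site aggregation, break-out, triggers and versioning."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import baskethta as b
from baskethta.engine import IncrementalResult

from .conftest import make_arm


def inc(dc, de, wtp=100_000.0) -> IncrementalResult:
    from baskethta.engine import classify

    cls = classify(dc, de)
    return IncrementalResult(dc, de, cls, dc / de if cls == "icer_defined" else None,
                             wtp * de - dc, wtp)


def two_site_model(grid=None) -> b.MultiSiteModel:
    grid = grid or b.TimeGrid(1.0, 240.0)
    sites = [
        b.SiteSubmodel(
            site_id="A", weight_source_count=50,
            intervention=make_arm(0.03, 0.05, grid, drug_cost_per_cycle=5000.0),
            comparator=make_arm(0.05, 0.09, grid, drug_cost_per_cycle=1000.0),
        ),
        b.SiteSubmodel(
            site_id="B", weight_source_count=50,
            intervention=make_arm(0.04, 0.07, grid, drug_cost_per_cycle=5000.0),
            comparator=make_arm(0.05, 0.08, grid, drug_cost_per_cycle=1000.0),
        ),
    ]
    return b.MultiSiteModel(sites, grid, b.EconomicParams(0.03, 0.03, True),
                            wtp=100_000.0)


class TestWeights:
    def test_equal_counts(self):
        w = b.normalize_weights({"A": 50, "B": 50})
        assert w["A"] == w["B"] == 0.5

    def test_single_site(self):
        assert b.normalize_weights({"A": 1})["A"] == 1.0

    def test_hand_arithmetic(self):
        w = b.normalize_weights({"A": 30, "B": 45, "C": 75})
        assert (w["A"], w["B"], w["C"]) == (0.2, 0.3, 0.5)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            b.normalize_weights({"A": 0, "B": 0})

    def test_weight_set_must_sum_to_one(self):
        with pytest.raises(ValueError):
            b.WeightSet({"A": 0.5, "B": 0.6})


class TestAggregate:
    def test_worked_two_site_case(self):
        """Weighted sums first, ICER last - never the mean of site ICERs."""
        per_site = {"A": inc(100_000.0, 2.0), "B": inc(50_000.0, 0.5)}
        res = b.aggregate(per_site, b.normalize_weights({"A": 1, "B": 1}))
        assert res.delta_cost_agg == pytest.approx(75_000.0)
        assert res.delta_qaly_agg == pytest.approx(1.25)
        assert res.icer_agg == pytest.approx(60_000.0)
        mean_of_icers = np.mean([per_site["A"].icer, per_site["B"].icer])
        assert mean_of_icers == pytest.approx(75_000.0)
        assert res.icer_agg != mean_of_icers

    def test_identical_sites_equal_aggregate(self):
        r = inc(80_000.0, 1.0)
        res = b.aggregate({"A": r, "B": r}, b.normalize_weights({"A": 3, "B": 7}))
        assert res.delta_cost_agg == pytest.approx(r.delta_cost)
        assert res.icer_agg == pytest.approx(r.icer)

    def test_degenerate_weight_identity(self):
        per_site = {"A": inc(100_000.0, 2.0), "B": inc(50_000.0, 0.5)}
        res = b.aggregate(per_site, b.WeightSet({"A": 1.0, "B": 0.0}))
        assert res.delta_cost_agg == per_site["A"].delta_cost
        assert res.delta_qaly_agg == per_site["A"].delta_qaly
        assert res.icer_agg == per_site["A"].icer

    def test_key_mismatch_lists_sites(self):
        with pytest.raises(KeyError, match="B"):
            b.aggregate({"A": inc(1.0, 1.0)},
                        b.normalize_weights({"A": 1, "B": 1}))

    def test_mediant_bound(self):
        """With all dE > 0 the pooled ICER lies between site ICER extremes."""
        rng = np.random.default_rng(77)
        for _ in range(1000):
            k = rng.integers(2, 6)
            dc = rng.normal(50_000, 50_000, k)
            de = rng.uniform(0.05, 2.0, k)
            w = rng.dirichlet(np.ones(k))
            per_site = {f"s{i}": inc(dc[i], de[i]) for i in range(k)}
            res = b.aggregate(per_site,
                              b.WeightSet({f"s{i}": w[i] for i in range(k)}))
            icers = dc / de
            agg_icer = res.delta_cost_agg / res.delta_qaly_agg
            assert icers.min() - 1e-9 <= agg_icer <= icers.max() + 1e-9

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.permutations(["A", "B", "C"]))
    def test_permutation_invariance(self, order):
        per = {"A": inc(10_000.0, 0.2), "B": inc(-5_000.0, 0.6),
               "C": inc(90_000.0, 1.4)}
        w = b.normalize_weights({"A": 10, "B": 20, "C": 70})
        res = b.aggregate({k: per[k] for k in order}, w)
        base = b.aggregate(per, w)
        assert res.delta_cost_agg == base.delta_cost_agg
        assert res.delta_qaly_agg == base.delta_qaly_agg


class TestBreakout:
    def test_noop_breakout_leaves_aggregate_unchanged(self):
        model = two_site_model()
        before = model.evaluate()
        site = model.sites["A"]
        model.breakout("A", {"intervention": site.intervention.copy(),
                             "comparator": site.comparator.copy()})
        after = model.evaluate()
        assert after.delta_cost_agg == pytest.approx(before.delta_cost_agg,
                                                     abs=1e-9)
        assert after.delta_qaly_agg == pytest.approx(before.delta_qaly_agg,
                                                     abs=1e-9)

    def test_breakout_shifts_aggregate_by_weighted_amount(self):
        model = two_site_model()
        before = model.evaluate()
        grid = model.grid
        better = {
            "intervention": make_arm(0.02, 0.04, grid, drug_cost_per_cycle=5000.0),
            "comparator": model.sites["A"].comparator.copy(),
        }
        model.breakout("A", better)
        after = model.evaluate()
        w = model.weights()["A"]
        predicted = before.delta_qaly_agg + w * (
            after.per_site["A"].delta_qaly - before.per_site["A"].delta_qaly)
        assert after.delta_qaly_agg == pytest.approx(predicted, abs=1e-9)
        assert after.per_site["A"].delta_qaly > before.per_site["A"].delta_qaly

    def test_breakout_locality(self):
        model = two_site_model()
        before = model.evaluate()
        model.breakout("A", {
            "intervention": make_arm(0.02, 0.04, model.grid,
                                     drug_cost_per_cycle=6000.0),
            "comparator": model.sites["A"].comparator.copy(),
        })
        after = model.evaluate()
        assert after.per_site["B"].delta_cost == before.per_site["B"].delta_cost
        assert after.per_site["B"].delta_qaly == before.per_site["B"].delta_qaly
        assert model.sites["A"].evidence_level == "site_specific"
        assert model.sites["B"].evidence_level == "pooled"

    def test_unknown_site_and_missing_fields(self):
        model = two_site_model()
        with pytest.raises(KeyError, match="nowhere"):
            model.breakout("nowhere", {})
        with pytest.raises(ValueError, match="comparator"):
            model.breakout("A", {"intervention": model.sites["A"].intervention})


class TestTriggers:
    def test_boundary_inclusive(self):
        model = two_site_model()
        model.record_version(timestamp="t0")
        due = b.check_reanalysis_triggers(model, {"A": 50, "B": 49},
                                          {"min_new_n": 50})
        assert due == ["A"]

    def test_elementwise_rule(self):
        model = two_site_model()
        model.sites["A"].evidence_n = 10
        model.sites["B"].evidence_n = 10
        model.record_version(timestamp="t0")
        due = b.check_reanalysis_triggers(model, {"A": 70, "B": 20},
                                          {"min_new_n": 50})
        assert due == ["A"]

    def test_negative_counts_error(self):
        model = two_site_model()
        with pytest.raises(ValueError):
            b.check_reanalysis_triggers(model, {"A": -1}, {"min_new_n": 50})

    def test_pure_function(self):
        model = two_site_model()
        snapshot = copy.deepcopy(model.snapshot())
        b.check_reanalysis_triggers(model, {"A": 500}, {"min_new_n": 50})
        assert model.snapshot() == snapshot


class TestVersions:
    def test_version_log_append_only_and_ordered(self):
        model = two_site_model()
        v1 = model.record_version(timestamp="t1")
        v2 = model.breakout("A", {
            "intervention": model.sites["A"].intervention.copy(),
            "comparator": model.sites["A"].comparator.copy(),
        }, timestamp="t2")
        assert [v.version_id for v in model.versions] == [1, 2]
        assert v1.version_id < v2.version_id

    def test_snapshot_reproduces_results_bit_for_bit(self):
        model = two_site_model()
        v = model.record_version(timestamp="t1")
        rebuilt = b.MultiSiteModel.from_snapshot(v.spec_snapshot)
        res = rebuilt.evaluate()
        assert res.delta_cost_agg == v.results.delta_cost_agg
        assert res.delta_qaly_agg == v.results.delta_qaly_agg
        assert res.icer_agg == v.results.icer_agg

    def test_diff_identical_versions_is_zero(self):
        model = two_site_model()
        v1 = model.record_version(timestamp="t1")
        v2 = model.record_version(timestamp="t2")
        report = b.diff_versions(v1, v2)
        assert report["aggregate"]["delta_cost_change"] == 0.0
        assert report["changed_fields"] == []

    def test_diff_localises_single_site_change(self):
        model = two_site_model()
        v1 = model.record_version(timestamp="t1")
        model.sites["B"].intervention.drug_cost_per_cycle += 500.0
        v2 = model.record_version(timestamp="t2")
        report = b.diff_versions(v1, v2)
        assert report["per_site"]["A"]["delta_cost_change"] == 0.0
        assert report["per_site"]["B"]["delta_cost_change"] > 0.0
        assert all("sites.B" in f or f.startswith("sites.B")
                   for f in report["changed_fields"])

    def test_diff_aggregate_consistent_with_per_site(self):
        model = two_site_model()
        v1 = model.record_version(timestamp="t1")
        model.sites["B"].intervention.drug_cost_per_cycle += 500.0
        model.sites["A"].intervention.utility_pf = 0.9
        v2 = model.record_version(timestamp="t2")
        report = b.diff_versions(v1, v2)
        w = model.weights()
        recomputed = sum(w[s] * report["per_site"][s]["delta_cost_change"]
                         for s in ("A", "B"))
        assert report["aggregate"]["delta_cost_change"] == pytest.approx(
            recomputed, abs=1e-9)

    def test_diff_requires_distinct_ordered_versions(self):
        model = two_site_model()
        v1 = model.record_version(timestamp="t1")
        with pytest.raises(ValueError):
            b.diff_versions(v1, v1)
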