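"""Summary statistics, urbanicity classes, regional aggregation, beta sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokeaccess import (
    accessibility_surface,
    aggregate_by_region,
    beta_sweep,
    build_problem,
    classify_urbanicity,
    crowdedness_surface,
    solve_allocation,
    summarize_access,
    summarize_crowdedness,
    weighted_median,
    weighted_sd,
)

from conftest import make_instance, random_instance, toy_expected


class TestWeightedMedian:
    def test_singleton(self):
        assert weighted_median([5], [10]) == 5

    def test_half_total_reached_at_middle_value(self):
        # cumulative weights 1, 2, 4; half-total 2 first reached at value 2
        assert weighted_median([1, 2, 3], [1, 1, 2]) == 2

    def test_zero_weight_values_ignored(self):
        assert weighted_median([1, 2], [0, 7]) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_median([], [])

    @settings(deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_equal_weights_reduce_to_lower_median(self, values):
        v = sorted(values)
        lower_median = v[(len(v) - 1) // 2]
        assert weighted_median(values, np.ones(len(values))) == lower_median


class TestWeightedSD:
    def test_symmetric_pair(self):
        assert weighted_sd([1, 3], [1, 1]) == pytest.approx(1.0)

    def test_asymmetric_weights(self):
        # weighted mean 1.5; sum w (v - mean)^2 / sum w = (3*0.25 + 2.25)/4
        assert weighted_sd([1, 3], [3, 1]) == pytest.approx(np.sqrt(0.75))

    def test_constant_vector_has_zero_spread(self):
        assert weighted_sd([7, 7, 7], [1, 2, 3]) == 0.0


class TestSummaries:
    def test_access_summary_on_toy(self, toy_2x2):
        exp = toy_expected()
        surf = accessibility_surface(
            toy_2x2.meshes, toy_2x2.facilities, toy_2x2.travel_times, scale=1.0
        )
        summary = summarize_access(surf, toy_2x2.meshes)
        # equal demand weights: lower median is the smaller accessibility value
        assert summary.weighted_median == pytest.approx(exp["A2"], rel=1e-12)
        assert summary.min == pytest.approx(exp["A2"], rel=1e-12)
        assert summary.max == pytest.approx(exp["A1"], rel=1e-12)
        assert summary.min <= summary.weighted_median <= summary.max

    def test_access_summary_after_symmetric_optimization(self, toy_2x2):
        opt = toy_2x2.with_staff([1.5, 1.5])
        surf = accessibility_surface(opt.meshes, opt.facilities, opt.travel_times, scale=1.0)
        summary = summarize_access(surf, opt.meshes, scenario="optimized")
        assert summary.weighted_sd == pytest.approx(0.0, abs=1e-15)
        assert surf.access == pytest.approx([0.015, 0.015], rel=1e-12)

    def test_crowdedness_summary_on_toy(self, toy_2x2):
        exp = toy_expected()
        surf = crowdedness_surface(toy_2x2.meshes, toy_2x2.facilities, toy_2x2.travel_times)
        summary = summarize_crowdedness(surf, toy_2x2.facilities)
        assert summary.mean == pytest.approx((exp["C1"] + exp["C2"]) / 2, rel=1e-12)
        assert summary.mean == pytest.approx(67.5155, abs=5e-4)
        assert summary.staffed_count == 2

    def test_staffed_threshold_semantics(self, toy_2x2):
        surf = crowdedness_surface(toy_2x2.meshes, toy_2x2.facilities, toy_2x2.travel_times)
        facs = toy_2x2.facilities.copy()
        facs["staff"] = [0.005, 2.995]
        summary = summarize_crowdedness(surf, facs)
        assert summary.staffed_count == 1
        facs["staff"] = [0.0, 3.0]
        assert summarize_crowdedness(surf, facs).staffed_count == 1


class TestClassifyUrbanicity:
    def test_floor_quartiles_on_eight_regions(self):
        regions = pd.DataFrame(
            {"region_id": [f"r{i}" for i in range(8)],
             "urban_proportion": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]}
        )
        out = classify_urbanicity(regions)
        by = out.set_index("urban_proportion")["urbanicity_class"]
        assert set(by.loc[[0.8, 0.7]]) == {"high"}
        assert set(by.loc[[0.1, 0.2]]) == {"low"}
        assert (by.loc[[0.3, 0.4, 0.5, 0.6]] == "medium").all()

    def test_identical_proportions_split_deterministically(self):
        regions = pd.DataFrame(
            {"region_id": ["a", "b", "c", "d"], "urban_proportion": [0.5] * 4}
        )
        out1 = classify_urbanicity(regions)
        out2 = classify_urbanicity(regions.copy())
        assert (out1["urbanicity_class"] == out2["urbanicity_class"]).all()
        assert (out1["urbanicity_class"] == "high").sum() == 1
        assert (out1["urbanicity_class"] == "low").sum() == 1

    def test_forty_seven_regions_mirror_prefecture_split(self):
        rng = np.random.default_rng(0)
        regions = pd.DataFrame(
            {"region_id": [f"r{i:02d}" for i in range(47)],
             "urban_proportion": rng.uniform(0, 1, 47)}
        )
        out = classify_urbanicity(regions)
        counts = out["urbanicity_class"].value_counts()
        assert counts["high"] == 11
        assert counts["low"] == 11
        assert counts["medium"] == 25

    def test_fewer_than_four_regions_all_medium(self, caplog):
        regions = pd.DataFrame({"region_id": ["a", "b"], "urban_proportion": [0.1, 0.9]})
        with caplog.at_level("WARNING"):
            out = classify_urbanicity(regions)
        assert (out["urbanicity_class"] == "medium").all()
        assert "degenerate" in caplog.text


class TestAggregateByRegion:
    def test_single_region_conserves_staff(self, toy_2x2):
        out = aggregate_by_region(
            toy_2x2.facilities,
            pci_current=np.array([60.0, 70.0]),
            pci_optimized=np.array([65.0, 65.0]),
            staff_current=np.array([2.0, 1.0]),
            staff_optimized=np.array([1.5, 1.5]),
            regions=toy_2x2.regions,
        )
        row = out.iloc[0]
        assert row["staff_current"] == 3.0
        assert row["delta_staff"] == 0.0
        assert row["mean_pci_current"] == 65.0

    def test_cross_region_deltas_cancel(self):
        facilities = pd.DataFrame(
            {"facility_id": ["f1", "f2"], "x": [0.0, 1.0], "y": [0.0, 1.0],
             "staff": [3.0, 0.0], "region_id": ["A", "B"]}
        )
        regions = pd.DataFrame({"region_id": ["A", "B"], "urban_proportion": [0.9, 0.1]})
        out = aggregate_by_region(
            facilities, np.array([1.0, 2.0]), np.array([1.5, 1.5]),
            np.array([3.0, 0.0]), np.array([0.0, 3.0]), regions,
        )
        assert out["delta_staff"].sum() == 0.0
        a, b = out.set_index("region_id").loc["A"], out.set_index("region_id").loc["B"]
        assert a["delta_staff"] == -b["delta_staff"] == -3.0
        assert a["mean_pci_current"] == 1.0  # singleton mean equals the facility value

    def test_region_without_facilities_keeps_zero_staff_and_nan_pci(self):
        facilities = pd.DataFrame(
            {"facility_id": ["f1"], "x": [0.0], "y": [0.0], "staff": [2.0], "region_id": ["A"]}
        )
        regions = pd.DataFrame({"region_id": ["A", "B"], "urban_proportion": [0.9, 0.1]})
        out = aggregate_by_region(
            facilities, np.array([1.0]), np.array([1.0]),
            np.array([2.0]), np.array([2.0]), regions,
        ).set_index("region_id")
        assert out.loc["B", "staff_current"] == 0.0
        assert np.isnan(out.loc["B", "mean_pci_current"])

    def test_unknown_region_rejected(self, toy_2x2):
        facilities = toy_2x2.facilities.copy()
        facilities.loc[0, "region_id"] = "nowhere"
        with pytest.raises(ValueError, match="unknown region"):
            aggregate_by_region(
                facilities, np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2),
                toy_2x2.regions,
            )


@pytest.fixture(scope="module")
def sweep_result():
    rng = np.random.default_rng(5)
    inst = random_instance(rng, n_meshes=60, n_facilities=10)
    return inst, beta_sweep(inst, scale=1.0)


class TestBetaSweep:
    def test_cardinality_six_betas_times_two_scenarios(self, sweep_result):
        _, sweep = sweep_result
        assert len(sweep.access) == 12
        assert len(sweep.crowdedness) == 12
        assert sorted(sweep.access["beta"].unique()) == [0.02, 0.03, 0.04, 0.05, 0.06, 0.07]

    def test_optimization_never_widens_access_dispersion(self, sweep_result):
        _, sweep = sweep_result
        table = sweep.access.pivot(index="beta", columns="scenario", values="weighted_sd")
        assert (table["optimized"] <= table["current"] + 1e-12).all()

    def test_demand_weighted_mean_access_pinned_for_every_beta(self, sweep_result):
        inst, sweep = sweep_result
        target = inst.total_staff / inst.total_demand
        D = inst.meshes["population"].to_numpy(float)
        for beta, solution in sweep.solutions.items():
            for staff in (inst.facilities["staff"].to_numpy(float), solution.staff):
                scen = inst.with_staff(staff)
                from strokeaccess import DecayConfig

                surf = accessibility_surface(
                    scen.meshes, scen.facilities, scen.travel_times,
                    DecayConfig(beta=beta), scale=1.0,
                )
                assert D @ surf.access / D.sum() == pytest.approx(target, rel=1e-9)

    def test_rejects_nonpositive_beta(self, toy_2x2):
        with pytest.raises(ValueError):
            beta_sweep(toy_2x2, betas=[0.07, -0.01])
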