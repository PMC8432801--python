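"""Standardization contracts: filters, list length, zero-filling, balancing."""

import numpy as np
import pandas as pd
import pytest

from birdindex import preprocess, synthetic
from birdindex.preprocess import FilterConfig
from birdindex.synthetic import ChecklistTable, StopTable

from conftest import fill_species, make_meta, make_obs


class TestFilterChecklists:
    def test_single_duration_violation(self, toy_checklists):
        out, tally = preprocess.filter_checklists(toy_checklists)
        assert len(out.meta) == 5
        assert tally["duration"] == 1

    def test_random_protocol_reclassified_by_distance(self):
        meta = make_meta(2, protocol=["random", "random"], distance_km=[0.0, 2.0])
        cl = ChecklistTable(meta, make_obs({"C0": fill_species(6), "C1": fill_species(6)}))
        out, _ = preprocess.filter_checklists(cl)
        got = out.meta.set_index("checklist_id")["protocol"]
        assert got["C0"] == "stationary" and got["C1"] == "traveling"

    def test_short_lists_removed(self):
        meta = make_meta(2)
        cl = ChecklistTable(meta, make_obs({"C0": fill_species(4), "C1": fill_species(5)}))
        out, tally = preprocess.filter_checklists(cl)
        assert out.meta["checklist_id"].tolist() == ["C1"]
        assert tally["min_species"] == 1

    def test_incomplete_and_season_rules(self):
        meta = make_meta(3, complete=[True, False, True],
                         date=["2010-06-01", "2010-06-01", "2010-04-30"])
        cl = ChecklistTable(meta, make_obs({f"C{i}": fill_species(6) for i in range(3)}))
        out, tally = preprocess.filter_checklists(cl)
        assert out.meta["checklist_id"].tolist() == ["C0"]
        assert tally["incomplete"] == 1 and tally["season"] == 1

    def test_unknown_protocol_rejected(self):
        meta = make_meta(1, protocol=["incidental"])
        cl = ChecklistTable(meta, make_obs({"C0": fill_species(6)}))
        with pytest.raises(ValueError, match="protocol"):
            preprocess.filter_checklists(cl)

    def test_idempotent(self):
        truth = synthetic.generate_truth(3, 3, [(0.5, 0.0, 0.2)], seed=1)
        cl = synthetic.simulate_checklists(
            truth, synthetic.EffortConfig(checklists_per_year=120), seed=2
        )
        once, _ = preprocess.filter_checklists(cl)
        twice, tally = preprocess.filter_checklists(once)
        pd.testing.assert_frame_equal(once.meta, twice.meta)
        assert all(v == 0 for v in tally.values())

    def test_zero_violation_rates_all_pass(self):
        truth = synthetic.generate_truth(2, 3, [(0.5, 0.0, 0.2)], seed=1)
        eff = synthetic.EffortConfig(
            checklists_per_year=150, frac_incomplete=0, frac_overlong=0,
            frac_overdistance=0, frac_bigparty=0, frac_out_of_season=0,
            richness_base=25.0,  # keep every list at >= 5 species
        )
        cl = synthetic.simulate_checklists(truth, eff, seed=3)
        out, tally = preprocess.filter_checklists(cl)
        assert len(out.meta) == len(cl.meta)
        assert all(v == 0 for v in tally.values())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(max_duration=-1)
        with pytest.raises(ValueError):
            FilterConfig(season_start=(7, 15), season_end=(5, 1))


class TestListLength:
    def test_distinct_species_count(self):
        cl = ChecklistTable(make_meta(1), make_obs({"C0": ["A", "B", "C"]}))
        assert preprocess.compute_list_length(cl)["C0"] == 3

    def test_duplicates_counted_once(self):
        obs = pd.DataFrame({"checklist_id": ["C0"] * 3, "species_id": ["A", "A", "B"],
                            "count": [1, 1, 1]})
        cl = ChecklistTable(make_meta(1), obs)
        assert preprocess.compute_list_length(cl)["C0"] == 2

    def test_group_checklists_merge_to_union(self):
        meta = make_meta(2, group_id=["G1", "G1"])
        cl = ChecklistTable(meta, make_obs({"C0": ["A", "B"], "C1": ["B", "C"]}))
        ll = preprocess.compute_list_length(cl)
        assert len(ll) == 1 and ll.iloc[0] == 3

    def test_empty_checklist_gets_zero(self):
        cl = ChecklistTable(make_meta(2), make_obs({"C0": ["A"]}))
        ll = preprocess.compute_list_length(cl)
        assert ll["C1"] == 0


class TestRestrictToRange:
    def _table(self):
        meta = make_meta(15, location_id=["L1"] * 4 + ["L2"] * 5 + ["L3"] * 6,
                         checklist_id=[f"C{i}" for i in range(15)])
        mapping = {f"C{i}": fill_species(5) for i in range(15)}
        mapping["C0"] = fill_species(5) + ["SP"]
        mapping["C5"] = fill_species(5) + ["SP"]
        return ChecklistTable(meta, make_obs(mapping))

    def test_surveys_outside_range_dropped(self):
        out = preprocess.restrict_to_range(self._table(), "SP")
        assert len(out.meta) == 9  # locations L1 (4) + L2 (5); L3's 6 dropped
        assert set(out.meta["location_id"]) == {"L1", "L2"}

    def test_identity_when_detected_everywhere(self):
        cl = self._table()
        cl.obs = pd.concat([cl.obs, make_obs({"C10": ["SP"]})], ignore_index=True)
        out = preprocess.restrict_to_range(cl, "SP")
        assert len(out.meta) == 15

    def test_never_detected_warns_and_empties(self):
        with pytest.warns(UserWarning, match="never detected"):
            out = preprocess.restrict_to_range(self._table(), "ABSENT")
        assert out.meta.empty


class TestZeroFill:
    def test_responses_and_conservation(self):
        cl = ChecklistTable(
            make_meta(3),
            make_obs({"C0": fill_species(5) + ["SP"], "C1": fill_species(5),
                      "C2": fill_species(5)}),
        )
        det = preprocess.zero_fill(cl, "SP")
        assert len(det) == 3
        assert det.set_index("unit_id")["response"].tolist() == [1, 0, 0]

    def test_centered_covariates_have_zero_mean(self):
        truth = synthetic.generate_truth(3, 3, [(0.5, 0.0, 0.2)], seed=1)
        cl = synthetic.simulate_checklists(
            truth, synthetic.EffortConfig(checklists_per_year=100), seed=2
        )
        det = preprocess.zero_fill(cl, "SP01")
        assert abs(det["doy_c"].mean()) < 1e-9
        assert abs(det["start_c"].mean()) < 1e-9

    def test_recentering_is_a_noop(self):
        cl = ChecklistTable(make_meta(4), make_obs({f"C{i}": fill_species(5) for i in range(4)}))
        det = preprocess.zero_fill(cl, "F0")
        again = preprocess.recenter(det)
        assert np.allclose(det["doy_c"], again["doy_c"], atol=1e-12)
        assert np.allclose(det["start_c"], again["start_c"], atol=1e-12)


def _balance_fixture(n_det=10, n_nondet=100):
    """Unique (town, year, week) stratum per row so dedup keeps everything."""
    n = n_det + n_nondet
    det = pd.DataFrame({
        "unit_id": [f"U{i}" for i in range(n)],
        "response": [1] * n_det + [0] * n_nondet,
        "town": [f"T{i}" for i in range(n)],  # one cell per row
        "year": 2010,
        "doy": 150.0,
        "doy_c": 0.0,
        "start_time": 0.3,
        "start_c": 0.0,
        "observer_id": "obs1",
        "list_length": 8,
        "protocol": "traveling",
        "species_id": "SP",
        "source": "checklist",
        "location_id": "L",
    })
    return det


class TestBalanceChecklists:
    def test_ratio_caps_nondetections(self):
        out = preprocess.balance_checklists(_balance_fixture(), seed=1, target_ratio=4.0)
        assert (out["response"] == 0).sum() <= 40
        assert (out["response"] == 1).sum() == 10

    def test_detections_never_dropped_by_ratio_or_year_stages(self):
        out = preprocess.balance_checklists(_balance_fixture(), seed=3, target_ratio=1.0)
        assert (out["response"] == 1).sum() == 10

    def test_deterministic_under_seed(self):
        a = preprocess.balance_checklists(_balance_fixture(), seed=9)
        b = preprocess.balance_checklists(_balance_fixture(), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_balanced_input_is_fixed_point_up_to_dedup(self):
        det = _balance_fixture(n_det=10, n_nondet=40)
        out = preprocess.balance_checklists(det, seed=2, target_ratio=4.0)
        assert len(out) == 50  # unique strata, ratio already met, one year

    def test_stratum_dedup_keeps_one_per_class(self):
        det = _balance_fixture(n_det=6, n_nondet=6)
        det["town"] = "T01"  # everything in one cell-week stratum
        out = preprocess.balance_checklists(det, seed=4, target_ratio=10.0)
        assert (out["response"] == 1).sum() == 1
        assert (out["response"] == 0).sum() == 1

    def test_year_downsampling_toward_min_year(self):
        det = _balance_fixture(n_det=10, n_nondet=100)
        det["year"] = [2010] * 55 + [2011] * 55
        out = preprocess.balance_checklists(det, seed=5, target_ratio=50.0,
                                            year_tolerance=0.25)
        sizes = out.groupby("year").size()
        assert sizes.max() <= np.ceil(sizes.min() * 1.25)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            preprocess.balance_checklists(_balance_fixture(), seed=1, target_ratio=0.0)


class TestBuildStopDetections:
    def test_thresholding_and_zero_materialization(self, toy_stops):
        det = preprocess.build_stop_detections(toy_stops, "A", mode="detection")
        assert len(det) == 6  # 2 runs x 3 stops
        run1 = det[det["unit_id"].str.startswith("R1-2010")]
        assert run1.sort_values("unit_id")["response"].tolist() == [1, 0, 1]
        run2 = det[det["unit_id"].str.startswith("R1-2011")]
        assert run2["response"].tolist() == [0, 0, 0]

    def test_count_mode_keeps_counts(self, toy_stops):
        det = preprocess.build_stop_detections(toy_stops, "A", mode="count")
        assert sorted(det["response"].tolist()) == [0, 0, 0, 0, 1, 2]

    def test_absent_species_gets_all_zero_rows(self, toy_stops):
        det = preprocess.build_stop_detections(toy_stops, "NEVER", mode="detection")
        assert len(det) == 6 and (det["response"] == 0).all()

    def test_low_quality_runs_removed(self, toy_stops):
        toy_stops.runs.loc[0, "quality"] = "bad"
        det = preprocess.build_stop_detections(toy_stops, "A")
        assert len(det) == 3

    def test_duplicate_rows_rejected(self, toy_stops):
        dup = toy_stops.counts.iloc[[0]]
        toy_stops.counts = pd.concat([toy_stops.counts, dup], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            preprocess.build_stop_detections(toy_stops, "A")

    def test_row_conservation_on_simulation(self):
        truth = synthetic.generate_truth(3, 3, [(0.8, 0.0, 0.2)], seed=1)
        st = synthetic.simulate_routes(truth, 4, stops_per_route=50, seed=2,
                                       bad_run_rate=0.0)
        det = preprocess.build_stop_detections(st, "SP01")
        assert len(det) == 4 * 3 * 50

    def test_route_range_restriction(self):
        truth = synthetic.generate_truth(3, 3, [(1e-9, 0.0, 0.0)], seed=1)
        st = synthetic.simulate_routes(truth, 3, seed=2)
        with pytest.warns(UserWarning):
            out = preprocess.restrict_stops_to_range(st, "SP01")
        assert out.runs.empty
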