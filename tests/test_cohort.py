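import numpy as np
import pandas as pd
import pytest

from readmit_rsf.cohort import (
    aggregate_features,
    assign_subcohort,
    facility_balanced_split,
    variance_filter,
)
from readmit_rsf.synthetic_ehr import ENCOUNTER_COLUMNS


def _mk_patient(pid="P1", fac="F01"):
    return pd.DataFrame([{
        "patient_id": pid, "facility_id": fac, "age_group": "50-65",
        "gender": "F", "payer": "medicare", "income_band": 3,
        "education_band": 2, "phenotype": -1,
    }])


def _mk_encounter(pid, eid, etype, discharge, los=0, **kw):
    row = {c: "" for c in ENCOUNTER_COLUMNS}
    row.update({
        "patient_id": pid, "encounter_id": eid, "encounter_type": etype,
        "admit_date": pd.Timestamp(discharge) - pd.Timedelta(days=los),
        "discharge_date": pd.Timestamp(discharge),
        "n_labs": 0, "n_meds": 0, "n_radiology": 0,
        "primary_dx": "DX01", "secondary_dx": "DX02",
    })
    row.update(kw)
    return row


def _mk_index(pid, iid, discharge):
    return pd.DataFrame([{
        "index_id": iid, "patient_id": pid,
        "discharge_date": pd.Timestamp(discharge),
        "true_time_to_readmission": 99, "event_within_30d": False,
        "observed_time": 30, "event_observed": False,
        "true_daily_hazard": 0.001, "true_prob_30d": 0.03, "phenotype": -1,
    }])


class TestAggregateFeatures:
    def test_lookback_window_excludes_old_and_post_index_visits(self):
        # 2 E + 1 I inside the year, 1 I at 400 days: only the 3 recent count
        enc = pd.DataFrame([
            _mk_encounter("P1", "E1", "E", "2012-06-01"),
            _mk_encounter("P1", "E2", "E", "2012-09-15"),
            _mk_encounter("P1", "E3", "I", "2012-11-01", los=3),
            _mk_encounter("P1", "E4", "I", "2011-11-27", los=5),  # 400 d old
            _mk_encounter("P1", "IDX", "I", "2013-01-01", los=2),
            _mk_encounter("P1", "E5", "O", "2013-01-20"),  # post-index
        ])
        feats = aggregate_features(_mk_patient(), enc,
                                   _mk_index("P1", "IDX", "2013-01-01"))
        row = feats.loc["IDX"]
        assert row["count_E"] == 2
        assert row["count_I"] == 1
        assert row["count_O"] == 0

    def test_no_lookback_encounters_gives_zero_counts(self):
        enc = pd.DataFrame([_mk_encounter("P1", "IDX", "I", "2013-01-01")])
        feats = aggregate_features(_mk_patient(), enc,
                                   _mk_index("P1", "IDX", "2013-01-01"))
        row = feats.loc["IDX"]
        assert row["count_E"] == row["count_I"] == row["labs_total"] == 0
        assert row["age_group_idx"] == 6  # demographics still populated
        assert row["is_female"] == 1

    def test_length_of_stay_is_additive(self):
        enc = pd.DataFrame([
            _mk_encounter("P1", "E1", "I", "2012-06-01", los=3),
            _mk_encounter("P1", "E2", "I", "2012-08-01", los=5),
            _mk_encounter("P1", "IDX", "I", "2013-01-01"),
        ])
        feats = aggregate_features(_mk_patient(), enc,
                                   _mk_index("P1", "IDX", "2013-01-01"))
        assert feats.loc["IDX", "total_los"] == 8

    def test_unknown_patient_raises(self):
        enc = pd.DataFrame([_mk_encounter("P1", "E1", "E", "2012-06-01")])
        with pytest.raises(ValueError, match="unknown patients"):
            aggregate_features(_mk_patient("P9"), enc,
                               _mk_index("P1", "IDX", "2013-01-01"))

    def test_post_index_data_never_leaks(self, small_cohort):
        patients, encounters, index = small_cohort
        base = aggregate_features(patients, encounters, index)
        idx_dates = index.set_index("patient_id")["discharge_date"]
        pre_only = encounters[
            encounters["discharge_date"]
            <= encounters["patient_id"].map(idx_dates)]
        again = aggregate_features(patients, pre_only, index)
        pd.testing.assert_frame_equal(base, again)


class TestVarianceFilter:
    def test_constant_feature_never_kept(self):
        df = pd.DataFrame({"a": [1, 1, 1, 1], "b": [1, 2, 3, 4],
                           "c": [0, 5, 0, 5]})
        assert "a" not in variance_filter(df, 2)

    def test_keep_all_when_n_keep_equals_p(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        assert sorted(variance_filter(df, 5)) == list("abcde")

    def test_matches_bruteforce_scaled_variance_ranking(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((200, 100)) ** rng.uniform(
            0.2, 5, 100), columns=[f"f{j:03d}" for j in range(100)])
        got = variance_filter(df, 10)
        x = df.to_numpy()
        scaled = (x - x.min(0)) / (x.max(0) - x.min(0))
        var = scaled.var(axis=0, ddof=1)
        expect = [c for _, c in sorted(zip(-var, df.columns))][:10]
        assert got == expect

    @pytest.mark.parametrize("n_keep", [0, -1, 999])
    def test_invalid_n_keep_rejected(self, n_keep):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            variance_filter(df, n_keep)


class TestSubcohorts:
    @pytest.mark.parametrize("chronic,ip,expected", [
        (2, 1, "CD+IP"),
        (0, 0, "neither"),
        (1, 0, "CD-only"),
        (0, 3, "IP-only"),
    ])
    def test_labels_follow_history_definition(self, chronic, ip, expected):
        df = pd.DataFrame({"chronic_count": [chronic], "count_I": [ip]})
        assert assign_subcohort(df).iloc[0] == expected

    def test_labels_partition_the_cohort(self, small_features):
        labels = assign_subcohort(small_features)
        assert labels.isin(["CD+IP", "CD-only", "IP-only", "neither"]).all()
        assert len(labels) == len(small_features)

    def test_missing_required_feature_raises(self):
        with pytest.raises(ValueError, match="chronic_count"):
            assign_subcohort(pd.DataFrame({"count_I": [1]}))


def _index_for_facilities(volumes: dict, month="2012-03"):
    rows = []
    k = 0
    for fac, vol in volumes.items():
        for _ in range(vol):
            rows.append({
                "index_id": f"I{k}", "patient_id": f"P{k}",
                "facility_id": fac,
                "discharge_date": pd.Timestamp(f"{month}-15"),
                "event_within_30d": k % 5 == 0,
            })
            k += 1
    return pd.DataFrame(rows)


class TestFacilitySplit:
    def test_two_identical_facilities_balance_exactly(self):
        idx = _index_for_facilities({"F1": 10, "F2": 10})
        split = facility_balanced_split(idx, seed=0)
        sides = set(split.facility_partition.values())
        assert sides == {1, 2}

    def test_four_facilities_match_exhaustive_optimum(self):
        # volumes {10,10,20,20}: the optimum pairs one of each size per side
        idx = _index_for_facilities({"F1": 10, "F2": 10, "F3": 20, "F4": 20})
        split = facility_balanced_split(idx, seed=0)
        part = split.facility_partition
        side1 = {f for f, s in part.items() if s == 1}
        vols = {"F1": 10, "F2": 10, "F3": 20, "F4": 20}
        assert sum(vols[f] for f in side1) == 30

    def test_single_facility_rejected(self):
        idx = _index_for_facilities({"F1": 8})
        with pytest.raises(ValueError, match="2 facilities"):
            facility_balanced_split(idx, seed=0)

    def test_blind_test_facilities_are_disjoint_from_training(
            self, small_cohort):
        patients, _, index = small_cohort
        merged = index.merge(patients[["patient_id", "facility_id"]],
                             on="patient_id")
        split = facility_balanced_split(
            merged, seed=1, prospective_start="2013-07-01")
        df = merged.set_index("index_id")
        fac = df["facility_id"]
        train_fac = set(fac[split.ids("train")]) | set(
            fac[split.ids("calibration")])
        blind_fac = set(fac[split.ids("blind_test")])
        assert train_fac.isdisjoint(blind_fac)
        # prospective rows are strictly later than every retrospective row
        retro_max = df.loc[split.assignment != "prospective",
                           "discharge_date"].max()
        prosp_min = df.loc[split.ids("prospective"), "discharge_date"].min()
        assert prosp_min > retro_max

    def test_train_calibration_split_is_at_patient_level(self, small_cohort):
        patients, _, index = small_cohort
        merged = index.merge(patients[["patient_id", "facility_id"]],
                             on="patient_id")
        split = facility_balanced_split(merged, seed=2)
        df = merged.set_index("index_id")
        train_p = set(df.loc[split.ids("train"), "patient_id"])
        cal_p = set(df.loc[split.ids("calibration"), "patient_id"])
        assert train_p.isdisjoint(cal_p)
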