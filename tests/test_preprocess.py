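"""Exclusion rules, POMP scaling, group assignment, and the cohort split."""

import numpy as np
import pandas as pd
import pytest

from latentchange.model import ModelError
from latentchange.preprocess import (
    apply_exclusions,
    assign_groups,
    scale_0_100,
    split_exploratory,
)
from latentchange.simulate import canonical_params, simulate_dataset, to_native_scale


def _raw_frame():
    n = 40
    rng = np.random.default_rng(2)
    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "friends_t1": rng.uniform(0, 80, n).round(),
        "caregiver_mon_t1": rng.normal(4.0, 0.4, n).clip(1, 5),
        "ct_t1": rng.normal(2.7, 0.1, n),
        "ct_t2": rng.normal(2.6, 0.1, n),
        "qc_exclude_flag_t1": 0,
        "qc_exclude_flag_t2": 0,
        "qc_clinical_score_t1": 1,
        "qc_clinical_score_t2": 1,
    })
    return df


class TestExclusions:
    def test_friend_counts_truncate_at_100(self):
        df = _raw_frame()
        df.loc[0, "friends_t1"] = 150.0
        out, log = apply_exclusions(df)
        assert out.loc[0, "friends_t1"] == 100.0
        entries = log.to_frame()
        row = entries[entries["rule"] == "truncate100"].iloc[0]
        assert row["original_value"] == 150.0 and row["variable"] == "friends"

    def test_qc_rules_blank_brain_values(self):
        df = _raw_frame()
        df.loc[1, "qc_clinical_score_t2"] = 3      # consider clinical referral
        df.loc[2, "qc_exclude_flag_t1"] = 1
        out, log = apply_exclusions(df)
        assert np.isnan(out.loc[1, "ct_t2"]) and np.isnan(out.loc[2, "ct_t1"])
        assert log.count("qc_clinical") == 1 and log.count("qc_recommend") == 1

    def test_zscore_rule_is_cellwise_and_strictly_beyond_five(self):
        df = _raw_frame()
        base = df["caregiver_mon_t1"].copy()
        # place one cell exactly at z = 5 and one strictly beyond
        m, s = base.mean(), base.std(ddof=0)
        df.loc[3, "caregiver_mon_t1"] = m + 5 * s  # shifts the moments slightly
        out, log = apply_exclusions(df, variables=("caregiver_mon",))
        vals = df["caregiver_mon_t1"]
        z = (vals - vals.mean()) / vals.std(ddof=0)
        expected_gone = set(df.index[z.abs() > 5])
        assert set(out.index[out["caregiver_mon_t1"].isna()]) == expected_gone
        assert log.count("zscore5") == len(expected_gone)
        # other columns untouched by the caregiver rule
        assert out["friends_t1"].notna().all()

    def test_exclusion_counts_match_log(self):
        df = _raw_frame()
        df.loc[0, "friends_t1"] = 500.0
        df.loc[4, "qc_exclude_flag_t2"] = 1
        out, log = apply_exclusions(df)
        assert log.count() == log.count("truncate100") + log.count("qc_recommend") + \
            log.count("qc_clinical") + log.count("zscore5")

    def test_idempotent_on_generated_cohort(self, canonical):
        scaled = simulate_dataset(canonical, 400, seed=5, include_demographics=True)
        native = to_native_scale(scaled)
        once, _ = apply_exclusions(native)
        twice, log2 = apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.count() == 0


class TestScaling:
    def test_pomp_examples(self):
        df = pd.DataFrame({"school_env_t1": [3.0, 1.0], "friends_t1": [37.0, 0.0]})
        out = scale_0_100(df, {"school_env": (1, 4), "friends": (0, 100)})
        assert out["school_env_t1"][0] == pytest.approx(100 * 2 / 3)
        assert out["school_env_t1"][1] == 0.0
        assert out["friends_t1"][0] == 37.0      # identity range

    def test_degenerate_range_rejected(self):
        with pytest.raises(ModelError, match="degenerate range"):
            scale_0_100(pd.DataFrame({"prosocial_t1": [1.0]}), {"prosocial": (2, 2)})

    def test_scale_then_unscale_round_trips(self, canonical):
        scaled = simulate_dataset(canonical, 200, seed=6)
        # drop friends: its native form is integer-rounded by design
        cols = [c for c in scaled.columns if c != "subject_id" and not c.startswith("friends")]
        native = to_native_scale(scaled[cols])
        back = scale_0_100(native)
        pd.testing.assert_frame_equal(back[cols], scaled[cols], atol=1e-10)

    def test_missing_cells_preserved(self):
        df = pd.DataFrame({"prosocial_t1": [1.0, np.nan]})
        out = scale_0_100(df, {"prosocial": (0, 2)})
        assert out["prosocial_t1"][0] == 50.0 and np.isnan(out["prosocial_t1"][1])


class TestGroups:
    def test_sex_by_puberty_labels(self):
        df = pd.DataFrame({
            "sex": ["F", "M", "M", "F"],
            "puberty_stage": ["early", "post", "missing", "mid"],
        })
        lab = assign_groups(df, "early_vs_nonearly")
        assert list(lab) == ["female_early", "male_nonearly", None, "female_nonearly"]
        lab_c = assign_groups(df, "consecutive")
        assert list(lab_c) == ["female_early", "male_late", None, "female_late"]

    def test_ses_median_tie_goes_high(self):
        df = pd.DataFrame({"parent_education_years": [12, 16, 16, 18, 21]})
        lab = assign_groups(df, "ses_median")
        assert list(lab) == ["low", "high", "high", "high", "high"]

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ModelError, match="unknown grouping"):
            assign_groups(pd.DataFrame({"sex": [], "puberty_stage": []}), "nope")


class TestSplit:
    def test_sizes_determinism_and_partition(self):
        df = pd.DataFrame({"x": np.arange(100)})
        a1, b1 = split_exploratory(df, 0.20, seed=9)
        a2, b2 = split_exploratory(df, 0.20, seed=9)
        assert len(a1) == 20 and len(b1) == 80
        pd.testing.assert_frame_equal(a1, a2)
        assert set(a1.index).isdisjoint(b1.index)
        assert set(a1.index) | set(b1.index) == set(df.index)

    def test_rounding_floors_first_part(self):
        df = pd.DataFrame({"x": np.arange(9)})
        a, b = split_exploratory(df, 0.5, seed=1)
        assert (len(a), len(b)) == (4, 5)

    def test_fraction_bounds(self):
        with pytest.raises(ModelError):
            split_exploratory(pd.DataFrame({"x": [1]}), 1.0, seed=0)
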