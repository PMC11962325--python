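"""Daily summarization, eGFR, deltas, imputation and scaling."""

import numpy as np
import pandas as pd
import pytest
from oracles import ckd_epi_2021_reference

from wardaki import (
    FeatureConfig,
    ScalerState,
    compute_delta,
    compute_egfr,
    fit_apply_scaler,
    impute,
    summarize_days,
)
from wardaki.cohort import EXPOSURE_FLAGS, Cohort, PatientAdmission
from wardaki.util import PipelineError

T0 = pd.Timestamp("2020-05-01 10:00")


def _cohort(measurement_rows, exposures=None, los=12):
    adm = PatientAdmission("P", 50, "female", T0,
                           T0.normalize() + pd.Timedelta(days=los - 1, hours=12))
    m = pd.DataFrame(measurement_rows,
                     columns=["patient_id", "analyte", "time", "value"])
    m = m.sort_values(["patient_id", "analyte", "time"]).reset_index(drop=True)
    if exposures is None:
        exposures = pd.DataFrame(columns=["patient_id", "day", *EXPOSURE_FLAGS])
    return Cohort({"P": adm}, m, exposures)


def day_time(d, h=9):
    return T0.normalize() + pd.Timedelta(days=d - 1, hours=h)


class TestEgfr:
    @pytest.mark.parametrize("scr,age,sex,expected", [
        (0.8, 50, "female", 89.7),
        (1.0, 60, "male", 86.2),
    ])
    def test_reference_values(self, scr, age, sex, expected):
        assert compute_egfr(scr, age, sex) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize("sex,kappa,factor", [("female", 0.7, 1.012),
                                                  ("male", 0.9, 1.0)])
    def test_at_kappa_both_spline_terms_vanish(self, sex, kappa, factor):
        age = 40
        assert compute_egfr(kappa, age, sex) == pytest.approx(
            142 * 0.9938 ** age * factor)

    def test_nonpositive_scr_rejected(self):
        with pytest.raises(ValueError):
            compute_egfr(0.0, 50, "female")

    def test_grid_agreement_with_independent_reference(self):
        for sex in ("female", "male"):
            for scr in np.arange(0.4, 4.01, 0.2):
                for age in range(19, 91, 7):
                    assert compute_egfr(scr, age, sex) == pytest.approx(
                        ckd_epi_2021_reference(scr, age, sex), abs=0.1)


class TestSummarize:
    def test_vital_aggregates(self):
        rows = [("P", "heart_rate", day_time(1, h), v)
                for h, v in [(11, 60.0), (14, 80.0), (20, 100.0)]]
        tab = summarize_days(_cohort(rows, los=2))
        r = tab[tab["day"] == 1].iloc[0]
        assert (r["heart_rate_mean"], r["heart_rate_max"], r["heart_rate_min"],
                r["heart_rate_count"]) == (80.0, 100.0, 60.0, 3.0)
        r2 = tab[tab["day"] == 2].iloc[0]
        assert r2["heart_rate_count"] == 0.0 and np.isnan(r2["heart_rate_mean"])

    def test_negative_vitals_rejected(self):
        rows = [("P", "heart_rate", day_time(1, 11), -5.0)]
        with pytest.raises(ValueError, match="negative vital"):
            summarize_days(_cohort(rows))

    def test_labs_carry_forward_with_provenance(self):
        rows = [("P", "SCr", day_time(1, 11), 0.8), ("P", "SCr", day_time(3), 1.0)]
        tab = summarize_days(_cohort(rows, los=4)).set_index("day")
        assert tab.loc[1, "SCr_src"] == "observed"
        assert tab.loc[2, "SCr"] == 0.8 and tab.loc[2, "SCr_src"] == "carried"
        assert tab.loc[3, "SCr"] == 1.0 and tab.loc[4, "SCr_src"] == "carried"

    def test_delta_is_current_minus_median_of_history(self):
        assert compute_delta([0.8, 1.0], 1.3) == pytest.approx(0.4)
        assert compute_delta([1.0], 1.0) == 0.0
        assert np.isnan(compute_delta([], 1.0))
        rows = [("P", "SCr", day_time(d), v)
                for d, v in [(1, 0.8), (2, 1.0), (3, 1.3)]]
        tab = summarize_days(_cohort(rows, los=3)).set_index("day")
        assert np.isnan(tab.loc[1, "SCr_delta"])  # no history on day 1
        assert tab.loc[3, "SCr_delta"] == pytest.approx(0.4)

    def test_exposure_flag_covers_trailing_seven_days(self):
        exp = pd.DataFrame([{"patient_id": "P", "day": day_time(3, 0).normalize(),
                             **{f: f == "surgery" for f in EXPOSURE_FLAGS}}])
        rows = [("P", "SCr", day_time(1, 11), 0.8)]
        tab = summarize_days(_cohort(rows, exposures=exp, los=11)).set_index("day")
        assert all(tab.loc[d, "exp_surgery"] == 1.0 for d in range(3, 10))
        assert tab.loc[2, "exp_surgery"] == 0.0 and tab.loc[10, "exp_surgery"] == 0.0

    def test_bun_cr_ratio_and_egfr(self):
        rows = [("P", "SCr", day_time(1, 11), 0.8), ("P", "BUN", day_time(1, 12), 16.0)]
        tab = summarize_days(_cohort(rows, los=1))
        assert tab["bun_cr_ratio"].iloc[0] == pytest.approx(20.0)
        assert tab["egfr"].iloc[0] == pytest.approx(89.7, abs=0.05)


class TestImpute:
    def _table(self, n=200, missing_a=0.05, missing_b=0.4, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "a": rng.normal(size=n), "b": rng.normal(2, 1, size=n),
            "c": rng.normal(5, 2, size=n),
        })
        df.loc[rng.random(n) < missing_a, "a"] = np.nan
        df.loc[rng.random(n) < missing_b, "b"] = np.nan
        df["a_src"] = np.where(df["a"].isna(), "missing", "observed")
        return df

    def test_low_missingness_imputed_high_categorized(self):
        df = self._table()
        out, policy = impute(df, ["a", "b", "c"], np.ones(len(df), bool), seed=1)
        assert "a" in policy["numeric"] and "b" in policy["categorical"]
        assert out["a"].notna().all()
        assert "b__missing" in out.columns and "b" not in out.columns
        assert (out.loc[out["b__missing"] == 1].filter(like="b__bin").sum(axis=1)
                == 0).all()

    def test_provenance_updated(self):
        df = self._table()
        was_missing = df["a"].isna()
        out, _ = impute(df, ["a", "b", "c"], np.ones(len(df), bool))
        assert (out.loc[was_missing, "a_src"] == "imputed").all()
        assert (out.loc[~was_missing, "a_src"] == "observed").all()

    def test_fully_observed_feature_untouched(self):
        df = self._table()
        out, _ = impute(df, ["a", "b", "c"], np.ones(len(df), bool))
        pd.testing.assert_series_equal(out["c"], df["c"])

    def test_empty_train_mask_is_leakage_error(self):
        df = self._table()
        with pytest.raises(PipelineError):
            impute(df, ["a"], np.zeros(len(df), bool))

    def test_deterministic_under_fixed_seed(self):
        df = self._table()
        o1, _ = impute(df, ["a", "b", "c"], np.ones(len(df), bool), seed=3)
        o2, _ = impute(df, ["a", "b", "c"], np.ones(len(df), bool), seed=3)
        pd.testing.assert_frame_equal(o1, o2)

    def test_evaluation_rows_cannot_influence_training_output(self):
        # shuffling (even rewriting) evaluation rows leaves train-side
        # transformed values bit-identical
        df = self._table(n=300)
        mask = np.zeros(len(df), bool)
        mask[:200] = True
        out1, _ = impute(df, ["a", "b", "c"], mask, seed=2)
        df2 = df.copy()
        df2.loc[~mask, ["a", "b", "c"]] = df2.loc[~mask, ["a", "b", "c"]].to_numpy()[::-1]
        out2, _ = impute(df2, ["a", "b", "c"], mask, seed=2)
        num_cols = [c for c in out1.columns if out1[c].dtype.kind == "f"]
        pd.testing.assert_frame_equal(out1.loc[mask, num_cols],
                                      out2.loc[mask, num_cols])


class TestScaler:
    def test_median_and_iqr_scaling(self):
        train = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        (scaled,), state = fit_apply_scaler(train, feature_cols=["x"])
        assert scaled["x"].iloc[2] == 0.0  # median maps to 0
        other = state.transform(pd.DataFrame({"x": [5.0]}))
        assert other["x"].iloc[0] == pytest.approx((5 - 3) / 2.0)

    def test_constant_feature_flagged_and_passed_through(self):
        train = pd.DataFrame({"x": [2.0, 2, 2], "y": [1.0, 2, 3]})
        (scaled,), state = fit_apply_scaler(train, feature_cols=["x", "y"])
        assert state.constant == ["x"]
        assert (scaled["x"] == 2.0).all()

    def test_state_round_trips_through_json_bit_exactly(self, tmp_path):
        rng = np.random.default_rng(4)
        train = pd.DataFrame({"x": rng.normal(size=57), "y": rng.normal(size=57)})
        _, state = fit_apply_scaler(train, feature_cols=["x", "y"])
        path = tmp_path / "scaler.json"
        state.to_json(path)
        back = ScalerState.from_json(path)
        assert back.medians == state.medians and back.iqrs == state.iqrs
        test = pd.DataFrame({"x": rng.normal(size=9), "y": rng.normal(size=9)})
        pd.testing.assert_frame_equal(state.transform(test), back.transform(test))

    def test_leakage_audit_train_output_independent_of_eval_rows(self):
        rng = np.random.default_rng(6)
        train = pd.DataFrame({"x": rng.normal(size=40)})
        eval_a = pd.DataFrame({"x": rng.normal(size=20)})
        eval_b = pd.DataFrame({"x": rng.normal(100, 50, size=20)})
        (tr_a, _), _ = fit_apply_scaler(train, eval_a, feature_cols=["x"])
        (tr_b, _), _ = fit_apply_scaler(train, eval_b, feature_cols=["x"])
        pd.testing.assert_frame_equal(tr_a, tr_b)
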