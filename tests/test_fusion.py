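"""Dataset fusion: merge, imputation, encoding, scaling, splitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vpaml.fusion import (CONTINUOUS_FEATURES, FEATURES, TARGET,
                          build_feature_table, encode_and_drop, knn_impute,
                          merge_with_placeholders, minmax_scale,
                          split_derivation_validation)
from vpaml.vpop_sim import COLUMNS


def _raw_row(source="A", genotype="wildtype", gender="male", comeds="None",
             bw=60.0, alb=40.0, x0=500.0, tau=12.0, t=2.0, css=70.0):
    return dict(source=source, genotype=genotype, gender=gender,
                comeds=comeds, BW=bw, ALB=alb, single_dose=x0, tau=tau, t=t,
                daily_dose=x0 * 24 / tau, ka=2.38, Vd=22.15, CL=0.64, css=css)


class TestMerge:
    def test_row_counts_add(self, small_sim):
        a, b = small_sim
        merged = merge_with_placeholders(a, b)
        assert len(merged) == len(a) + len(b)
        missing_share = merged["gender"].isna().mean()
        assert missing_share == pytest.approx(len(b) / len(merged))

    def test_empty_second_input(self, small_sim):
        a, _ = small_sim
        empty = a.iloc[0:0]
        merged = merge_with_placeholders(a, empty)
        pd.testing.assert_frame_equal(merged, a[COLUMNS].reset_index(drop=True))

    def test_schema_mismatch_rejected(self, small_sim):
        a, b = small_sim
        with pytest.raises(ValueError, match="lacks columns"):
            merge_with_placeholders(a.drop(columns=["BW"]), b)

    def test_inconsistent_placeholders_rejected(self, small_sim):
        a, b = small_sim
        bad = a.copy()
        bad.loc[0, "comeds"] = "CBZ"
        with pytest.raises(ValueError, match="placeholder"):
            merge_with_placeholders(bad, b)


class TestKnnImpute:
    def _toy(self):
        # three complete donors, ALB 30/40/50; one incomplete row whose BW
        # makes it equidistant to the first two donors only
        rows = [_raw_row(bw=10.0, alb=30.0, gender="male"),
                _raw_row(bw=20.0, alb=40.0, gender="female"),
                _raw_row(bw=99.0, alb=50.0, gender="female"),
                _raw_row(source="B", genotype="unknown", comeds="CBZ",
                         bw=15.0, alb=np.nan, gender=np.nan)]
        return pd.DataFrame(rows)

    def test_hand_computed_neighbour_mean(self):
        out = knn_impute(self._toy(), k=2, distance_features=("BW",),
                         include_css=False)
        assert out.loc[3, "ALB"] == pytest.approx(35.0)

    def test_gender_tie_breaks_to_female(self):
        # k=2 neighbours are one male + one female: tie -> female
        out = knn_impute(self._toy(), k=2, distance_features=("BW",),
                         include_css=False)
        assert out.loc[3, "gender"] == "female"

    def test_strict_majority_yields_male(self):
        toy = self._toy()
        toy.loc[1, "gender"] = "male"
        out = knn_impute(toy, k=2, distance_features=("BW",),
                         include_css=False)
        assert out.loc[3, "gender"] == "male"

    def test_complete_rows_unchanged_and_no_missing_left(self, small_sim):
        a, b = small_sim
        merged = merge_with_placeholders(a, b)
        out = knn_impute(merged, k=5)
        complete = merged["gender"].notna()
        pd.testing.assert_frame_equal(out.loc[complete], merged.loc[complete])
        assert out["gender"].notna().all() and out["ALB"].notna().all()

    def test_k_exceeding_donor_count_rejected(self):
        with pytest.raises(ValueError, match="donor"):
            knn_impute(self._toy(), k=10)
        with pytest.raises(ValueError):
            knn_impute(self._toy(), k=0)


class TestEncoding:
    def test_source_a_wildtype_male_row(self):
        enc = encode_and_drop(pd.DataFrame([_raw_row()]))
        row = enc.iloc[0]
        assert row["CYP2C19*1/*1"] == 1.0
        assert row["CYP2C19*2 and/or *3 variants"] == 0.0
        assert row["Male"] == 1.0
        assert sum(row[f] for f in FEATURES if f.startswith("Co-")) == 0.0

    def test_source_b_row_drops_unknown_reference(self):
        enc = encode_and_drop(pd.DataFrame([_raw_row(
            source="B", genotype="unknown", gender="female",
            comeds="CBZ+PHT", alb=38.0)]))
        row = enc.iloc[0]
        assert row["CYP2C19*1/*1"] == 0.0
        assert row["CYP2C19*2 and/or *3 variants"] == 0.0
        assert row["Co-administered CBZ+PHT"] == 1.0

    def test_exactly_sixteen_features_and_no_latents(self):
        enc = encode_and_drop(pd.DataFrame([_raw_row()]))
        assert list(enc.columns) == list(FEATURES) + [TARGET]
        assert len(FEATURES) == 16
        for latent in ("ka", "Vd", "CL"):
            assert latent not in enc.columns

    def test_unexpected_categories_rejected(self):
        with pytest.raises(ValueError, match="genotype"):
            encode_and_drop(pd.DataFrame([_raw_row(genotype="het")]))
        with pytest.raises(ValueError, match="co-medication"):
            encode_and_drop(pd.DataFrame([_raw_row(comeds="VPA")]))
        with pytest.raises(ValueError, match="gender"):
            encode_and_drop(pd.DataFrame([_raw_row(gender=np.nan)]))


class TestScaling:
    def test_dose_extremes_map_to_unit_interval(self):
        df = pd.DataFrame({"Single Dose": [125.0, 500.0, 900.0]})
        scaled, spec = minmax_scale(df, features=("Single Dose",))
        assert scaled["Single Dose"].tolist() == pytest.approx(
            [0.0, (500 - 125) / 775, 1.0])

    def test_reuse_is_idempotent_and_roundtrip_exact(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({f: rng.uniform(1, 100, 50)
                           for f in CONTINUOUS_FEATURES})
        scaled, spec = minmax_scale(df)
        again, _ = minmax_scale(df, scaler=spec)
        pd.testing.assert_frame_equal(scaled, again)
        back = spec.inverse_transform(scaled)
        assert np.allclose(back.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_out_of_range_inputs_leave_unit_interval(self):
        df = pd.DataFrame({"BW": [50.0, 70.0]})
        _, spec = minmax_scale(df, features=("BW",))
        out = spec.transform(pd.DataFrame({"BW": [90.0]}))
        assert out["BW"].iloc[0] > 1.0

    def test_degenerate_feature_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            minmax_scale(pd.DataFrame({"BW": [60.0, 60.0]}), features=("BW",))


class TestSplit:
    def test_published_cohort_sizes(self):
        split = split_derivation_validation(26173, 0.8, seed=0)
        assert (split == "validation").sum() == 5235
        assert (split == "derivation").sum() == 20938

    def test_deterministic_and_partition(self):
        s1 = split_derivation_validation(1000, 0.8, seed=9)
        s2 = split_derivation_validation(1000, 0.8, seed=9)
        assert np.array_equal(s1, s2)
        assert set(np.unique(s1)) == {"derivation", "validation"}
        assert not np.array_equal(s1, split_derivation_validation(1000, 0.8,
                                                                  seed=10))


class TestFeatureTable:
    def test_row_conservation_and_schema(self, small_sim, small_table):
        a, b = small_sim
        assert len(small_table.df) == len(a) + len(b)
        assert list(small_table.df.columns) == list(FEATURES) + [TARGET]

    def test_indicators_mutually_exclusive(self, small_table):
        df = small_table.df
        assert (df["CYP2C19*1/*1"] + df["CYP2C19*2 and/or *3 variants"]
                <= 1).all()
        comed = df[[f for f in FEATURES if f.startswith("Co-")]].sum(axis=1)
        assert (comed <= 1).all()
        for f in FEATURES[6:]:
            assert set(np.unique(df[f])) <= {0.0, 1.0}

    def test_scaled_continuous_in_unit_interval(self, small_table):
        for f in CONTINUOUS_FEATURES:
            assert small_table.df[f].between(0, 1).all()

    def test_no_perfectly_collinear_feature_pair(self, small_table):
        corr = small_table.df[list(FEATURES)].corr().to_numpy()
        off = corr[~np.eye(16, dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.999

    def test_fused_css_close_to_normal(self, small_table):
        # probability-plot straightness of the concentration distribution
        (osm, osr), (slope, icpt, r) = stats.probplot(small_table.df[TARGET])
        assert r ** 2 > 0.9

    def test_scaler_mode_derivation_restricts_fit_rows(self, small_sim):
        a, b = small_sim
        t = build_feature_table(a, b, seed=7, scaler_mode="derivation")
        deriv = t.df.loc[(t.split == "derivation").to_numpy()]
        for f in CONTINUOUS_FEATURES:
            assert deriv[f].min() == pytest.approx(0.0, abs=1e-12)
            assert deriv[f].max() == pytest.approx(1.0, abs=1e-12)
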