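import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foxscreen import synth, triage
from foxscreen.flow import EventTable
from foxscreen.triage import (
    autofluorescence_flags,
    call_hits,
    channel_interference_profile,
    compile_triage_report,
    delta_ratio,
    normalize_viability,
    roc_analysis,
    toxicity_outliers,
    v450_stain_ratio,
)


def wells_frame(foxp3_values, dmso_value=10.0, plate_id="P1", n_dmso=4, **extra_cols):
    rows = []
    for i in range(n_dmso):
        rows.append(
            {"plate_id": plate_id, "well": f"P{i+1:02d}", "role": "dmso_positive",
             "compound_id": "DMSO", "foxp3_pct_cd4": dmso_value}
        )
    for i, v in enumerate(foxp3_values):
        rows.append(
            {"plate_id": plate_id, "well": f"A{i+1:02d}", "role": "compound",
             "compound_id": f"C{i+1:03d}", "foxp3_pct_cd4": v}
        )
    df = pd.DataFrame(rows)
    for k, v in extra_cols.items():
        df[k] = v
    return df


class TestCallHits:
    def test_rule_boundaries(self):
        df = call_hits(wells_frame([16.0, 4.0, 12.0, 15.0, 5.0]))
        calls = df[df["role"] == "compound"].set_index("compound_id")["hit_call"]
        assert calls["C001"] == "up"      # fold 1.6
        assert calls["C002"] == "down"    # fold 0.4
        assert calls["C003"] == "none"    # fold 1.2
        assert calls["C004"] == "up"      # fold 1.5 boundary inclusive
        assert calls["C005"] == "down"    # fold 0.5 boundary inclusive

    def test_dmso_mean_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            call_hits(wells_frame([10.0], dmso_value=0.0))

    def test_missing_dmso_errors(self):
        df = wells_frame([10.0], n_dmso=0)
        with pytest.raises(ValueError, match="dmso_positive"):
            call_hits(df)

    @given(
        st.lists(st.floats(0.0, 40.0), min_size=1, max_size=50),
        st.floats(5.0, 20.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force_rule(self, values, dmso):
        df = call_hits(wells_frame(values, dmso_value=dmso))
        sub = df[df["role"] == "compound"]
        for v, call in zip(values, sub["hit_call"]):
            fold = v / dmso
            expected = "up" if fold >= 1.5 else ("down" if fold <= 0.5 else "none")
            assert call == expected


class TestDeltaRatio:
    def test_simple_ratio(self):
        df = wells_frame([10.0], fsch_mfi=20_000.0)
        out = delta_ratio(df, {"P1": 10_000.0})
        assert out.loc[out["role"] == "compound", "delta_ratio"].iloc[0] == 2.0

    def test_dmso_well_near_own_pool(self, plate_summaries):
        summaries, plate_stats = plate_summaries
        out = delta_ratio(summaries, {"T1": plate_stats["dmso_pooled_fsch_mfi"]})
        dmso = out[out["role"] == "dmso_positive"]["delta_ratio"]
        assert np.allclose(dmso, 1.0, atol=0.05)

    def test_zero_pool_errors(self):
        df = wells_frame([10.0], fsch_mfi=20_000.0)
        with pytest.raises(ValueError, match="zero"):
            delta_ratio(df, {"P1": 0.0})

    def test_missing_plate_reference_errors(self):
        df = wells_frame([10.0], fsch_mfi=20_000.0)
        with pytest.raises(ValueError, match="no pooled"):
            delta_ratio(df, {})


class TestToxicityOutliers:
    def test_single_extreme_outlier_flagged(self, rng):
        ratios = np.full(50, 1.0) + rng.normal(0, 0.01, 50)
        ratios[7] = 2.0
        df = wells_frame(np.full(50, 10.0), delta_ratio=1.0)
        df.loc[df["role"] == "compound", "delta_ratio"] = ratios
        out = toxicity_outliers(df, scope="screen")
        flagged = out[out["toxic"]]
        assert list(flagged["compound_id"]) == ["C008"]

    def test_flags_match_brute_force_z(self, rng):
        ratios = rng.normal(1.0, 0.05, 80)
        df = wells_frame(np.full(80, 10.0))
        df.loc[df["role"] == "compound", "delta_ratio"] = ratios
        out = toxicity_outliers(df, scope="screen", k=2.0)
        z = (ratios - ratios.mean()) / np.std(ratios, ddof=1)
        sub = out[out["role"] == "compound"]
        np.testing.assert_allclose(sub["tox_z"].to_numpy(), z)
        np.testing.assert_array_equal(sub["toxic"].to_numpy(), np.abs(z) >= 2.0)

    def test_scope_plate_vs_screen_branches(self, rng):
        df1 = wells_frame(np.full(20, 10.0), plate_id="P1")
        df2 = wells_frame(np.full(20, 10.0), plate_id="P2")
        df = pd.concat([df1, df2], ignore_index=True)
        comp = df["role"] == "compound"
        df.loc[comp, "delta_ratio"] = np.concatenate(
            [rng.normal(1.0, 0.01, 20), rng.normal(1.3, 0.01, 20)]
        )
        screen = toxicity_outliers(df, scope="screen")
        plate = toxicity_outliers(df, scope="plate")
        # between-plate offset dominates in screen scope only
        assert not screen[comp].equals(plate[comp])
        assert not plate["toxic"].any()

    def test_sd_zero_errors(self):
        df = wells_frame(np.full(20, 10.0), delta_ratio=1.0)
        with pytest.raises(ValueError, match="SD is zero"):
            toxicity_outliers(df)

    def test_min_wells_enforced(self):
        df = wells_frame(np.full(3, 10.0), delta_ratio=1.0)
        with pytest.raises(ValueError, match="at least"):
            toxicity_outliers(df, min_wells=10)

    def test_controls_never_flagged(self, rng):
        df = wells_frame(np.full(30, 10.0))
        df["delta_ratio"] = rng.normal(1.0, 0.02, len(df))
        out = toxicity_outliers(df, scope="screen")
        assert not out.loc[out["role"] != "compound", "toxic"].any()


class TestViability:
    def test_equal_is_100(self):
        assert normalize_viability(80.0, 80.0) == 100.0

    def test_half_is_50(self):
        assert normalize_viability(40.0, 80.0) == 50.0

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            normalize_viability(50.0, 0.0)

    def test_simulated_dead_fraction(self):
        t = synth.simulate_well_events(
            "compound", synth.CompoundEffect("tox", dead_fraction=0.3), None, None, 20000, seed=2
        )
        d = synth.simulate_well_events("dmso_positive", None, None, None, 20000, seed=2)
        live_c = 100 * t.labels["live"].mean()
        live_d = 100 * d.labels["live"].mean()
        assert normalize_viability(live_c, live_d) == pytest.approx(70.0, abs=2.0)


class TestV450StainRatio:
    def test_simple_ratio(self):
        df = wells_frame([10.0], v450_mfi_pos=5000.0, v450_mfi_neg=500.0,
                         n_foxp3_pos=100, n_foxp3_neg=100)
        out = v450_stain_ratio(df)
        assert (out["v450_ratio"] == 10.0).all()

    def test_equal_medians_ratio_one(self):
        df = wells_frame([10.0], v450_mfi_pos=400.0, v450_mfi_neg=400.0,
                         n_foxp3_pos=50, n_foxp3_neg=50)
        assert (v450_stain_ratio(df)["v450_ratio"] == 1.0).all()

    def test_nonpositive_neg_median_indeterminate(self):
        df = wells_frame([10.0], v450_mfi_pos=5000.0, v450_mfi_neg=-3.0,
                         n_foxp3_pos=100, n_foxp3_neg=100)
        out = v450_stain_ratio(df)
        assert out["v450_ratio_indeterminate"].all()
        assert out["v450_ratio"].isna().all()

    def test_low_event_floor_indeterminate(self):
        df = wells_frame([10.0], v450_mfi_pos=5000.0, v450_mfi_neg=500.0,
                         n_foxp3_pos=3, n_foxp3_neg=100)
        assert v450_stain_ratio(df, min_events=10)["v450_ratio_indeterminate"].all()


class TestAutofluorescenceFlags:
    @staticmethod
    def frame(ratios, plate_id="P1"):
        df = wells_frame(np.full(len(ratios), 10.0), plate_id=plate_id)
        df["v450_ratio"] = np.nan
        df.loc[df["role"] == "compound", "v450_ratio"] = ratios
        return df

    def test_extreme_positive_outlier_high(self, rng):
        ratios = rng.normal(16.0, 0.5, 40)
        ratios[5] = ratios.mean() + 10 * ratios.std()
        out = autofluorescence_flags(self.frame(ratios))
        comp = out[out["role"] == "compound"].reset_index()
        assert comp.loc[5, "autofluor_level"] == "high"

    def test_minus_1p5_sd_is_low_moderate(self):
        # constructed so one well sits near z = -1.5
        base = np.concatenate([np.full(20, 16.0), np.full(20, 17.0)])
        ratios = np.concatenate([base, [16.5 - 1.5 * np.std(base, ddof=1)]])
        out = autofluorescence_flags(self.frame(ratios))
        comp = out[out["role"] == "compound"].reset_index()
        z = comp.loc[40, "af_z"]
        assert -3.0 < z <= -1.0
        assert comp.loc[40, "autofluor_level"] == "low_moderate"

    def test_sd_zero_errors(self):
        with pytest.raises(ValueError, match="SD is zero"):
            autofluorescence_flags(self.frame(np.full(30, 16.0)))

    def test_indeterminate_ratio_flagged_high(self, rng):
        ratios = rng.normal(16.0, 0.5, 40)
        df = self.frame(ratios)
        idx = df.index[df["role"] == "compound"][3]
        df.loc[idx, "v450_ratio"] = np.nan
        out = autofluorescence_flags(df)
        assert out.loc[idx, "autofluor_level"] == "high"

    def test_per_plate_statistics(self, rng):
        df1 = self.frame(rng.normal(16.0, 0.5, 30), plate_id="P1")
        df2 = self.frame(rng.normal(8.0, 0.5, 30), plate_id="P2")
        out = autofluorescence_flags(pd.concat([df1, df2], ignore_index=True))
        comp = out[out["role"] == "compound"]
        # plate-wise centering: despite the plate offset nothing is "high",
        # and each plate's z-scores are centered on its own mean
        assert not (comp["autofluor_level"] == "high").any()
        for pid in ("P1", "P2"):
            assert abs(comp.loc[comp["plate_id"] == pid, "af_z"].mean()) < 1e-9


class TestChannelInterference:
    @staticmethod
    def unstained(additive=None, seed=0):
        eff = synth.CompoundEffect("c", autofluor_additive=additive or {})
        return synth.simulate_well_events("unstained", None, None, None, 3000, seed=seed)

    def test_dmso_vs_dmso_nothing_flagged(self):
        a = self.unstained(seed=1)
        b = self.unstained(seed=2)
        report = channel_interference_profile(a, b)
        assert not report["interfered"].any()
        assert set(report.attrs["safe_channels"]) == {"PE-Cy7-A", "V450-A"}

    def test_single_channel_additive_flagged(self):
        compound = self.unstained(seed=3)
        compound.events[:, compound.channel_index("V450-A")] += 3000.0
        dmso = self.unstained(seed=4)
        report = channel_interference_profile(compound, dmso).set_index("channel")
        assert report.loc["V450-A", "interfered"]
        assert not report.loc["PE-Cy7-A", "interfered"]

    def test_three_adjacent_channels_flagged(self, rng):
        channels = ["FSC-A", "BV421-A", "BV510-A", "BV605-A", "APC-A"]
        base = np.exp(rng.normal(np.log(200), 0.4, size=(2000, 5)))
        dmso = EventTable(channels=channels, events=base.copy())
        shifted = base.copy()
        for ch in ("BV421-A", "BV510-A", "BV605-A"):
            shifted[:, channels.index(ch)] += 2000.0
        compound = EventTable(channels=channels, events=shifted)
        report = channel_interference_profile(compound, dmso).set_index("channel")
        assert report["interfered"].sum() == 3
        assert set(report.index[report["interfered"]]) == {"BV421-A", "BV510-A", "BV605-A"}
        assert report.attrs["safe_channels"] == ["APC-A"]

    def test_missing_shared_channels_errors(self):
        a = self.unstained()
        b = EventTable(channels=["OTHER-A"], events=np.ones((10, 1)))
        with pytest.raises(ValueError, match="shared|missing"):
            channel_interference_profile(a, b, fluor_channels=["V450-A"])


class TestRoc:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.1, 0.2, 0.3, 2.0, 2.5, 3.0])
        labels = np.array([False, False, False, True, True, True])
        assert roc_analysis(scores, labels).auc == 1.0

    def test_reversed_scores_complement(self, rng):
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.4
        auc = roc_analysis(scores, labels).auc
        assert roc_analysis(-scores, labels).auc == pytest.approx(1.0 - auc, abs=1e-12)

    def test_random_labels_auc_half(self, rng):
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.3
        base = roc_analysis(scores, labels).auc
        assert roc_analysis(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_analysis(3 * scores + 7, labels).auc == pytest.approx(base, abs=1e-12)

    def test_curve_monotone_and_ties_grouped(self, rng):
        scores = np.round(rng.normal(size=500), 1)  # force ties
        labels = scores + rng.normal(0, 1, 500) > 0
        curve = roc_analysis(scores, labels)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert len(np.unique(curve.thresholds)) == len(curve.thresholds)

    def test_agrees_with_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=400)
        labels = (scores + rng.normal(0, 1.5, 400)) > 0.2
        ours = roc_analysis(scores, labels).auc
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1.0, 2.0], [True, True])


class TestCompileReport:
    @staticmethod
    def staged(n=20, seed=0):
        rng = np.random.default_rng(seed)
        df = wells_frame(rng.normal(10, 0.5, n))
        df["fsch_mfi"] = 50_000.0
        df["v450_mfi_pos"] = 5000.0
        df["v450_mfi_neg"] = 300.0
        df["n_foxp3_pos"] = 100
        df["n_foxp3_neg"] = 500
        df = call_hits(df)
        df["delta_ratio"] = np.where(df["role"] == "compound", rng.normal(1, 0.02, len(df)), np.nan)
        df = toxicity_outliers(df, scope="screen")
        df = v450_stain_ratio(df)
        df["af_z"] = 0.0
        df["autofluor_level"] = np.where(df["role"] == "compound", "none", "")
        return df

    def test_empty_screen_empty_report(self):
        df = self.staged().iloc[0:0]
        report = compile_triage_report(df.assign(hit_call="", toxic=False, autofluor_level=""))
        assert report.empty

    def test_down_hit_with_high_autofluor_gets_retest_flag(self):
        df = self.staged()
        comp = df.index[df["role"] == "compound"]
        df.loc[comp[0], "hit_call"] = "down"
        df.loc[comp[0], "autofluor_level"] = "high"
        df.loc[comp[1], "hit_call"] = "up"
        df.loc[comp[1], "autofluor_level"] = "high"
        report = compile_triage_report(df).set_index("compound_id")
        assert report.loc["C001", "retest_alternate_fluorochrome"]
        assert not report.loc["C001", "candidate"]
        assert not report.loc["C002", "retest_alternate_fluorochrome"]  # up-hit: dropped outright
        assert not report.loc["C002", "candidate"]

    def test_candidates_exclude_toxic_and_high_af(self):
        df = self.staged()
        comp = df.index[df["role"] == "compound"]
        df.loc[comp[0], "hit_call"] = "up"
        df.loc[comp[1], "hit_call"] = "up"
        df.loc[comp[1], "toxic"] = True
        report = compile_triage_report(df).set_index("compound_id")
        assert report.loc["C001", "candidate"]
        assert not report.loc["C002", "candidate"]
        assert int(report["candidate"].sum()) == 1

    def test_missing_stage_columns_rejected(self):
        with pytest.raises(ValueError, match="stages"):
            compile_triage_report(wells_frame([10.0]))
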