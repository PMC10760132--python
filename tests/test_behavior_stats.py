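import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import tmrsim as tm


def interaction(df, spec=None):
    frame = tm.prepare_model_frame(df, spec or tm.ModelSpec())
    res = tm.fit_primary_model(frame)
    return tm.interaction_coefficient(res)[1], res


class TestPrepareModelFrame:
    def test_never_cued_items_in_cued_category_are_not_cued(self, behavior34):
        frame = tm.prepare_model_frame(behavior34, tm.ModelSpec())
        assert "uncued_in_cued" not in set(frame["cue_condition"])
        cued = frame[frame["cueing"] == "cued"]
        assert (cued["times_cued"] >= 1).all()

    def test_style_model_requires_four_cues(self, behavior34):
        frame = tm.prepare_model_frame(behavior34,
                                       tm.ModelSpec(variant="style"))
        assert (frame["times_cued"] >= 4).all()
        assert set(frame["cueing"].unique()) <= {"interleaved", "blocked"}

    def test_times_cued_centered_to_zero_mean(self, behavior34):
        frame = tm.prepare_model_frame(behavior34, tm.ModelSpec())
        assert abs(frame["times_cued_c"].mean()) < 1e-12

    def test_seqpos_keeps_only_labelled_blocked_and_uncued(self, behavior34):
        frame = tm.prepare_model_frame(
            behavior34, tm.ModelSpec(variant="seqpos_numeric"))
        blocked = frame[frame["sequence_position"] > 0]
        assert (blocked["order_condition"] == "blocked").all()
        assert set(frame.loc[frame["sequence_position"] == 0,
                             "cue_condition"]) == {"uncued"}

    def test_degenerate_design_raises(self, behavior34):
        only_uncued = behavior34[behavior34["cue_condition"] == "uncued"]
        with pytest.raises(tm.DegenerateDesignError):
            tm.prepare_model_frame(only_uncued, tm.ModelSpec())

    def test_shared_ge_unique_subset_filter(self, behavior34):
        frame = tm.prepare_model_frame(
            behavior34, tm.ModelSpec(shared_ge_unique_subset=True))
        wide = frame.pivot_table(index=["subject", "item"],
                                 columns="feature_type",
                                 values="prenap_accuracy")
        wide = wide.dropna()
        assert (wide["shared"] >= wide["unique"]).all()


class TestPrimaryModel:
    def test_matches_lme4_on_small_data(self, stimuli, tmp_path):
        """Independent oracle: REML fixed effects from R's lmer agree with
        the statsmodels fit to ~1e-4."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = tm.simulate_behavior(stimuli, n_subjects=10, seed=31)
        frame = tm.prepare_model_frame(df, tm.ModelSpec())
        res = tm.fit_primary_model(frame)
        csv = tmp_path / "frame.csv"
        frame.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$cueing <- factor(d$cueing, levels=c("uncued","cued"))
d$feature_type <- factor(d$feature_type, levels=c("shared","unique"))
m <- lmer(accuracy_difference ~ cueing*feature_type + times_cued_c +
          prenap_accuracy + (1|subject), data=d, REML=TRUE)
write.csv(data.frame(b=fixef(m)), "{tmp_path}/fe.csv")
""")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        fe = pd.read_csv(tmp_path / "fe.csv", index_col=0)["b"]
        order = ["(Intercept)", "cueingcued", "feature_typeunique",
                 "times_cued_c", "prenap_accuracy",
                 "cueingcued:feature_typeunique"]
        ours = ["Intercept", "cueing[T.cued]", "feature_type[T.unique]",
                "times_cued_c", "prenap_accuracy",
                "cueing[T.cued]:feature_type[T.unique]"]
        np.testing.assert_allclose(res.params[ours].to_numpy(),
                                   fe[order].to_numpy(), atol=1e-4)

    def test_recovers_planted_interaction(self, stimuli):
        vals = []
        for r in range(30):
            df = tm.simulate_behavior(tm.build_stimuli(seed=400 + r),
                                      n_subjects=34, seed=500 + r)
            vals.append(interaction(df)[0])
        assert np.mean(vals) == pytest.approx(0.17, abs=0.03)

    def test_equal_effects_on_both_features_give_pure_main_effect(self, stimuli):
        eff = tm.EffectSpec(delta_unique=0.10, delta_shared=-0.10,
                            spread_fraction=0.0, subject_sd=0.02,
                            item_sd=0.02)
        df = tm.simulate_behavior(stimuli, eff, n_subjects=300, seed=32)
        b, res = interaction(df)
        assert abs(b) < 0.02
        assert res["cueing[T.cued]"] == pytest.approx(0.10, abs=0.03)

    def test_type_one_error_near_nominal(self):
        """Null data rejects the interaction at ~5%."""
        eff = tm.EffectSpec(delta_unique=0.0, delta_shared=0.0,
                            spread_fraction=0.0)
        hits = 0
        runs = 120
        for r in range(runs):
            df = tm.simulate_behavior(tm.build_stimuli(seed=600 + r), eff,
                                      n_subjects=34, seed=700 + r)
            frame = tm.prepare_model_frame(df, tm.ModelSpec())
            res = tm.fit_primary_model(frame)
            name, _ = tm.interaction_coefficient(res)
            hits += res.pvalues[name] < 0.05
        rate = hits / runs
        assert 0.05 - 2.58 * np.sqrt(0.05 * 0.95 / runs) <= rate \
            <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / runs)

    def test_marginal_mean_contrasts_reflect_planted_margins(self, stimuli):
        df = tm.simulate_behavior(stimuli, n_subjects=500, seed=33)
        _, res = interaction(df)
        con = res.contrasts.set_index(["lhs", "rhs"])
        cu = con.loc[("uncued,unique", "cued,unique"), "estimate"]
        assert cu == pytest.approx(-tm.EffectSpec().delta_unique, abs=0.03)
        cs = con.loc[("uncued,shared", "cued,shared"), "estimate"]
        assert cs == pytest.approx(tm.EffectSpec().delta_shared, abs=0.03)

    def test_result_carries_df_method_flag(self, behavior34):
        _, res = interaction(behavior34)
        assert res.df_method == "normal"
        assert res.converged


class TestVariantModels:
    def test_spread_zero_when_no_spread_planted(self, stimuli):
        # few never-cued items exist per subject, so this cell is noisy;
        # n_subjects is sized to bring its SE near 0.01
        eff = tm.EffectSpec(spread_fraction=0.0, subject_sd=0.03, item_sd=0.03)
        df = tm.simulate_behavior(stimuli, eff, n_subjects=800, seed=41)
        frame = tm.prepare_model_frame(df, tm.ModelSpec(variant="spread"))
        res = tm.fit_variant_model(frame)
        b = res.params["cueing[T.uncued_cued]:feature_type[T.unique]"]
        assert abs(b) < 0.04

    def test_spread_recovered_when_planted(self, stimuli):
        eff = tm.EffectSpec()  # spread fraction 0.6 of the 0.17 interaction
        df = tm.simulate_behavior(stimuli, eff, n_subjects=500, seed=42)
        frame = tm.prepare_model_frame(df, tm.ModelSpec(variant="spread"))
        res = tm.fit_variant_model(frame)
        b = res.params["cueing[T.uncued_cued]:feature_type[T.unique]"]
        assert b == pytest.approx(0.6 * 0.17, abs=0.03)

    def test_style_interaction_zero_under_equal_styles(self, stimuli):
        df = tm.simulate_behavior(stimuli, tm.EffectSpec(), n_subjects=300,
                                  seed=43)
        frame = tm.prepare_model_frame(df, tm.ModelSpec(variant="style"))
        res = tm.fit_variant_model(frame)
        assert abs(res.params["cueing[T.blocked]:feature_type[T.unique]"]) < 0.03

    def test_style_asymmetry_recovered(self, stimuli):
        eff = tm.EffectSpec(style_multiplier={"blocked": 1.4,
                                              "interleaved": 0.6})
        df = tm.simulate_behavior(stimuli, eff, n_subjects=400, seed=44)
        frame = tm.prepare_model_frame(df, tm.ModelSpec(variant="style"))
        res = tm.fit_variant_model(frame)
        b = res.params["cueing[T.blocked]:feature_type[T.unique]"]
        assert b == pytest.approx(0.8 * 0.17, abs=0.04)  # (1.4-0.6) x plant

    def test_sequence_position_gradient_recovered(self, stimuli):
        g = 0.03
        eff = tm.EffectSpec(seqpos_gradient=g)
        df = tm.simulate_behavior(stimuli, eff, n_subjects=500, seed=45)
        frame = tm.prepare_model_frame(
            df, tm.ModelSpec(variant="seqpos_categorical"))
        res = tm.fit_variant_model(frame, tm.ModelSpec(
            variant="seqpos_categorical"))
        b4 = res.params["sequence_position[T.4]:feature_type[T.unique]"]
        b1 = res.params["sequence_position[T.1]:feature_type[T.unique]"]
        assert b4 - b1 == pytest.approx(2 * g * 3, abs=0.04)

    def test_stage_model_levels_all_recover_plant(self, stimuli):
        df = tm.simulate_behavior(stimuli, n_subjects=400, seed=46)
        frame = tm.prepare_model_frame(df, tm.ModelSpec(variant="stage"))
        res = tm.fit_variant_model(frame)
        for lv in ("N2", "N3", "both"):
            b = res.params[f"cueing[T.{lv}]:feature_type[T.unique]"]
            assert b == pytest.approx(0.17, abs=0.04)

    def test_power_covariate_null_by_default(self, stimuli):
        df = tm.simulate_behavior(stimuli, n_subjects=300, seed=47)
        frame = tm.prepare_model_frame(df, tm.ModelSpec(variant="power_theta"))
        res = tm.fit_variant_model(frame, tm.ModelSpec(variant="power_theta"))
        assert abs(res.params["theta_power:feature_type[T.unique]"]) < 0.02

    def test_novel_model_drops_feature_type(self, behavior34):
        frame = tm.prepare_model_frame(behavior34,
                                       tm.ModelSpec(variant="novel"))
        res = tm.fit_variant_model(frame, tm.ModelSpec(variant="novel"))
        assert all("feature_type" not in n for n in res.params.index)

    def test_unpopulated_level_raises_named_error(self, stimuli):
        df = tm.simulate_behavior(stimuli, n_subjects=20, seed=48)
        df = df[df["cue_condition"] != "uncued_in_cued"]
        with pytest.raises(tm.DegenerateDesignError, match="uncued_cued"):
            tm.prepare_model_frame(df, tm.ModelSpec(variant="spread"))


class TestTradeoffSlopes:
    def test_independent_features_give_zero_mean_slope(self, stimuli):
        eff = tm.EffectSpec(item_sd=0.0)
        df = tm.simulate_behavior(stimuli, eff, n_subjects=300, seed=51)
        res = tm.tradeoffs = tm.tradeoff_slopes(df, "pre")
        assert abs(res.mean) < 0.03

    def test_planted_anticorrelation_recovered(self, stimuli):
        eff = tm.EffectSpec(item_sd=0.0, tradeoff_slope=-0.11,
                            delta_unique=0.0, delta_shared=0.0,
                            spread_fraction=0.0)
        means = [tm.tradeoff_slopes(
            tm.simulate_behavior(stimuli, eff, n_subjects=200, seed=60 + r),
            "post").mean for r in range(5)]
        assert np.mean(means) == pytest.approx(-0.11, abs=0.03)

    def test_subject_without_unique_variance_excluded(self, stimuli):
        df = tm.simulate_behavior(stimuli, n_subjects=5, seed=52)
        flat = df["subject"] == "s001"
        df.loc[flat & (df["feature_type"] == "unique"),
               ["prenap_accuracy", "postnap_accuracy"]] = 0.5
        res = tm.tradeoff_slopes(df, "post")
        assert "s001" in res.excluded
        assert "s001" not in res.slopes.index

    def test_paired_change_runs(self, stimuli):
        df = tm.simulate_behavior(stimuli, n_subjects=40, seed=53)
        out = tm.paired_slope_change(df)
        assert set(out) == {"change", "t", "p", "n"}
        assert out["n"] >= 30
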