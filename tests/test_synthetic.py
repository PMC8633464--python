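"""The cohort generator: determinism, calibration, planting, builders."""

import numpy as np
import pytest

from ezloc import (
    CohortTable,
    ConfigError,
    FeatureName,
    PlantingError,
    Rule,
    SimulationConfig,
    adjusted_prevalence,
    cohens_kappa,
    cohort_from_feature_counts,
    cohort_from_multiplicity_histogram,
    evaluate_rule,
    generate_cohort,
    plant_rule,
)
from ezloc.core_data import FCD_COLUMNS, LESION_FEATURES


def _zero_prev():
    return {f.value: 0.0 for f in LESION_FEATURES}


def _unit_or():
    return {f.value: 1.0 for f in LESION_FEATURES}


NOISELESS = {"R1": {"fp_rate": 0.0, "fn_rate": 0.0},
             "R2": {"fp_rate": 0.0, "fn_rate": 0.0}}


class TestConfig:
    def test_zero_patients_rejected(self):
        with pytest.raises(Exception):
            SimulationConfig(n_patients=0)

    def test_size_dist_must_sum_to_one(self):
        with pytest.raises(Exception):
            SimulationConfig(ez_size_dist=(0.5, 0.5, 0.5, 0.0))

    def test_feature_keys_checked(self):
        with pytest.raises(Exception):
            SimulationConfig(baseline_prev={"tuber": 0.1})

    def test_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_patients=5, seed=3)
        path = tmp_path / "cfg.json"
        path.write_text(cfg.model_dump_json())
        assert SimulationConfig.from_json(path) == cfg

    def test_invalid_json_config_is_config_error(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"n_patients": -3}')
        with pytest.raises(ConfigError):
            SimulationConfig.from_json(path)


class TestGeneration:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_patients=10, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert a.cohort == b.cohort
        assert a.truth.equals(b.truth)

    def test_seed_changes_cohort(self):
        a = generate_cohort(SimulationConfig(n_patients=10, seed=1))
        b = generate_cohort(SimulationConfig(n_patients=10, seed=2))
        assert a.cohort != b.cohort

    def test_null_model_is_empty(self):
        cfg = SimulationConfig(
            n_patients=4, seed=0, baseline_prev=_zero_prev(),
            ez_odds_ratio=_unit_or(), rater_flip=NOISELESS,
        )
        cohort = generate_cohort(cfg).cohort
        frame = cohort.frame
        feature_cols = [f.value for f in FeatureName]
        assert not frame[feature_cols].to_numpy().any()

    def test_perfect_raters_reproduce_latent_truth(self):
        cfg = SimulationConfig(n_patients=20, seed=8, rater_flip=NOISELESS)
        result = generate_cohort(cfg)
        f1 = result.cohort.rater_frame("R1")
        f2 = result.cohort.rater_frame("R2")
        lesion = [f.value for f in LESION_FEATURES]
        assert f1[lesion].equals(f2[lesion])
        truth = result.truth.sort_values(
            ["patient_id", "hemisphere", "region"]
        ).reset_index(drop=True)
        assert f1[lesion].to_numpy().tolist() == (
            truth[lesion].to_numpy().tolist()
        )
        tuber = f1["tuber"].to_numpy(int)
        assert cohens_kappa(tuber, f2["tuber"].to_numpy(int)).estimate == 1.0

    def test_roi_prevalence_within_binomial_error(self):
        # flat 17.9% prevalence, no EZ enrichment, no noise: the empirical
        # ROI rate over 4400 draws must sit within 3 binomial SEs
        prev = _zero_prev()
        prev["gwm_blurring"] = 0.179
        cfg = SimulationConfig(
            n_patients=200, seed=13, baseline_prev=prev,
            ez_odds_ratio=_unit_or(), rater_flip=NOISELESS,
        )
        cohort = generate_cohort(cfg).cohort
        frame = cohort.rater_frame("R1")
        p_hat = frame["gwm_blurring"].mean()
        se = np.sqrt(0.179 * (1 - 0.179) / len(frame))
        assert abs(p_hat - 0.179) <= 3 * se

    def test_mixture_prevalence_with_enrichment(self):
        # empirical prevalence must converge to the EZ/non-EZ mixture
        cfg = SimulationConfig(n_patients=300, seed=21, rater_flip=NOISELESS)
        result = generate_cohort(cfg)
        frame = result.cohort.rater_frame("R1")
        sizes = np.asarray(cfg.ez_size_dist)
        f_ez = float((sizes * np.arange(1, 5)).sum()) / 22
        for feat in ("calcification", "transmantle_sign"):
            p0 = cfg.baseline_prev[feat]
            p1 = adjusted_prevalence(p0, cfg.ez_odds_ratio[feat])
            p_mix = f_ez * p1 + (1 - f_ez) * p0
            p_hat = frame[feat].mean()
            se = np.sqrt(p_mix * (1 - p_mix) / len(frame))
            assert abs(p_hat - p_mix) <= 3 * se

    def test_largest_area_designation_invariant(self):
        result = generate_cohort(SimulationConfig(n_patients=30, seed=4))
        for rater in ("R1", "R2"):
            frame = result.cohort.rater_frame(rater)
            for _, grp in frame.groupby("patient_id"):
                n_largest = int(grp["largest_fcd_area"].sum())
                if grp[FCD_COLUMNS].to_numpy().any():
                    assert n_largest == 1
                else:
                    assert n_largest == 0


class TestPlanting:
    RULE = Rule(frozenset({FeatureName.TUBER, FeatureName.CALCIFICATION}), 2)

    def test_noiseless_planting_is_perfect(self):
        cfg = SimulationConfig(n_patients=8, seed=6, p_seizure_free=1.0,
                               rater_flip=NOISELESS)
        planted = plant_rule(generate_cohort(cfg), self.RULE)
        ev = evaluate_rule(self.RULE, planted.cohort, "R1")
        assert ev.n_perfect == ev.n_patients == 8

    def test_single_feature_planting_edits_latent_truth(self):
        cfg = SimulationConfig(n_patients=6, seed=3, p_seizure_free=1.0,
                               rater_flip=NOISELESS)
        rule = Rule(frozenset({FeatureName.CYST}), 1)
        planted = plant_rule(generate_cohort(cfg), rule)
        truth = planted.truth
        assert truth.loc[truth["ez"], "cyst"].all()
        assert not truth.loc[~truth["ez"], "cyst"].any()

    def test_heavy_noise_breaks_coverage(self):
        noisy = {"R1": {"fp_rate": 0.0, "fn_rate": 0.5}}
        cfg = SimulationConfig(n_patients=15, seed=0, p_seizure_free=1.0,
                               rater_flip=noisy)
        planted = plant_rule(generate_cohort(cfg), self.RULE)
        ev = evaluate_rule(self.RULE, planted.cohort, "R1")
        assert ev.n_perfect < ev.n_patients

    def test_guarantee_flag_shields_rule_features_from_noise(self):
        noisy = {"R1": {"fp_rate": 0.1, "fn_rate": 0.5}}
        cfg = SimulationConfig(n_patients=15, seed=0, p_seizure_free=1.0,
                               rater_flip=noisy)
        planted = plant_rule(generate_cohort(cfg), self.RULE, guarantee=True)
        ev = evaluate_rule(self.RULE, planted.cohort, "R1")
        assert ev.n_perfect == ev.n_patients

    def test_largest_area_cannot_be_planted(self):
        cfg = SimulationConfig(n_patients=4, seed=1)
        rule = Rule(frozenset({FeatureName.LARGEST_FCD_AREA}), 1)
        with pytest.raises(PlantingError):
            plant_rule(generate_cohort(cfg), rule)


class TestPrintedCountBuilders:
    ROI_COUNTS = {"tuber": 187, "cyst": 11, "calcification": 13,
                  "increased_thickness": 34, "gwm_blurring": 110,
                  "transmantle_sign": 65}
    PATIENT_COUNTS = {"tuber": 28, "cyst": 6, "calcification": 11,
                      "increased_thickness": 21, "gwm_blurring": 26,
                      "transmantle_sign": 24}

    def test_feature_counts_are_reproduced(self):
        from ezloc import summarize_prevalence

        cohort = cohort_from_feature_counts(self.ROI_COUNTS,
                                            self.PATIENT_COUNTS)
        summary = summarize_prevalence(cohort, "R1")
        for f in LESION_FEATURES:
            prev = summary.features[f]
            assert prev.rois_positive == self.ROI_COUNTS[f.value]
            assert prev.patients_positive == self.PATIENT_COUNTS[f.value]
        assert summary.rois_total == 616

    def test_histogram_is_reproduced(self):
        from ezloc import summarize_prevalence

        hist = {0: 372, 1: 128, 2: 74, 3: 27, 4: 10, 5: 5, 6: 0}
        cohort = cohort_from_multiplicity_histogram(hist)
        summary = summarize_prevalence(cohort, "R1")
        assert dict(summary.histogram) == hist

    def test_infeasible_counts_rejected(self):
        bad = dict(self.ROI_COUNTS, cyst=500)  # 6 patients can't host 500
        with pytest.raises(ConfigError):
            cohort_from_feature_counts(bad, self.PATIENT_COUNTS)
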