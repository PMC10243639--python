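import numpy as np
import pytest
from dataclasses import replace

import glimpsetrf as g
from glimpsetrf.comparison import (
    ablation_test,
    classify_joint_encoding,
    run_ablations,
    shuffled_feature_test,
    snr_threshold_sweep,
)
from glimpsetrf.phonemes import (
    build_phonetic_regressors,
    compute_glimpse_ratios,
    shuffle_feature_mapping,
)
from glimpsetrf.trf import CVRidge, RegressorBank, make_lag_frames


LAGS = make_lag_frames((0.0, 150.0), 100.0)


@pytest.fixture(scope="module")
def encoded_ds():
    """Small two-group dataset with both phonetic groups encoded."""
    sc = replace(g.make_scenario_presets()["threshold_recovery"],
                 n_subjects=3, electrodes_per_subject=4, duration_s=30.0)
    return g.generate_dataset(sc, 21)


@pytest.fixture(scope="module")
def encoded_lams(encoded_ds):
    return {n: 100.0 for n in encoded_ds.bank.names}


class TestAblation:
    def test_encoded_group_detected(self, encoded_ds, encoded_lams):
        res = ablation_test(encoded_ds.bank, encoded_ds.responses,
                            "glimpsed_phonetic", encoded_ds.subject_ids,
                            encoded_lams, LAGS, n_boot=1000, seed=0)
        assert res.mean_delta_z > 0
        assert res.bootstrap_p < 0.05
        assert res.t_statistic > 0

    def test_duplicated_group_has_no_unique_contribution(self, rng):
        # a group duplicated by a collinear copy carries no unique information
        n = 3000
        x = rng.standard_normal((n, 3))
        bank = (RegressorBank(100.0)
                .add("orig", x).add("copy", x.copy()))
        from glimpsetrf.trf import build_lagged_design
        design = build_lagged_design(x, LAGS[:6])
        y = design @ rng.standard_normal((design.shape[1], 4)) \
            + rng.standard_normal((n, 4))
        res = ablation_test(bank, y, "orig", np.repeat([0, 1], 2),
                            {"orig": 10.0, "copy": 10.0}, LAGS[:6],
                            n_boot=500, seed=0)
        assert abs(res.mean_delta_z) < 0.01
        assert res.bootstrap_p > 0.05

    def test_add_back_reproduces_baseline_exactly(self, encoded_ds, encoded_lams):
        engine = CVRidge(encoded_ds.bank, encoded_ds.responses, LAGS, 5)
        z1 = engine.evaluate(lambdas=encoded_lams)
        z2 = engine.evaluate(list(encoded_ds.bank.names), encoded_lams)
        assert np.array_equal(z1, z2)

    def test_unknown_group_raises(self, encoded_ds, encoded_lams):
        with pytest.raises(KeyError):
            ablation_test(encoded_ds.bank, encoded_ds.responses, "nope",
                          encoded_ds.subject_ids, encoded_lams, LAGS)

    def test_run_ablations_table(self, encoded_ds, encoded_lams):
        table, results = run_ablations(
            encoded_ds.bank, encoded_ds.responses,
            ["glimpsed_phonetic", "masked_phonetic"],
            encoded_ds.subject_ids, encoded_ds.regions,
            lambdas=encoded_lams, lag_frames=LAGS, n_boot=500, seed=0)
        assert set(table["feature"]) == {"glimpsed_phonetic", "masked_phonetic"}
        assert len(table) == 2 * encoded_ds.responses.shape[0]
        assert all(r.bootstrap_p < 0.05 for r in results.values())


class TestShuffledFeatureTest:
    def test_encoded_electrodes_flagged(self):
        sc = replace(g.make_scenario_presets()["threshold_recovery"],
                     alphabet=g.synthetic.FULL_ALPHABET,
                     n_subjects=2, electrodes_per_subject=4, duration_s=60.0,
                     subject_snr_sd=0.0)
        ds = g.generate_dataset(sc, 3)
        ratios = compute_glimpse_ratios(ds.target_spec, ds.background_spec,
                                        ds.target_tier, sc.theta_star_db)

        def shuffler(seed):
            fm = shuffle_feature_mapping(ds.fmap, seed)
            return build_phonetic_regressors(ds.target_tier, fm, ratios,
                                             100.0, ds.n_frames)["glimpsed"]

        res = shuffled_feature_test(
            ds.bank, ds.responses, "glimpsed_phonetic", shuffler,
            n_shuffles=10, seed=0, lambdas={n: 1e3 for n in ds.bank.names},
            lag_frames=LAGS)
        assert res.significant.mean() >= 0.75
        # shuffled accuracies sit below baseline for encoded electrodes
        assert np.mean(res.shuffled_z.mean(axis=0) < res.baseline_z) >= 0.75

    def test_unencoded_response_rarely_flagged(self, rng):
        sc = replace(g.make_scenario_presets()["threshold_recovery"],
                     alphabet=g.synthetic.FULL_ALPHABET,
                     n_subjects=2, electrodes_per_subject=4, duration_s=30.0,
                     encoding={}, target_r=0.0)
        ds = g.generate_dataset(sc, 5)
        ratios = compute_glimpse_ratios(ds.target_spec, ds.background_spec,
                                        ds.target_tier, sc.theta_star_db)

        def shuffler(seed):
            fm = shuffle_feature_mapping(ds.fmap, seed)
            return build_phonetic_regressors(ds.target_tier, fm, ratios,
                                             100.0, ds.n_frames)["glimpsed"]

        res = shuffled_feature_test(
            ds.bank, ds.responses, "glimpsed_phonetic", shuffler,
            n_shuffles=8, seed=0, lambdas={n: 100.0 for n in ds.bank.names},
            lag_frames=LAGS)
        assert res.significant.mean() <= 0.25


class TestThresholdSweep:
    def test_deterministic_and_peaked_near_truth(self, encoded_ds, encoded_lams):
        thresholds = np.arange(-8.0, 1.0, 1.0)
        kw = dict(thresholds_db=thresholds, lambdas=encoded_lams,
                  lag_frames=LAGS, n_boot=300, seed=4)
        r1 = snr_threshold_sweep(lambda th: encoded_ds.bank_at(th),
                                 encoded_ds.responses, encoded_ds.subject_ids, **kw)
        r2 = snr_threshold_sweep(lambda th: encoded_ds.bank_at(th),
                                 encoded_ds.responses, encoded_ds.subject_ids, **kw)
        assert np.array_equal(r1.mean_z, r2.mean_z)
        assert abs(r1.best_threshold_db - encoded_ds.scenario.theta_star_db) <= 2.0
        assert r1.comparison_p[list(thresholds).index(r1.best_threshold_db)] == 1.0

    def test_binary_drive_gives_flat_profile(self):
        sc = replace(g.make_scenario_presets()["flat_threshold"],
                     n_subjects=3, electrodes_per_subject=4, duration_s=30.0)
        ds = g.generate_dataset(sc, 9)
        res = snr_threshold_sweep(
            lambda th: ds.bank_at(th), ds.responses, ds.subject_ids,
            thresholds_db=np.arange(-8.0, 1.0, 2.0),
            lambdas={n: 100.0 for n in ds.bank.names},
            lag_frames=LAGS, n_boot=500, seed=0)
        # no threshold is significantly better than any other
        assert np.ptp(res.mean_z) < 0.1 * res.mean_z.mean()
        assert (res.comparison_p > 0.05).all()

    def test_empty_threshold_list_rejected(self, encoded_ds, encoded_lams):
        with pytest.raises(ValueError):
            snr_threshold_sweep(lambda th: encoded_ds.bank_at(th),
                                encoded_ds.responses, encoded_ds.subject_ids,
                                thresholds_db=np.array([]))


class TestJointEncodingClassification:
    def test_four_way_partition(self):
        sig_g = np.array([True, True, False, False])
        sig_m = np.array([True, False, True, False])
        cats, counts = classify_joint_encoding(sig_g, sig_m,
                                               np.array(["HG", "HG", "STG", "STG"]))
        assert cats.tolist() == ["both", "glimpsed-only", "masked-only", "none"]
        assert counts["HG"]["both"] == 1 and counts["STG"]["none"] == 1

    def test_glimpsed_only_region(self):
        sig_g = np.ones(10, bool)
        sig_m = np.zeros(10, bool)
        cats, counts = classify_joint_encoding(sig_g, sig_m)
        assert (cats == "glimpsed-only").all()
        assert counts["all"]["glimpsed-only"] == 10
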